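# Methods

This note records the models, conventions and parameter choices behind
`transmod`, in the order the pipeline runs them.

## ISA variant and normalization

The iterative signature algorithm is implemented in its
binary-membership form: after each scoring step the scores are
thresholded to a set, so a module is a self-consistent pair (gene set,
signed tissue set) and convergence, deduplication and merging are all
well defined on sets. The update rules are

* tissue scores `s_t = mean over current genes of col_norm[·, t]`,
  selection `|s_t| > Tc·σ(s)` with the sign retained;
* gene scores `s_i = mean over selected tissues of sign(s_t)·row_norm[i, t]`,
  selection `s_i > mean(s) + Tg·σ(s)`.

The tissue threshold is two-sided so a module can include coherently
suppressed tissues (negative score); the gene threshold is one-sided
because a module's genes are one co-regulated set. All standard
deviations are population-convention over the current score vector;
this convention is load-bearing (it sets the effective thresholds) and
is fixed throughout. Row/column standardization happens once on the
log-scale matrix; zero-variance rows or columns are set to zeros and
logged — they can never pass a threshold.

A seed dissolves when a selection empties, when `max_iter` (100)
passes without a fixed point, or when the gene-set sequence revisits a
state within the last 10 iterations (limit cycle, detected by
hashing). Converged modules with fewer than `min_module_genes` genes
(default 2) are discarded. Random noise supports many self-consistent
2–5-gene fixed points in this variant; because the smallest module the
method reports on real atlas data has 10 genes, analysis-scale runs in
the examples and tests use `min_module_genes = 10`. Discovery
deduplicates fixed points on identical gene sets (gene-level
similarity exactly 1).

A geometric constraint worth knowing: row standardization caps the
score of a gene expressed in k of T tissues at `√((T−k)/k)` sd units,
so with T = 29 tissues a Tg = 3 search can only ever capture modules
active in roughly k ≤ 5 tissues. This matches the tissue-sparse
modules the method targets and explains why planted blocks in tests
use ~3 tissues.

## Merging and refinement

Module similarity is defined at three levels, each normalized by the
geometric mean of set sizes (gene, tissue, combined), plus
min-cardinality variants whose value is 1 exactly when the smaller set
is nested in the larger. The merge graph uses the gene-level form —
every explicit similarity computation elsewhere in the pipeline is
gene-level — but the level is configurable.

IGMM merges each maximal clique of the module relationship graph
(threshold 0.7), keeping items present in `⌈0.8k⌉` of k parents
("no less than 80 %" is a ≥ constraint, hence the ceiling). When
cliques overlap within a round they are processed in decreasing size
with lexicographic tie-breaks, and a module consumed by an earlier
clique is dropped from later ones; remaining overlap resolves in
subsequent rounds. The rule is deterministic, and the set size
strictly decreases whenever a merge happens, so the iteration
terminates. Merged tissue scores are means of the parents' signed
scores. Refinement keeps a merged module only if some raw ISA module
attains min-cardinality similarity 1 against it on both the gene and
the tissue level (the strictest reading; a combined-level-only mode
exists).

## Cross-species comparison

Cross-species gene overlaps are counted through a validated one-to-one
orthology map. The paralog-modified similarity counts, per side, genes
with an ortholog in the opposite module or sharing a paralog family
with the ortholog of an opposite-module gene; each gene counts once
even if matched both ways, so the modified value never falls below the
plain one. Paralog families are disjoint within-species partitions.

The permutation null redraws the species-A module set from the pool of
module-associated A genes with the observed size spectrum (without
replacement within a module, genes reusable across modules, mirroring
real modules' overlap), records every B-module's maximal similarity,
and pools `n_reps × |B|` values; the 95 % quantile uses the empirical
distribution with linear interpolation. Under this construction the
fraction of null-drawn observed maxima exceeding the quantile
calibrates to 0.05; maxima within one replicate share a simulated
module set, so calibration tests use a binomial band with `n_eff = |B|`.

Hierarchical clustering of pooled modules uses average linkage on
`1 − similarity`; the tissue distribution counts modules per tissue,
optionally restricted to positively scored tissues.

## Expression coherence

Coherence is the mean Pearson correlation over all gene pairs computed
on the full tissue profile (not only module tissues). With rows
standardized, the pair mean reduces to `((‖Σ_i z_i‖²/T) − n)/(n(n−1))`,
which makes 10,000-set control ensembles cheap. Controls are gene sets
drawn without replacement from the full matrix universe with sizes
uniform in 20–50 (the seed-size range); fixed-size controls are
available. Zero-variance profiles are skipped and logged. The z-score
is `(observed − mean(control))/sd(control)`.

## Constraint quantities and Ka/Ks

For each gene in at least one module whose positive-score tissue set
is non-empty, six quantities are computed over its qualifying modules:
module count, interactors `|∪G_j \ {gene}|`, interactions
`Σ(|G_j|−1)`, tissues `|∪T_j|`, tissues repeated `Σ|T_j|`, and total
constraint intensity `Σ|G_j|·|T_j|` with `T_j` the positive tissues.
The focal gene is excluded from interactor/interaction counts
(neighbour semantics); genes with no qualifying module are excluded
rather than zero-filled. Correlations with Ka/Ks report Pearson r and
Spearman ρ (t-approximation p-values, average ranks for ties), after
removing genes with Ks ≥ 1 (synonymous saturation) and optionally the
largest-Ks genes as a robustness check; constant quantities are
flagged as degenerate instead of being reported.

## Synthetic data model

The generator emits log-scale matrices directly: i.i.d. Gaussian
background (mean 0, sd `noise_sd`) with planted blocks shifted by
±`signal_effect`. ISA standardizes everything, so the raw intensity
scale is immaterial and no microarray-summarization emulation is
attempted. Defaults, chosen once for realism: `noise_sd = 0.2`
(typical log10-scale background spread in MAS5-style atlas data) and
`signal_effect = 1.5` (≈30-fold tissue-specific induction), 29 named
homologous tissues, module sizes 10–63 genes over 1–6 tissues
(matching the observed range on real atlases), `suppression_fraction
= 0.2` with at least one up-regulated tissue per module, and 15 % of
genes in paralog families of 2–4. Planted gene sets may overlap by
default (modules on real data overlap); `disjoint_genes=True` plants
non-overlapping blocks for recovery benchmarks. Shared modules occupy
the same orthologous rows and homologous tissues in both species with
independent noise.

The Ka/Ks table follows
`ka_ks = kaks_baseline − kaks_slope · rank(TCI)/n + N(0, kaks_noise_sd)`,
clipped positive, with Ks uniform in (0.05, 0.95) so it honours the
saturation bound, and Ka = ka_ks·Ks. Defaults 0.4/0.3/0.05 keep
ratios in a plausible mammalian purifying-selection range while
giving the monotone dependence a clearly detectable effect size at a
few hundred genes.

What the generator does **not** emulate: probe-set structure and
replicate averaging, heavy-tailed or heteroscedastic array noise,
correlated backgrounds between tissues, expression-level-dependent
variance, or genuinely hierarchical module structure. Passing tests
therefore demonstrate correctness of the algorithms under a clean
block-plus-noise model, not performance on real atlas data.

## Problem sizes and determinism

Tests and examples run at desk scale: 400–1,000 genes, 29 tissues,
300–500 ISA seeds, 100–1,000 permutation replicates/control sets, and
5 sensitivity replicates — the same statistical structure as
atlas-scale runs (6,200 genes, 2,000 seeds, 1,000 replicates, 10,000
controls, 20 replicates) at a fraction of the cost; all counts are
parameters. Every stochastic component takes an explicit seed or
generator; the pipeline derives one seed per stage from the global
seed and stage name, making report bundles byte-reproducible.

## Known limitations

* The binary-membership ISA produces abundant tiny noise fixed points;
  a minimum module size (or stricter thresholds) is needed in practice.
* Similarity forms other than the gene-level one are pinned only by
  analogy (their exact algebra is isolated behind single functions and
  can be swapped).
* Whether a gene matched both by ortholog and by paralog should count
  once in the modified similarity is a convention; it counts once here.
* The permutation null conditions on the observed module sizes but not
  on per-gene participation frequencies.
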