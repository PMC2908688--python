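# transmod

Cross-species discovery and comparison of tissue-related transcription
modules in gene-expression atlases, for computational biologists who
want to ask how much of a genome's co-expression structure is conserved
between two species (e.g. human and mouse) and whether module
membership constrains a gene's rate of protein evolution.

## What it computes

A **transcription module** M(G, T) is a set of co-regulated genes G
together with the tissues T in which the co-regulation occurs, with a
signed score per tissue (positive = highly expressed, negative =
coherently suppressed). The pipeline:

1. **ISA discovery.** The iterative signature algorithm alternates
   between scoring tissues against a gene set and genes against the
   selected tissues on row-/column-standardized data, thresholding each
   score vector in sd units (tissue threshold `|s_t| > Tc·σ(s)`, gene
   threshold `s_i > mean(s) + Tg·σ(s)`; defaults Tc = 1.5, Tg = 3.0)
   until the gene set is a fixed point. Thousands of random seed sets
   of 20–50 genes make the search exhaustive.
2. **IGMM merging and refinement.** Module similarity at the gene
   level is `|G_i ∩ G_j| / √(|G_i||G_j|)` (tissue-level and combined
   analogues are available). A module relationship graph links pairs
   above 0.7; every maximal clique is merged, keeping genes/tissues
   present in ≥ 80 % of the clique (`⌈0.8k⌉` of k). Iterating to
   convergence and keeping only merged modules with 100 %
   min-cardinality similarity to some raw ISA module yields the
   refined post-merged (**RMP**) modules.
3. **Cross-species comparison.** All-vs-all gene-level similarity
   through a one-to-one orthology map; a **paralog-modified**
   similarity `((n_H + n_M)/2)/√(|G_H||G_M|)` where `n_H`, `n_M` count
   genes with an ortholog- or paralog-family-mediated counterpart in
   the opposite module; per-module maximal similarity with a
   permutation null (size-matched simulated modules drawn from the
   module-associated gene pool, empirical 95 % quantile).
4. **Expression coherence.** Mean pairwise Pearson correlation of a
   module's profiles across all tissues, as a z-score against random
   gene sets of sizes 20–50.
5. **Evolutionary constraint.** Six per-gene module-context
   quantities — number of modules, interactors, interactions, tissues,
   tissues (repeated) and the **total constraint intensity**
   `TCI = Σ_j |G_j|·|T_j|` over the gene's modules (positive-score
   tissues only) — correlated (Pearson and Spearman) with per-gene
   Ka/Ks, with guards against synonymous-site saturation.
6. **Robustness.** Leave-out sensitivity: remove 5–20 % of genes,
   rerun everything, and score the mean maximal similarity S to the
   full-data modules.

A first-class synthetic-data generator (`transmod.synth`) emulates the
whole input bundle — two species-matched log-scale matrices with
planted shared/specific modules, orthology and paralog maps, and a
Ka/Ks table with tunable negative dependence on planted constraint —
so every stage is testable without external data.

## Worked example

```bash
python examples/02_module_discovery.py
```

```
raw ISA fixed points: 3; refined (RMP) modules: 3
  human_raw_0: 33 genes, tissues ['amygdala', 'prostate', 'thyroid'], best similarity to planted truth = 1.000
  human_raw_1: 29 genes, tissues ['cd8_tcells', 'hypothalamus', 'lymph_node'], best similarity to planted truth = 1.000
  human_raw_2: 30 genes, tissues ['placenta', 'thyroid', 'trachea'], best similarity to planted truth = 1.000
A similarity of 1.0 means the recovered gene set equals the planted one.
```

Three modules planted in a 1,000-gene × 29-tissue synthetic atlas are
recovered exactly by the seed search. The cross-species example
(`examples/03_cross_species_comparison.py`) prints the worked
similarity pair — a 7-gene human module and an 8-gene mouse module
sharing 3 orthologs score 0.401 at the gene level, rising to 0.735
once 5 + 6 paralog-mediated matches are counted — and shows planted
orthologous pairs standing far above the permutation-null 95 %
quantile (0.467 on that data) while a species-specific module does
not. The other examples cover the generator, coherence z-scores
(planted modules ≈ 82, random sets ≈ 0), the constraint–Ka/Ks
correlation (Spearman ρ = −0.33, p = 0.002 on default synthetic data)
and the leave-out sensitivity curve (S: 1.00 → 0.89 as removal grows
to 20 %).

A thin CLI mirrors the library (`transmod synth | discover | merge |
compare | coherence | constraint | sensitivity | scan-thresholds |
run-all`); `run-all` executes the whole pipeline from a YAML config
and writes a JSON/TSV report bundle reproducible byte-for-byte from
its seed.

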