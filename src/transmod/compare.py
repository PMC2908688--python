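"""Cross-species module comparison.

All-vs-all gene-level similarity through the one-to-one orthology map, a
paralog-aware "modified" similarity, per-module maximal similarity, a
permutation null for the maximal similarity with its 95% quantile,
hierarchical clustering of pooled modules, and the tissue distribution of
a module set.

The modified similarity counts, on each side, the genes with an
ortholog- or paralog-mediated counterpart in the opposite module:
a gene h of module H matches when its ortholog lies in G_M, or when some
gene of G_M has an ortholog (in h's species) belonging to the same
paralog family as h.  With n_H and n_M the two matched counts, the value
is ((n_H + n_M)/2) / sqrt(|G_H| |G_M|).  A gene counts once even if
matched both ways, so the modified similarity is never below the plain
gene-level similarity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .core import (
    ConfigurationError,
    ModuleSet,
    OrthologyMap,
    ParalogMap,
    TranscriptionModule,
)
from .merge import sim_gene

__all__ = [
    "all_vs_all",
    "modified_similarity",
    "max_similarity",
    "permutation_null",
    "PermutationNullResult",
    "cluster_modules",
    "tissue_distribution",
]


def all_vs_all(a: ModuleSet, b: ModuleSet, orth: OrthologyMap) -> pd.DataFrame:
    """Gene-level similarity matrix between two module sets (rows: ``a``)."""
    if not len(a) or not len(b):
        raise ConfigurationError("all_vs_all requires non-empty module sets")
    out = np.empty((len(a), len(b)))
    for i, mi in enumerate(a.modules):
        for j, mj in enumerate(b.modules):
            out[i, j] = sim_gene(mi, mj, orth)
    return pd.DataFrame(out, index=a.module_ids, columns=b.module_ids)


def _matched_count(src: TranscriptionModule, dst: TranscriptionModule,
                   orth: OrthologyMap, para: ParalogMap) -> int:
    """Genes of ``src`` with an ortholog- or paralog-mediated match in ``dst``."""
    # Orthologs of the destination module expressed in the source species.
    dst_in_src_space = orth.translate(dst.genes, src.species)
    matched = 0
    for g in src.genes:
        if g in dst_in_src_space:
            matched += 1
            continue
        fam = para.family(g)
        if fam is not None and any(para.family(x) == fam for x in dst_in_src_space):
            matched += 1
    return matched


def modified_similarity(h: TranscriptionModule, m: TranscriptionModule,
                        orth: OrthologyMap, para: ParalogMap) -> float:
    """Paralog-aware cross-species similarity (see module docstring)."""
    if not h.genes or not m.genes:
        raise ConfigurationError("empty gene set")
    n_h = _matched_count(h, m, orth, para)
    n_m = _matched_count(m, h, orth, para)
    return ((n_h + n_m) / 2.0) / np.sqrt(len(h.genes) * len(m.genes))


def max_similarity(b: ModuleSet, a: ModuleSet, orth: OrthologyMap) -> pd.Series:
    """For each module of ``b``, its maximal gene-level similarity over ``a``."""
    sim = all_vs_all(b, a, orth)
    return sim.max(axis=1)


@dataclass
class PermutationNullResult:
    """Null distribution of per-module maximal similarity.

    ``null_values`` pools n_reps x n_b maxima from simulated module sets;
    ``q95`` is their empirical 95% quantile (linear interpolation);
    ``exceed_fraction`` is the share of observed maxima above ``q95``
    (``None`` when no observed values were supplied).
    """

    null_values: np.ndarray
    q95: float
    exceed_fraction: float | None
    n_reps: int


def permutation_null(
    b: ModuleSet,
    a_gene_pool: list[str] | np.ndarray,
    a_sizes: list[int],
    orth: OrthologyMap,
    n_reps: int = 1000,
    rng: np.random.Generator | int | None = None,
    observed_max: np.ndarray | pd.Series | None = None,
) -> PermutationNullResult:
    """Permutation null for the per-module maximal cross-species similarity.

    Each replicate draws ``len(a_sizes)`` simulated species-A modules from
    ``a_gene_pool`` (without replacement within a module, genes reusable
    across modules) with the observed size spectrum, and records the
    maximal similarity of every module of ``b`` against them.  Pools
    ``n_reps * len(b)`` values.
    """
    rng = np.random.default_rng(rng)
    pool = np.asarray(a_gene_pool, dtype=object)
    if len(pool) < max(a_sizes):
        raise ConfigurationError("gene pool smaller than the largest requested module")
    if not len(b):
        raise ConfigurationError("empty module set")
    # Map B gene sets into species-A id space once.
    b_sets = [orth.translate(m.genes, orth.species_a) if m.species != orth.species_a
              else m.genes for m in b.modules]
    b_sizes = np.array([len(m.genes) for m in b.modules], dtype=float)

    null = np.empty((n_reps, len(b_sets)))
    for rep in range(n_reps):
        sim_modules = [frozenset(rng.choice(pool, size=s, replace=False))
                       for s in a_sizes]
        for i, (bs, bn) in enumerate(zip(b_sets, b_sizes)):
            best = 0.0
            for sm in sim_modules:
                v = len(bs & sm) / np.sqrt(bn * len(sm))
                if v > best:
                    best = v
            null[rep, i] = best
    null = null.ravel()
    q95 = float(np.quantile(null, 0.95))
    exceed = None
    if observed_max is not None:
        obs = np.asarray(observed_max, dtype=float)
        exceed = float(np.mean(obs > q95))
    return PermutationNullResult(null_values=null, q95=q95,
                                 exceed_fraction=exceed, n_reps=n_reps)


def cluster_modules(modules: list[TranscriptionModule], orth: OrthologyMap):
    """Average-linkage hierarchical clustering of pooled modules.

    Distance is 1 - gene-level similarity, computed through the orthology
    map for cross-species pairs.  Returns ``(linkage_matrix, module_ids,
    species_labels)``; a single module yields an empty linkage.
    """
    ids = [m.module_id for m in modules]
    species = [m.species for m in modules]
    n = len(modules)
    if n == 0:
        raise ConfigurationError("no modules to cluster")
    if n == 1:
        return np.empty((0, 4)), ids, species
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            orth_arg = orth if modules[i].species != modules[j].species else None
            d = 1.0 - sim_gene(modules[i], modules[j], orth_arg)
            dist[i, j] = dist[j, i] = d
    z = linkage(squareform(dist, checks=False), method="average")
    return z, ids, species


def tissue_distribution(ms: ModuleSet, tissue_ids: list[str] | None = None,
                        positive_only: bool = False) -> pd.Series:
    """Number of modules whose tissue set contains each tissue.

    With ``positive_only`` only positively scored tissues are counted.
    ``tissue_ids`` fixes the index (tissues absent from every module get
    count 0); otherwise the union of module tissues is used.
    """
    counts: dict[str, int] = {t: 0 for t in (tissue_ids or [])}
    for m in ms.modules:
        tset = m.positive_tissues if positive_only else m.tissues
        for t in tset:
            counts[t] = counts.get(t, 0) + 1
    index = tissue_ids if tissue_ids is not None else sorted(counts)
    return pd.Series([counts.get(t, 0) for t in index], index=index,
                     name="n_modules", dtype=int)
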