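"""Iterative signature algorithm (ISA) for transcription-module discovery.

ISA alternates between scoring tissues against a current gene set and
scoring genes against the selected tissues, thresholding each score
vector in standard-deviation units, until the gene set reaches a fixed
point.  The variant implemented here is binary-membership: after every
scoring step the scores are thresholded to a set, so a module is a
self-consistent pair of a gene set and a signed tissue set.

Update rules (all standard deviations are population-convention):

* tissue score  ``s_t = mean over current genes of col_normalized[., t]``;
  a tissue is selected when ``|s_t| > Tc * sd(s)``, and its sign is kept;
* gene score    ``s_i = mean over selected tissues of sign(s_t) * row_normalized[i, t]``;
  a gene is selected when ``s_i > mean(s) + Tg * sd(s)``.

A seed whose iteration empties either set, exceeds ``max_iter``, or
enters a limit cycle is dissolved (returns ``None``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .core import (
    ConfigurationError,
    ExpressionMatrix,
    ModuleSet,
    OrthologyMap,
    TranscriptionModule,
)

__all__ = [
    "IsaParams",
    "NormalizedPair",
    "normalize",
    "isa_iterate",
    "discover",
    "cross_seed",
    "scan_thresholds",
]

logger = logging.getLogger(__name__)


@dataclass
class IsaParams:
    """Thresholds and search parameters for ISA.

    ``tg``/``tc`` are the gene and condition thresholds in sd units of the
    respective score vectors.  Seeds are random gene sets with sizes drawn
    uniformly from ``seed_size_range``.
    """

    tg: float = 3.0
    tc: float = 1.5
    max_iter: int = 100
    seed_size_range: tuple[int, int] = (20, 50)
    n_seeds: int = 2000
    rng_seed: int = 0
    min_module_genes: int = 2
    cycle_window: int = 10

    def validate(self, n_genes: int | None = None) -> None:
        if self.tg <= 0 or self.tc <= 0:
            raise ConfigurationError("thresholds Tg and Tc must be positive")
        lo, hi = self.seed_size_range
        if lo < 2 or lo > hi:
            raise ConfigurationError("seed_size_range must satisfy 2 <= lo <= hi")
        if n_genes is not None and hi > n_genes:
            raise ConfigurationError("seed size exceeds number of genes")
        if self.max_iter < 1 or self.n_seeds < 0:
            raise ConfigurationError("max_iter must be >= 1 and n_seeds >= 0")


@dataclass
class NormalizedPair:
    """Row- and column-standardized views of one expression matrix.

    ``row_norm`` standardizes each gene across tissues (used for gene
    scores); ``col_norm`` standardizes each tissue across genes (used for
    tissue scores).  Zero-variance rows/columns are set to all zeros and
    logged — they can never pass a threshold.
    """

    gene_ids: list[str]
    tissue_ids: list[str]
    row_norm: np.ndarray
    col_norm: np.ndarray
    species: str
    gene_index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.gene_index:
            self.gene_index = {g: i for i, g in enumerate(self.gene_ids)}


def _standardize(x: np.ndarray, axis: int, what: str) -> np.ndarray:
    mean = x.mean(axis=axis, keepdims=True)
    sd = x.std(axis=axis, keepdims=True)
    flat = (sd == 0)
    if flat.any():
        logger.warning("%d zero-variance %s set to zeros during normalization",
                       int(flat.sum()), what)
    sd = np.where(flat, 1.0, sd)
    out = (x - mean) / sd
    return np.where(np.broadcast_to(flat, out.shape), 0.0, out)


def normalize(E: ExpressionMatrix) -> NormalizedPair:
    """Standardize an expression matrix by rows (genes) and by columns (tissues)."""
    if E.n_genes < 2 or E.n_tissues < 2:
        raise ConfigurationError("expression matrix needs at least 2 genes and 2 tissues")
    x = E.values
    return NormalizedPair(
        gene_ids=E.gene_ids,
        tissue_ids=E.tissue_ids,
        row_norm=_standardize(x, axis=1, what="gene rows"),
        col_norm=_standardize(x, axis=0, what="tissue columns"),
        species=E.species,
    )


def _select_tissues(s_t: np.ndarray, tc: float) -> np.ndarray:
    """Boolean mask of tissues with |score| above tc sd-units of the score vector."""
    return np.abs(s_t) > tc * s_t.std()


def _select_genes(s_g: np.ndarray, tg: float) -> np.ndarray:
    """Boolean mask of genes scoring above mean + tg sd-units of the score vector."""
    return s_g > s_g.mean() + tg * s_g.std()


def _scores_for_genes(gene_mask: np.ndarray, N: NormalizedPair, p: IsaParams):
    """One ISA half-sweep: tissue scores/selection from a gene set, then gene scores."""
    s_t = N.col_norm[gene_mask].mean(axis=0)
    tissue_mask = _select_tissues(s_t, p.tc)
    if not tissue_mask.any():
        return None
    signs = np.sign(s_t[tissue_mask])
    s_g = (N.row_norm[:, tissue_mask] * signs).mean(axis=1)
    return s_t, tissue_mask, s_g


def isa_iterate(
    seed_genes: Iterable[str],
    N: NormalizedPair,
    p: IsaParams,
    module_id: str = "module",
    provenance: dict | None = None,
) -> TranscriptionModule | None:
    """Run ISA from a seed gene set to a fixed point.

    Returns the fixed-point module, or ``None`` when the seed dissolves
    (empty selection, limit cycle, too few genes, or no convergence
    within ``max_iter``).
    """
    seed = [g for g in seed_genes]
    if not seed:
        raise ConfigurationError("empty seed gene set")
    try:
        idx = [N.gene_index[g] for g in seed]
    except KeyError as e:
        raise ConfigurationError(f"seed gene {e.args[0]!r} not in matrix") from e

    n = len(N.gene_ids)
    mask = np.zeros(n, dtype=bool)
    mask[idx] = True

    history: list[bytes] = []
    for _ in range(p.max_iter):
        step = _scores_for_genes(mask, N, p)
        if step is None:
            return None
        _, _, s_g = step
        new_mask = _select_genes(s_g, p.tg)
        if not new_mask.any():
            return None
        if np.array_equal(new_mask, mask):
            return _finalize(mask, N, p, module_id, provenance)
        key = new_mask.tobytes()
        if key in history:  # limit cycle
            return None
        history.append(key)
        if len(history) > p.cycle_window:
            history.pop(0)
        mask = new_mask
    return None


def _finalize(
    mask: np.ndarray,
    N: NormalizedPair,
    p: IsaParams,
    module_id: str,
    provenance: dict | None,
) -> TranscriptionModule | None:
    if mask.sum() < p.min_module_genes:
        return None
    step = _scores_for_genes(mask, N, p)
    if step is None:  # cannot happen at a fixed point, defensive
        return None
    s_t, tissue_mask, s_g = step
    gene_ids = np.asarray(N.gene_ids, dtype=object)
    tissue_ids = np.asarray(N.tissue_ids, dtype=object)
    prov = dict(provenance or {})
    prov.setdefault("tg", p.tg)
    prov.setdefault("tc", p.tc)
    return TranscriptionModule(
        module_id=module_id,
        species=N.species,
        gene_scores={g: float(s) for g, s in zip(gene_ids[mask], s_g[mask])},
        tissue_scores={t: float(s) for t, s in zip(tissue_ids[tissue_mask], s_t[tissue_mask])},
        provenance=prov,
    )


def discover(E: ExpressionMatrix | NormalizedPair, p: IsaParams) -> ModuleSet:
    """Exhaustive random-seed search: run ISA from ``n_seeds`` random seeds.

    Converged fixed points are deduplicated on identical gene sets
    (gene-level similarity exactly 1).  Fully reproducible from
    ``p.rng_seed``.
    """
    N = normalize(E) if isinstance(E, ExpressionMatrix) else E
    p.validate(n_genes=len(N.gene_ids))
    rng = np.random.default_rng(p.rng_seed)
    lo, hi = p.seed_size_range
    gene_ids = N.gene_ids
    seen: set[frozenset[str]] = set()
    modules: list[TranscriptionModule] = []
    for k in range(p.n_seeds):
        size = int(rng.integers(lo, hi + 1))
        seed = [gene_ids[i] for i in rng.choice(len(gene_ids), size=size, replace=False)]
        mod = isa_iterate(seed, N, p, module_id=f"{N.species}_raw_{len(modules)}",
                          provenance={"seed_index": k, "seed_size": size})
        if mod is None:
            continue
        if mod.genes in seen:
            continue
        seen.add(mod.genes)
        modules.append(mod)
    return ModuleSet(modules, species=N.species, stage="raw")


def cross_seed(
    module: TranscriptionModule,
    orth: OrthologyMap,
    E_other: ExpressionMatrix | NormalizedPair,
    p: IsaParams,
) -> TranscriptionModule | None:
    """Seed ISA in the other species with a module's orthologs.

    Maps the module's gene set through the one-to-one orthology map and
    iterates in the other species' matrix; returns the fixed point there
    or ``None`` if the seed dissolves.
    """
    N = normalize(E_other) if isinstance(E_other, ExpressionMatrix) else E_other
    mapped = orth.translate(module.genes, N.species)
    mapped = frozenset(g for g in mapped if g in N.gene_index)
    if not mapped:
        raise ConfigurationError(
            f"module {module.module_id!r} has no orthologs in species {N.species!r}"
        )
    return isa_iterate(
        sorted(mapped), N, p,
        module_id=f"{module.module_id}_xs_{N.species}",
        provenance={"cross_seeded_from": module.module_id},
    )


def scan_thresholds(
    E: ExpressionMatrix,
    tc_grid: Sequence[float],
    tg_grid: Sequence[float],
    p: IsaParams,
    merge_threshold: float = 0.7,
    membership: float = 0.8,
):
    """Count RMP modules over a (Tc, Tg) grid.

    For every grid point runs the full discover -> merge -> refine chain
    and records the number of refined modules.  Returns a DataFrame with
    columns ``tc``, ``tg``, ``n_raw``, ``n_rmp``.
    """
    import pandas as pd

    from .merge import igmm, refine

    N = normalize(E)
    rows = []
    for tc in tc_grid:
        for tg in tg_grid:
            params = replace(p, tc=float(tc), tg=float(tg))
            raw = discover(N, params)
            if len(raw):
                rmp = refine(igmm(raw, threshold=merge_threshold, membership=membership), raw)
            else:
                rmp = ModuleSet([], species=E.species, stage="refined")
            rows.append({"tc": float(tc), "tg": float(tg),
                         "n_raw": len(raw), "n_rmp": len(rmp)})
    return pd.DataFrame(rows, columns=["tc", "tg", "n_raw", "n_rmp"])
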