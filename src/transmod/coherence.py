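"""Expression coherence of modules.

Coherence of a module is the mean Pearson correlation over all gene
pairs, computed on the full tissue profile (all shared tissues, not only
the module's own tissues).  Significance is a z-score against random
gene sets sampled from the matrix's gene universe with sizes drawn
uniformly from the ISA seed-size range (20-50 by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .core import ConfigurationError, ExpressionMatrix, TranscriptionModule

__all__ = ["CoherenceResult", "mean_pcc", "coherence_z"]

logger = logging.getLogger(__name__)


@dataclass
class CoherenceResult:
    module_id: str
    mean_pcc: float
    z: float
    control_mean: float
    control_sd: float
    n_random: int
    size_range: tuple[int, int] | int


def _standardized_rows(E: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Population-standardized rows plus a mask of zero-variance genes."""
    x = E.values
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    flat = (sd == 0).ravel()
    sd = np.where(sd == 0, 1.0, sd)
    return (x - mu) / sd, flat


def _mean_pairwise_pcc(z_rows: np.ndarray) -> float:
    """Mean pairwise Pearson correlation of standardized rows.

    With rows standardized to mean 0, sd 1 over T tissues, r_ij is the
    scaled dot product, so the pair mean reduces to a single column sum:
    mean r = (||sum_i z_i||^2 / T - n) / (n (n - 1)).
    """
    n, t = z_rows.shape
    s = z_rows.sum(axis=0)
    return float((s @ s / t - n) / (n * (n - 1)))


def mean_pcc(module: TranscriptionModule | Iterable[str], E: ExpressionMatrix) -> float:
    """Mean pairwise Pearson correlation of a module's expression profiles.

    Zero-variance gene profiles are skipped (their pairs are undefined)
    and logged.  Raises if fewer than two usable genes remain.
    """
    genes = module.genes if isinstance(module, TranscriptionModule) else set(module)
    idx = [i for i, g in enumerate(E.gene_ids) if g in genes]
    if len(idx) < 2:
        raise ConfigurationError("mean_pcc needs at least two genes present in the matrix")
    z, flat = _standardized_rows(E)
    keep = [i for i in idx if not flat[i]]
    if len(keep) < len(idx):
        logger.warning("mean_pcc: skipped %d zero-variance gene profiles",
                       len(idx) - len(keep))
    if len(keep) < 2:
        raise ConfigurationError("fewer than two genes with non-constant profiles")
    return _mean_pairwise_pcc(z[keep])


def _control_mean_pccs(z: np.ndarray, sizes: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
    """Mean pairwise PCC of random gene sets with the given sizes."""
    n_genes, t = z.shape
    out = np.empty(len(sizes))
    for k, size in enumerate(sizes):
        idx = rng.choice(n_genes, size=int(size), replace=False)
        out[k] = _mean_pairwise_pcc(z[idx])
    return out


def coherence_z(
    module: TranscriptionModule,
    E: ExpressionMatrix,
    n_random: int = 10000,
    size_rule: tuple[int, int] | int = (20, 50),
    rng: np.random.Generator | int | None = None,
) -> CoherenceResult:
    """Coherence z-score of a module against random size-matched gene sets.

    ``z = (mean_pcc(module) - mean(control)) / sd(control)`` where the
    control ensemble holds ``n_random`` gene sets drawn without
    replacement (within a set) from the full gene universe.  ``size_rule``
    is either a ``(lo, hi)`` interval for variable sizes (the default,
    uniform in 20-50) or a fixed integer size.
    """
    rng = np.random.default_rng(rng)
    observed = mean_pcc(module, E)
    z, flat = _standardized_rows(E)
    if flat.any():
        z = z[~flat]
    if isinstance(size_rule, int):
        sizes = np.full(n_random, size_rule)
    else:
        lo, hi = size_rule
        sizes = rng.integers(lo, hi + 1, size=n_random)
    control = _control_mean_pccs(z, sizes, rng)
    mu, sd = float(control.mean()), float(control.std())
    if sd == 0:
        raise ConfigurationError("degenerate control ensemble (zero sd)")
    return CoherenceResult(
        module_id=module.module_id,
        mean_pcc=observed,
        z=(observed - mu) / sd,
        control_mean=mu,
        control_sd=sd,
        n_random=n_random,
        size_range=size_rule if isinstance(size_rule, int) else tuple(size_rule),
    )
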