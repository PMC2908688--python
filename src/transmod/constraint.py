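"""Module-context characteristic quantities and their relation to Ka/Ks.

For a gene participating in n qualifying modules M_1(G_1, T_1) ...
M_n(G_n, T_n) — where T_j is the module's positively scored tissue set
and a module qualifies only when T_j is non-empty — six quantities are
defined:

* number of modules            ``n``
* number of interactors        ``|union_j G_j  \\  {gene}|``
* number of interactions       ``sum_j (|G_j| - 1)``
* number of tissues            ``|union_j T_j|``
* number of tissues (repeated) ``sum_j |T_j|``
* total constraint intensity   ``sum_j |G_j| * |T_j|``

Total constraint intensity (TCI) sums, over a gene's modules, the
product of gene-set and tissue-set size — a proxy for the multiple
constraints (co-regulated partners and the tissues where co-regulation
occurs) acting on the gene.  The focal gene is excluded from the
interactor/interaction counts (neighbour semantics).

``correlate`` joins the quantities with a per-gene Ka/Ks table and
reports Pearson and Spearman correlations of the evolutionary rate with
each quantity, optionally guarding against synonymous-site saturation by
excluding high-Ks genes.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy import stats

from .core import ConfigurationError, ModuleSet

__all__ = [
    "CharacteristicQuantities",
    "QUANTITY_NAMES",
    "quantities",
    "quantities_table",
    "correlate",
]

QUANTITY_NAMES = [
    "n_modules",
    "n_interactors",
    "n_interactions",
    "n_tissues",
    "n_tissues_repeated",
    "total_constraint_intensity",
]


@dataclass
class CharacteristicQuantities:
    gene_id: str
    n_modules: int
    n_interactors: int
    n_interactions: int
    n_tissues: int
    n_tissues_repeated: int
    total_constraint_intensity: int


def _qualifying(gene: str, ms: ModuleSet):
    return [m for m in ms.modules
            if gene in m.genes and len(m.positive_tissues) > 0]


def quantities(gene: str, ms: ModuleSet) -> CharacteristicQuantities:
    """The six module-context quantities for one gene.

    Raises when the gene occurs in no qualifying module (a module counts
    only if its positive-score tissue set is non-empty); such genes are
    excluded from the analysis rather than zero-filled.
    """
    mods = _qualifying(gene, ms)
    if not mods:
        raise ConfigurationError(
            f"gene {gene!r} is in no module with a non-empty positive tissue set"
        )
    gene_union: set[str] = set()
    tissue_union: set[str] = set()
    n_interactions = 0
    n_tissues_repeated = 0
    tci = 0
    for m in mods:
        g, t = m.genes, m.positive_tissues
        gene_union |= g
        tissue_union |= t
        n_interactions += len(g) - 1
        n_tissues_repeated += len(t)
        tci += len(g) * len(t)
    return CharacteristicQuantities(
        gene_id=gene,
        n_modules=len(mods),
        n_interactors=len(gene_union - {gene}),
        n_interactions=n_interactions,
        n_tissues=len(tissue_union),
        n_tissues_repeated=n_tissues_repeated,
        total_constraint_intensity=tci,
    )


def quantities_table(ms: ModuleSet) -> pd.DataFrame:
    """Quantities for every module-associated gene, indexed by gene id.

    Only genes with at least one qualifying module appear.
    """
    rows = []
    seen: set[str] = set()
    for m in ms.modules:
        if not m.positive_tissues:
            continue
        for g in sorted(m.genes):
            if g in seen:
                continue
            seen.add(g)
            rows.append(quantities(g, ms))
    if not rows:
        return pd.DataFrame(columns=QUANTITY_NAMES)
    df = pd.DataFrame([{f.name: getattr(r, f.name) for f in fields(r)} for r in rows])
    return df.set_index("gene_id").sort_index()


def correlate(
    table: pd.DataFrame,
    kaks: pd.DataFrame,
    ks_max: float = 1.0,
    drop_top_ks: int = 0,
) -> pd.DataFrame:
    """Correlate Ka/Ks with each characteristic quantity.

    ``table`` is the output of :func:`quantities_table`; ``kaks`` must be
    indexed by gene id with columns ``ka``, ``ks`` and ``ka_ks``.  Genes
    with ``ks >= ks_max`` are excluded, and optionally the
    ``drop_top_ks`` genes with the largest Ks (a saturation robustness
    check).  Returns one row per quantity with Pearson r, Spearman rho
    (t-approximation p-values, average ranks for ties) and the joined n.
    Quantities with degenerate variance are flagged with NaN statistics.
    """
    joined = table.join(kaks, how="inner")
    joined = joined[joined["ks"] < ks_max]
    if drop_top_ks > 0:
        joined = joined.drop(joined["ks"].nlargest(drop_top_ks).index)
    if len(joined) < 10:
        raise ConfigurationError(
            f"only {len(joined)} genes joined with Ka/Ks data; need >= 10"
        )
    rate = joined["ka_ks"].to_numpy(dtype=float)
    rows = []
    for q in QUANTITY_NAMES:
        x = joined[q].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(rate) == 0:
            rows.append({"quantity": q, "pearson_r": np.nan, "pearson_p": np.nan,
                         "spearman_rho": np.nan, "spearman_p": np.nan,
                         "n": len(joined), "degenerate": True})
            continue
        pr = stats.pearsonr(x, rate)
        sr = stats.spearmanr(x, rate)
        rows.append({"quantity": q,
                     "pearson_r": float(pr.statistic), "pearson_p": float(pr.pvalue),
                     "spearman_rho": float(sr.statistic), "spearman_p": float(sr.pvalue),
                     "n": len(joined), "degenerate": False})
    return pd.DataFrame(rows).set_index("quantity")
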