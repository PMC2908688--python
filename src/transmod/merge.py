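"""Module similarity measures and iterative graph-based module merging (IGMM).

Similarity between two modules M_i(G_i, T_i) and M_j(G_j, T_j) is defined
at three levels, each normalized by the geometric mean of the two set
sizes:

* gene level        ``|G_i & G_j| / sqrt(|G_i| |G_j|)``
* tissue level      ``|T_i & T_j| / sqrt(|T_i| |T_j|)``
* combined          ``(|G_i & G_j| + |T_i & T_j|) / sqrt((|G_i|+|T_i|)(|G_j|+|T_j|))``

The min-cardinality variants replace the denominator by the minimum of
the two cardinalities, so a value of 1 means the smaller set is nested in
the larger.  For cross-species pairs the intersection is counted through
the one-to-one orthology map.

IGMM builds a module relationship graph (MRG: nodes are modules, edges
link pairs with similarity above a threshold, 0.7 by default), merges
every maximal clique under an 80%-membership rule, and repeats until the
module set no longer changes.  Refinement then keeps only merged modules
that retain 100% min-cardinality similarity to some raw ISA module.
"""

from __future__ import annotations

import logging
import math
from itertools import combinations
from typing import Sequence

import networkx as nx

from .core import (
    ConfigurationError,
    ModuleSet,
    OrthologyMap,
    TranscriptionModule,
)

__all__ = [
    "sim_gene",
    "sim_tissue",
    "sim_combined",
    "sim_min_gene",
    "sim_min_tissue",
    "sim_min_combined",
    "build_mrg",
    "merge_clique",
    "igmm",
    "refine",
]

logger = logging.getLogger(__name__)


def _gene_overlap(mi: TranscriptionModule, mj: TranscriptionModule,
                  orth: OrthologyMap | None) -> int:
    if mi.species == mj.species:
        return len(mi.genes & mj.genes)
    if orth is None:
        raise ConfigurationError(
            "orthology map required for cross-species module similarity"
        )
    return len(orth.translate(mi.genes, mj.species) & mj.genes)


def _tissue_overlap(mi: TranscriptionModule, mj: TranscriptionModule) -> int:
    # Tissues are homologous across species, so ids compare directly.
    return len(mi.tissues & mj.tissues)


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigurationError(msg)


def sim_gene(mi: TranscriptionModule, mj: TranscriptionModule,
             orth: OrthologyMap | None = None) -> float:
    """Gene-level similarity: shared genes over the geometric mean of sizes."""
    _require(len(mi.genes) > 0 and len(mj.genes) > 0, "empty gene set")
    return _gene_overlap(mi, mj, orth) / math.sqrt(len(mi.genes) * len(mj.genes))


def sim_tissue(mi: TranscriptionModule, mj: TranscriptionModule) -> float:
    """Tissue-level similarity: shared tissues over the geometric mean of sizes."""
    _require(len(mi.tissues) > 0 and len(mj.tissues) > 0, "empty tissue set")
    return _tissue_overlap(mi, mj) / math.sqrt(len(mi.tissues) * len(mj.tissues))


def sim_combined(mi: TranscriptionModule, mj: TranscriptionModule,
                 orth: OrthologyMap | None = None) -> float:
    """Combined similarity over genes and tissues jointly."""
    _require(len(mi.genes) > 0 and len(mj.genes) > 0, "empty gene set")
    _require(len(mi.tissues) > 0 and len(mj.tissues) > 0, "empty tissue set")
    num = _gene_overlap(mi, mj, orth) + _tissue_overlap(mi, mj)
    den = math.sqrt((len(mi.genes) + len(mi.tissues)) * (len(mj.genes) + len(mj.tissues)))
    return num / den


def sim_min_gene(mi: TranscriptionModule, mj: TranscriptionModule,
                 orth: OrthologyMap | None = None) -> float:
    """Gene-level similarity with min-cardinality denominator (1 iff nested)."""
    _require(len(mi.genes) > 0 and len(mj.genes) > 0, "empty gene set")
    return _gene_overlap(mi, mj, orth) / min(len(mi.genes), len(mj.genes))


def sim_min_tissue(mi: TranscriptionModule, mj: TranscriptionModule) -> float:
    """Tissue-level similarity with min-cardinality denominator."""
    _require(len(mi.tissues) > 0 and len(mj.tissues) > 0, "empty tissue set")
    return _tissue_overlap(mi, mj) / min(len(mi.tissues), len(mj.tissues))


def sim_min_combined(mi: TranscriptionModule, mj: TranscriptionModule,
                     orth: OrthologyMap | None = None) -> float:
    """Combined similarity with min of summed cardinalities as denominator."""
    _require(len(mi.genes) > 0 and len(mj.genes) > 0, "empty gene set")
    _require(len(mi.tissues) > 0 and len(mj.tissues) > 0, "empty tissue set")
    num = _gene_overlap(mi, mj, orth) + _tissue_overlap(mi, mj)
    den = min(len(mi.genes) + len(mi.tissues), len(mj.genes) + len(mj.tissues))
    return num / den


_SIM_LEVELS = {
    "gene": sim_gene,
    "tissue": lambda mi, mj, orth=None: sim_tissue(mi, mj),
    "combined": sim_combined,
}


def build_mrg(ms: ModuleSet, threshold: float = 0.7,
              level: str = "gene") -> nx.Graph:
    """Build the module relationship graph at a similarity threshold.

    Nodes are module ids; an undirected edge links two modules whose
    similarity (gene level by default) exceeds ``threshold``.
    """
    if level not in _SIM_LEVELS:
        raise ConfigurationError(f"unknown similarity level {level!r}")
    sim = _SIM_LEVELS[level]
    g = nx.Graph()
    g.add_nodes_from(ms.module_ids)
    for mi, mj in combinations(ms.modules, 2):
        s = sim(mi, mj)
        if s > threshold:
            g.add_edge(mi.module_id, mj.module_id, similarity=s)
    return g


def merge_clique(modules: Sequence[TranscriptionModule], membership: float = 0.8,
                 module_id: str | None = None) -> TranscriptionModule | None:
    """Coalesce a clique of modules into one united module.

    A gene or tissue is retained when it occurs in at least
    ``ceil(membership * k)`` of the ``k`` inputs ("no less than 80%").
    Scores of retained items are averaged over the parents carrying them.
    Returns ``None`` (and logs) when the retained gene set is empty.
    """
    k = len(modules)
    if k < 2:
        raise ConfigurationError("merge_clique needs at least two modules")
    species = modules[0].species
    _require(all(m.species == species for m in modules),
             "cannot merge modules from different species")
    need = math.ceil(membership * k)

    def united(items_of):
        counts: dict[str, list[float]] = {}
        for m in modules:
            for item, score in items_of(m).items():
                counts.setdefault(item, []).append(score)
        return {item: sum(ss) / len(ss) for item, ss in counts.items() if len(ss) >= need}

    genes = united(lambda m: m.gene_scores)
    if not genes:
        logger.warning("merged module from %s dissolved: empty gene set",
                       [m.module_id for m in modules])
        return None
    tissues = united(lambda m: m.tissue_scores)
    return TranscriptionModule(
        module_id=module_id or "+".join(sorted(m.module_id for m in modules)),
        species=species,
        gene_scores=genes,
        tissue_scores=tissues,
        provenance={"merged_from": sorted(m.module_id for m in modules),
                    "membership": membership},
    )


def igmm(ms: ModuleSet, threshold: float = 0.7, membership: float = 0.8,
         level: str = "gene") -> ModuleSet:
    """Iterative graph-based module merging, run to convergence.

    Each round: build the MRG, enumerate maximal cliques, merge every
    clique of size >= 2 under the membership rule, replace the clique
    members by the merged module, and repeat until the module set stops
    changing.  Overlapping cliques are processed in decreasing size
    (lexicographic tie-break on member ids); a module consumed by an
    earlier clique this round is dropped from later ones — any remaining
    overlap resolves in subsequent rounds.
    """
    current = list(ms.modules)
    round_no = 0
    while True:
        round_no += 1
        mrg = build_mrg(ModuleSet(current, ms.species, stage="merging"),
                        threshold=threshold, level=level)
        cliques = [sorted(c) for c in nx.find_cliques(mrg) if len(c) >= 2]
        if not cliques:
            break
        cliques.sort(key=lambda c: (-len(c), c))
        by_id = {m.module_id: m for m in current}
        consumed: set[str] = set()
        merged_out: list[TranscriptionModule] = []
        changed = False
        for clique in cliques:
            alive = [mid for mid in clique if mid not in consumed]
            if len(alive) < 2:
                continue
            merged = merge_clique([by_id[mid] for mid in alive], membership=membership,
                                  module_id=f"{ms.species}_mrg{round_no}_{len(merged_out)}")
            consumed.update(alive)
            if merged is not None:
                merged_out.append(merged)
            changed = True
        if not changed:
            break
        survivors = [m for m in current if m.module_id not in consumed]
        new_set = survivors + merged_out
        if [m.content_key() for m in new_set] == [m.content_key() for m in current]:
            break
        current = new_set
    return ModuleSet(current, species=ms.species, stage="merged")


def refine(merged: ModuleSet, raw: ModuleSet,
           mode: str = "gene_and_tissue") -> ModuleSet:
    """Keep merged modules fully consistent with some raw ISA module.

    A post-merged module is retained when a raw module attains
    min-cardinality similarity 1 against it — on both the gene and tissue
    level (default), or on the combined level with ``mode="combined"``.
    The survivors are the refined post-merged (RMP) modules.
    """
    if mode not in {"gene_and_tissue", "combined"}:
        raise ConfigurationError(f"unknown refine mode {mode!r}")
    eps = 1e-12
    kept = []
    for m in merged.modules:
        for r in raw.modules:
            if mode == "gene_and_tissue":
                if (m.tissues and r.tissues
                        and sim_min_gene(m, r) >= 1 - eps
                        and sim_min_tissue(m, r) >= 1 - eps):
                    kept.append(m)
                    break
            else:
                if m.tissues and r.tissues and sim_min_combined(m, r) >= 1 - eps:
                    kept.append(m)
                    break
    return ModuleSet(kept, species=merged.species, stage="refined")
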