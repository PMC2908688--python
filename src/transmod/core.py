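"""Core data containers shared by every analysis stage.

The central object is the transcription module M(G, T): a set of
co-regulated genes G together with the tissues T in which the
co-regulation occurs.  Tissue membership is signed — a positive score
marks a tissue where the module is highly expressed, a negative score a
tissue where it is coherently suppressed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "TransmodError",
    "ConfigurationError",
    "ParseError",
    "ExpressionMatrix",
    "TranscriptionModule",
    "ModuleSet",
    "OrthologyMap",
    "ParalogMap",
]


class TransmodError(Exception):
    """Base class for errors raised by transmod."""


class ConfigurationError(TransmodError):
    """Invalid parameter set or inconsistent configuration."""


class ParseError(TransmodError):
    """Malformed input file."""


@dataclass
class ExpressionMatrix:
    """A genes x tissues matrix of log-scale expression values for one species.

    Parameters
    ----------
    data
        DataFrame indexed by gene id with one column per tissue.  Values
        are log-scale signal intensities; no missing entries are allowed.
    species
        Species label, e.g. ``"human"``.
    """

    data: pd.DataFrame
    species: str

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ConfigurationError("duplicate gene ids in expression matrix")
        if self.data.columns.has_duplicates:
            raise ConfigurationError("duplicate tissue ids in expression matrix")
        if self.data.isna().any().any():
            bad = self.data.isna().stack()
            gene, tissue = bad[bad].index[0]
            raise ConfigurationError(
                f"missing expression value at gene {gene!r}, tissue {tissue!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def tissue_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_tissues(self) -> int:
        return self.data.shape[1]

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        """Return a copy restricted to ``gene_ids`` (original row order kept)."""
        keep = [g for g in self.gene_ids if g in set(gene_ids)]
        return ExpressionMatrix(self.data.loc[keep].copy(), self.species)


@dataclass
class TranscriptionModule:
    """A transcription module M(G, T) with signed tissue scores.

    ``gene_scores`` maps each member gene to its final ISA gene score;
    ``tissue_scores`` maps each selected tissue to its signed score.
    ``provenance`` records how the module was obtained (thresholds, seed,
    merge lineage).
    """

    module_id: str
    species: str
    gene_scores: dict[str, float]
    tissue_scores: dict[str, float]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.gene_scores) < 1:
            raise ConfigurationError(f"module {self.module_id!r} has an empty gene set")

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.gene_scores)

    @property
    def tissues(self) -> frozenset[str]:
        return frozenset(self.tissue_scores)

    @property
    def positive_tissues(self) -> frozenset[str]:
        """Tissues with a positive score (the T_j used by the constraint stage)."""
        return frozenset(t for t, s in self.tissue_scores.items() if s > 0)

    def content_key(self) -> tuple[frozenset[str], frozenset[str]]:
        return (self.genes, self.tissues)

    def __len__(self) -> int:
        return len(self.gene_scores)


@dataclass
class ModuleSet:
    """An ordered collection of modules from one species at one pipeline stage.

    ``stage`` is one of ``"raw"`` (ISA output), ``"merged"`` (post-IGMM) or
    ``"refined"`` (RMP modules).
    """

    modules: list[TranscriptionModule]
    species: str
    stage: str = "raw"

    def __post_init__(self) -> None:
        ids = [m.module_id for m in self.modules]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate module ids in module set")
        for m in self.modules:
            if m.species != self.species:
                raise ConfigurationError(
                    f"module {m.module_id!r} species {m.species!r} != set species {self.species!r}"
                )

    def __iter__(self) -> Iterator[TranscriptionModule]:
        return iter(self.modules)

    def __len__(self) -> int:
        return len(self.modules)

    def __getitem__(self, module_id: str) -> TranscriptionModule:
        for m in self.modules:
            if m.module_id == module_id:
                return m
        raise KeyError(module_id)

    @property
    def module_ids(self) -> list[str]:
        return [m.module_id for m in self.modules]

    def gene_universe(self) -> frozenset[str]:
        """Union of the gene sets of all modules (module-associated genes)."""
        out: set[str] = set()
        for m in self.modules:
            out |= m.genes
        return frozenset(out)


@dataclass
class OrthologyMap:
    """A one-to-one ortholog pairing between two species.

    ``a_to_b`` maps species-A gene ids to species-B gene ids and must be a
    bijection over its domain/range.
    """

    a_to_b: dict[str, str]
    species_a: str = "human"
    species_b: str = "mouse"

    def __post_init__(self) -> None:
        values = list(self.a_to_b.values())
        if len(set(values)) != len(values):
            raise ConfigurationError("orthology map is not one-to-one")
        self._b_to_a = {b: a for a, b in self.a_to_b.items()}

    def __len__(self) -> int:
        return len(self.a_to_b)

    def to_b(self, gene_a: str) -> str | None:
        return self.a_to_b.get(gene_a)

    def to_a(self, gene_b: str) -> str | None:
        return self._b_to_a.get(gene_b)

    def translate(self, genes: Iterable[str], to_species: str) -> frozenset[str]:
        """Map a gene-id set into ``to_species`` id space, dropping unmapped ids."""
        if to_species == self.species_b:
            table: Mapping[str, str] = self.a_to_b
        elif to_species == self.species_a:
            table = self._b_to_a
        else:
            raise ConfigurationError(f"unknown species {to_species!r} for orthology map")
        return frozenset(table[g] for g in genes if g in table)


@dataclass
class ParalogMap:
    """Within-species paralog families: gene id -> family id.

    Genes absent from the mapping are singletons (no paralogs).  Families
    never span species because gene ids are species-specific.
    """

    family_of: dict[str, str]

    def same_family(self, g1: str, g2: str) -> bool:
        f1 = self.family_of.get(g1)
        return f1 is not None and f1 == self.family_of.get(g2)

    def family(self, gene: str) -> str | None:
        return self.family_of.get(gene)

    def members(self, family_id: str) -> frozenset[str]:
        return frozenset(g for g, f in self.family_of.items() if f == family_id)

    def __len__(self) -> int:
        return len(self.family_of)
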