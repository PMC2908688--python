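"""Readers and writers for the package's plain-text formats.

Tabular data is TSV (tab-separated, UTF-8, header row); nested objects
(module sets, planted truth, reports) are JSON.  All readers validate
strictly and every write/read pair round-trips exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    ExpressionMatrix,
    ModuleSet,
    OrthologyMap,
    ParalogMap,
    ParseError,
    TranscriptionModule,
)
from .synth import PlantedTruth

__all__ = [
    "write_expression", "read_expression",
    "write_orthology", "read_orthology",
    "write_paralogs", "read_paralogs",
    "write_kaks", "read_kaks",
    "write_modules", "read_modules",
    "write_similarity", "read_similarity",
    "write_truth",
]


def write_expression(E: ExpressionMatrix, path: str | Path) -> None:
    E.data.to_csv(path, sep="\t", index_label="gene_id")


def read_expression(path: str | Path, species: str) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        bad = df.isna().stack()
        gene, tissue = bad[bad].index[0]
        raise ParseError(f"{path}: missing value at gene {gene!r}, tissue {tissue!r}")
    try:
        df = df.astype(float)
    except ValueError as e:
        raise ParseError(f"{path}: non-numeric expression value ({e})") from e
    return ExpressionMatrix(df, species)


def write_orthology(orth: OrthologyMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{orth.species_a}\t{orth.species_b}\n")
        for a, b in orth.a_to_b.items():
            fh.write(f"{a}\t{b}\n")


def read_orthology(path: str | Path) -> OrthologyMap:
    pairs: dict[str, str] = {}
    seen_b: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) != 2:
            raise ParseError(f"{path}: orthology header must have two columns")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2 or not all(parts):
                raise ParseError(f"{path}:{lineno}: malformed orthology row")
            a, b = parts
            if a in pairs or b in seen_b:
                raise ParseError(f"{path}:{lineno}: gene duplicated, map not one-to-one")
            pairs[a] = b
            seen_b.add(b)
    return OrthologyMap(pairs, species_a=header[0], species_b=header[1])


def write_paralogs(para: ParalogMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tfamily_id\n")
        for g, fam in para.family_of.items():
            fh.write(f"{g}\t{fam}\n")


def read_paralogs(path: str | Path) -> ParalogMap:
    fam: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["gene_id", "family_id"]:
            raise ParseError(f"{path}: expected header 'gene_id\\tfamily_id'")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2 or not all(parts):
                raise ParseError(f"{path}:{lineno}: malformed paralog row")
            if parts[0] in fam:
                raise ParseError(f"{path}:{lineno}: gene {parts[0]!r} assigned twice")
            fam[parts[0]] = parts[1]
    return ParalogMap(fam)


def write_kaks(kaks: pd.DataFrame, path: str | Path) -> None:
    kaks.to_csv(path, sep="\t", index_label="gene_id")


def read_kaks(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = {"ka", "ks", "ka_ks"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing Ka/Ks columns {sorted(missing)}")
    if df.isna().any().any():
        raise ParseError(f"{path}: missing values in Ka/Ks table")
    if (df["ks"] <= 0).any():
        raise ParseError(f"{path}: Ks must be positive for every ratio row")
    return df


def _module_to_dict(m: TranscriptionModule) -> dict:
    return {
        "module_id": m.module_id,
        "species": m.species,
        "gene_scores": m.gene_scores,
        "tissue_scores": m.tissue_scores,
        "provenance": m.provenance,
    }


def _module_from_dict(d: dict) -> TranscriptionModule:
    try:
        return TranscriptionModule(
            module_id=d["module_id"],
            species=d["species"],
            gene_scores={k: float(v) for k, v in d["gene_scores"].items()},
            tissue_scores={k: float(v) for k, v in d["tissue_scores"].items()},
            provenance=d.get("provenance", {}),
        )
    except KeyError as e:
        raise ParseError(f"module record missing field {e.args[0]!r}") from e


def write_modules(ms: ModuleSet, path: str | Path) -> None:
    payload = {
        "species": ms.species,
        "stage": ms.stage,
        "modules": [_module_to_dict(m) for m in ms.modules],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_modules(path: str | Path) -> ModuleSet:
    with open(path) as fh:
        payload = json.load(fh)
    for key in ("species", "stage", "modules"):
        if key not in payload:
            raise ParseError(f"{path}: module set missing field {key!r}")
    return ModuleSet(
        [_module_from_dict(d) for d in payload["modules"]],
        species=payload["species"],
        stage=payload["stage"],
    )


def write_similarity(sim: pd.DataFrame, path: str | Path) -> None:
    sim.to_csv(path, sep="\t", index_label="module_id")


def read_similarity(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    vals = df.to_numpy(dtype=float)
    if np.isnan(vals).any() or (vals < 0).any() or (vals > 1).any():
        raise ParseError(f"{path}: similarity values must lie in [0, 1]")
    return df


def write_truth(truth: PlantedTruth, path: str | Path) -> None:
    payload = {
        "modules": {s: [_module_to_dict(m) for m in ms.modules]
                    for s, ms in truth.modules.items()},
        "shared_pairs": [list(p) for p in truth.shared_pairs],
        "tci": truth.tci,
        "gene_ids": truth.gene_ids,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
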