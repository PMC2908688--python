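"""End-to-end pipeline: discovery, merging, comparison, scoring, reporting.

``run_all`` executes the whole analysis on a pair of expression matrices
plus orthology/paralogy maps and an optional Ka/Ks table, writing a
JSON/TSV report bundle.  Every stochastic stage consumes a seed derived
deterministically from the global seed and the stage name, so a config
reproduces its report byte for byte.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import io as tio
from .coherence import coherence_z
from .compare import (
    all_vs_all,
    max_similarity,
    modified_similarity,
    permutation_null,
    tissue_distribution,
)
from .constraint import correlate, quantities_table
from .core import ConfigurationError, ModuleSet
from .isa import IsaParams, discover
from .merge import igmm, refine
from .sensitivity import sensitivity

__all__ = ["PipelineConfig", "run_all", "stage_seed"]

logger = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (global_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class PipelineConfig:
    """Paths and parameters for a full run.

    File paths follow the formats written by :mod:`transmod.io`; the
    Ka/Ks table is optional (the constraint stage is skipped without it).
    """

    expr_a: str
    expr_b: str
    orthology: str
    paralogs: str
    out_dir: str
    kaks_a: str | None = None
    kaks_b: str | None = None
    species_a: str = "human"
    species_b: str = "mouse"
    isa: IsaParams = field(default_factory=IsaParams)
    merge_threshold: float = 0.7
    membership: float = 0.8
    n_permutations: int = 1000
    coherence_n_random: int = 10000
    coherence_size_range: tuple[int, int] = (20, 50)
    ks_max: float = 1.0
    run_sensitivity: bool = False
    sensitivity_fractions: tuple[float, ...] = (0.05, 0.10, 0.15, 0.20)
    sensitivity_replicates: int = 20
    rng_seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        isa_raw = raw.pop("isa", {})
        cfg = cls(**raw)
        if isa_raw:
            cfg.isa = IsaParams(**{**asdict(cfg.isa), **isa_raw})
        return cfg

    def validate(self) -> None:
        for name in ("expr_a", "expr_b", "orthology", "paralogs", "kaks_a", "kaks_b"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigurationError(f"{name} file not found: {p}")


def _rmp_stage(E, isa_params: IsaParams, cfg: PipelineConfig, stage: str):
    params = replace(isa_params, rng_seed=stage_seed(cfg.rng_seed, stage))
    raw = discover(E, params)
    if len(raw):
        rmp = refine(igmm(raw, threshold=cfg.merge_threshold,
                          membership=cfg.membership), raw)
    else:
        rmp = ModuleSet([], species=E.species, stage="refined")
    return raw, rmp


def run_all(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle under ``config.out_dir``.

    Returns the report dictionary (also written as ``report.json``).
    Any stage failure aborts with a stage-tagged diagnostic.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"parameters": {
        "isa": asdict(config.isa),
        "merge_threshold": config.merge_threshold,
        "membership": config.membership,
        "n_permutations": config.n_permutations,
        "coherence_n_random": config.coherence_n_random,
        "rng_seed": config.rng_seed,
    }, "stages": {}}

    def stage(name: str):
        logger.info("pipeline stage: %s", name)
        return name

    try:
        name = stage("load")
        ea = tio.read_expression(config.expr_a, config.species_a)
        eb = tio.read_expression(config.expr_b, config.species_b)
        orth = tio.read_orthology(config.orthology)
        para = tio.read_paralogs(config.paralogs)

        name = stage("discover")
        raw_a, rmp_a = _rmp_stage(ea, config.isa, config, "discover_a")
        raw_b, rmp_b = _rmp_stage(eb, config.isa, config, "discover_b")
        tio.write_modules(raw_a, out / "raw_a.json")
        tio.write_modules(raw_b, out / "raw_b.json")
        tio.write_modules(rmp_a, out / "rmp_a.json")
        tio.write_modules(rmp_b, out / "rmp_b.json")
        report["stages"]["discover"] = {
            "n_raw_a": len(raw_a), "n_raw_b": len(raw_b),
            "n_rmp_a": len(rmp_a), "n_rmp_b": len(rmp_b),
        }

        name = stage("compare")
        if len(rmp_a) and len(rmp_b):
            sim = all_vs_all(rmp_a, rmp_b, orth)
            tio.write_similarity(sim, out / "similarity.tsv")
            modified = {
                f"{ma.module_id}|{mb.module_id}": modified_similarity(ma, mb, orth, para)
                for ma in rmp_a for mb in rmp_b
            }
            maxsim = max_similarity(rmp_b, rmp_a, orth)
            pool = sorted(rmp_a.gene_universe())
            sizes = [len(m.genes) for m in rmp_a.modules]
            null = permutation_null(
                rmp_b, pool, sizes, orth,
                n_reps=config.n_permutations,
                rng=stage_seed(config.rng_seed, "permutation"),
                observed_max=maxsim.to_numpy(),
            )
            report["stages"]["compare"] = {
                "max_similarity": {k: float(v) for k, v in maxsim.items()},
                "modified_similarity_mean": float(np.mean(list(modified.values()))),
                "null_q95": null.q95,
                "exceed_fraction": null.exceed_fraction,
            }
        else:
            report["stages"]["compare"] = {"skipped": "empty RMP module set"}

        name = stage("coherence")
        coh = {}
        for label, ms_, e_ in (("a", rmp_a, ea), ("b", rmp_b, eb)):
            for i, m in enumerate(ms_.modules):
                r = coherence_z(
                    m, e_, n_random=config.coherence_n_random,
                    size_rule=config.coherence_size_range,
                    rng=stage_seed(config.rng_seed, f"coherence_{label}_{i}"),
                )
                coh[m.module_id] = {"mean_pcc": r.mean_pcc, "z": r.z}
        report["stages"]["coherence"] = coh

        name = stage("constraint")
        constraint_out = {}
        for label, ms_, kaks_path in (("a", rmp_a, config.kaks_a),
                                      ("b", rmp_b, config.kaks_b)):
            if kaks_path is None or not len(ms_):
                continue
            table = quantities_table(ms_)
            kaks = tio.read_kaks(kaks_path)
            try:
                corr = correlate(table, kaks, ks_max=config.ks_max)
            except ConfigurationError as e:
                constraint_out[label] = {"skipped": str(e)}
                continue
            corr.to_csv(out / f"constraint_{label}.tsv", sep="\t")
            constraint_out[label] = corr.reset_index().to_dict(orient="records")
        report["stages"]["constraint"] = constraint_out

        name = stage("tissue_distribution")
        report["stages"]["tissue_distribution"] = {
            "a": tissue_distribution(rmp_a, tissue_ids=ea.tissue_ids).to_dict(),
            "b": tissue_distribution(rmp_b, tissue_ids=eb.tissue_ids).to_dict(),
        }

        if config.run_sensitivity:
            name = stage("sensitivity")
            sens = sensitivity(
                ea, replace(config.isa, rng_seed=stage_seed(config.rng_seed, "discover_a")),
                fractions=config.sensitivity_fractions,
                n_replicates=config.sensitivity_replicates,
                merge_threshold=config.merge_threshold,
                membership=config.membership,
                rng=stage_seed(config.rng_seed, "sensitivity"),
            )
            sens.to_csv(out / "sensitivity.tsv", sep="\t", index=False)
            report["stages"]["sensitivity"] = sens.to_dict(orient="records")
    except ConfigurationError:
        raise
    except Exception as e:  # pragma: no cover - defensive stage tagging
        raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return report
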