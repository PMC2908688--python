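import numpy as np
import pytest

from transmod import (
    IsaParams,
    ModuleSet,
    SyntheticConfig,
    TranscriptionModule,
    generate_pair,
    make_worked_example,
)


def make_module(module_id, genes, tissues=("liver",), species="human",
                tissue_scores=None):
    """Small helper to build a module from plain gene/tissue collections."""
    if tissue_scores is None:
        tissue_scores = {t: 1.0 for t in tissues}
    return TranscriptionModule(
        module_id=module_id,
        species=species,
        gene_scores={g: 1.0 for g in genes},
        tissue_scores=dict(tissue_scores),
    )


@pytest.fixture(scope="session")
def worked_example():
    """The worked example: 7- and 8-gene modules, 3 shared orthologs,
    paralog families yielding 5 and 6 matched genes."""
    return make_worked_example()


@pytest.fixture(scope="session")
def planted_pair():
    """A medium synthetic pair with strong planted structure.

    500 genes x 29 tissues per species, 2 shared + 1 species-specific
    planted modules of 15-25 genes over 3 tissues, disjoint gene sets.
    """
    cfg = SyntheticConfig(
        n_genes=500,
        n_modules_shared=2,
        n_modules_specific_per_species=1,
        module_size_range=(15, 25),
        tissues_per_module_range=(3, 3),
        disjoint_genes=True,
        rng_seed=2,
    )
    return cfg, generate_pair(cfg)


@pytest.fixture(scope="session")
def discovery_params():
    """ISA parameters for analysis-scale runs: modules below the smallest
    plausible size (10 genes) are dissolved."""
    return IsaParams(n_seeds=300, rng_seed=5, min_module_genes=10)


@pytest.fixture
def three_disjoint_modules():
    g = [f"g{i}" for i in range(40)]
    return ModuleSet(
        [
            make_module("m0", g[0:10], ["liver", "kidney"]),
            make_module("m1", g[10:25], ["lung"]),
            make_module("m2", g[25:40], ["heart", "lung", "testis"]),
        ],
        species="human",
    )
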