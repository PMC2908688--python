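"""Compare module sets across species, with and without paralogs.

Shows the worked similarity example (gene-level 0.401 vs
paralog-modified 0.735), then an all-vs-all comparison of planted
module sets and the permutation null for per-module maximal similarity.
"""

import numpy as np

from transmod import (
    SyntheticConfig,
    all_vs_all,
    generate_pair,
    make_worked_example,
    max_similarity,
    modified_similarity,
    permutation_null,
    sim_gene,
)

# The worked toy: 7- and 8-gene modules, 3 shared orthologs, paralog
# families raising the matched counts to 5 (human side) and 6 (mouse side).
h, m, orth, para = make_worked_example()
print(f"gene-level similarity:      {sim_gene(h, m, orth):.3f}")
print(f"paralog-modified similarity: {modified_similarity(h, m, orth, para):.3f}")
print("Paralog-mediated matches raise the similarity of this pair "
      "from 0.401 to 0.735.\n")

config = SyntheticConfig(n_genes=1000, n_modules_shared=2,
                         n_modules_specific_per_species=1,
                         module_size_range=(25, 35),
                         tissues_per_module_range=(3, 3),
                         disjoint_genes=True, rng_seed=0)
_, _, orthology, _, truth = generate_pair(config)
human_ms = truth.modules["human"]
mouse_ms = truth.modules["mouse"]

sim = all_vs_all(human_ms, mouse_ms, orthology)
print("all-vs-all similarity (rows: human, cols: mouse):")
print(sim.round(2).to_string())

observed = max_similarity(mouse_ms, human_ms, orthology)
null = permutation_null(
    mouse_ms,
    sorted(human_ms.gene_universe()),
    [len(mod.genes) for mod in human_ms],
    orthology,
    n_reps=500,
    rng=0,
    observed_max=observed.to_numpy(),
)
print(f"\nnull 95% quantile of maximal similarity: {null.q95:.3f}")
print(f"observed maximal similarities: "
      f"{np.round(observed.to_numpy(), 3).tolist()}")
print("Shared planted pairs stand far above the null quantile; the")
print("species-specific module does not.")
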