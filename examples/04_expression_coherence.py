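"""Score the expression coherence of modules.

Coherence is the mean pairwise Pearson correlation of a module's
profiles over all tissues; significance is a z-score against random
gene sets of matched size range drawn from the whole matrix.
"""

import numpy as np

from transmod import (
    SyntheticConfig,
    TranscriptionModule,
    coherence_z,
    generate_pair,
)

config = SyntheticConfig(n_genes=1000, n_modules_shared=2,
                         n_modules_specific_per_species=1,
                         tissues_per_module_range=(3, 3),
                         disjoint_genes=True, rng_seed=0)
human, _, _, _, truth = generate_pair(config)

print("planted modules:")
for m in truth.modules["human"]:
    r = coherence_z(m, human, n_random=1000, rng=0)
    print(f"  {m.module_id}: mean PCC = {r.mean_pcc:.3f}, z = {r.z:.1f}")

rng = np.random.default_rng(1)
genes = rng.choice(human.gene_ids, size=30, replace=False)
random_set = TranscriptionModule("random", "human",
                                 {g: 1.0 for g in genes}, {"liver": 1.0})
r = coherence_z(random_set, human, n_random=1000, rng=0)
print(f"random 30-gene set: mean PCC = {r.mean_pcc:.3f}, z = {r.z:.1f}")
print("Planted modules are coherent far beyond chance (z >> 5); a random")
print("gene set sits inside the control distribution (|z| < 3).")
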