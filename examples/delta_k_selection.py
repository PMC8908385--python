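"""Choose the number of clusters with Evanno's delta-K.

Delta-K(K) is the mean absolute second difference of the run
log-likelihoods over replicates, divided by their SD at K; the peak marks
the strongest hierarchical level of structure.
"""

import numpy as np

from mixopop import evanno_delta_k
from mixopop.structure import StructureRun

# synthetic replicate ln-probs with a clear elbow at K = 2
rng = np.random.default_rng(1)
runs = []
for rep in range(10):
    lnp = {1: -5200.0, 2: -4400.0, 3: -4380.0, 4: -4370.0, 5: -4365.0}
    for k, base in lnp.items():
        runs.append(
            StructureRun(
                K=k, replicate=rep, ln_prob=base + rng.normal(0, 15),
                labels=["I1"], q_matrix=np.ones((1, k)) / k,
            )
        )

table = evanno_delta_k(runs)
print(table.table.round(2).to_string(index=False))
print(f"best K = {table.best_k}")
# Delta-K is undefined at the boundary Ks and translation-invariant: adding
# a constant to every ln-prob leaves the table unchanged.
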