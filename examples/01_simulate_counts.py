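"""Generate a synthetic microbiome count table with a known association graph.

Builds an Erdos-Renyi ground truth (one edge per taxon), a precision matrix
with condition number 100, and draws zero-inflated log-normal counts with
negative-binomial library sizes.
"""

import numpy as np

from ziln import simulation1_dataset

graph, cov, counts = simulation1_dataset("erdos_renyi", p=100, n=200, seed=1)

print(f"graph: {graph.p} taxa, {graph.edge_count} true edges ({graph.topology})")
print(f"precision condition number: {cov.condition_number:.6f}")
print(f"count matrix: {counts.n} samples x {counts.p} taxa")
print(f"zero cells: {100 * (counts.counts == 0).mean():.1f}%")
print(f"median library size: {np.median(counts.library_sizes):.3g} reads")
# ~45% of cells are zero: structural zeros from the latent thresholds plus
# a few sampling zeros from the finite multinomial draw.
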