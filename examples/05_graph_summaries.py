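"""Graph-level summaries: assortativity and edge-set overlap.

Labels taxa by cliques of a planted modular graph, checks that edges stay
within modules (assortativity near 1), and intersects the top-k edges of
two inference methods.
"""

import numpy as np

from ziln import assortativity, edge_overlap, infer_network, simulation1_dataset

# assortativity on a modular toy graph: edges only within label groups
edges = [(0, 1), (1, 2), (3, 4), (4, 5), (6, 7)]
labels = {0: "A", 1: "A", 2: "A", 3: "B", 4: "B", 5: "B", 6: "C", 7: "C"}
print(f"within-module edges only -> assortativity {assortativity(edges, labels):+.2f}")

labels_crossed = {**labels, 1: "B", 4: "A"}
print(f"after crossing two labels -> assortativity "
      f"{assortativity(edges, labels_crossed):+.2f}")

# overlap of the top-30 edges of two estimators on the same data
_, _, counts = simulation1_dataset("erdos_renyi", p=40, n=200, seed=5)
sets = {}
for method in ("mb", "glasso"):
    _, ranked = infer_network(counts, method=method, n_lambda=25)
    sets[method] = ranked.pairs
overlap = edge_overlap(sets, top_k=30)
print(f"top-30 edges shared by both methods: {overlap['unanimous']}")
print(f"idiosyncratic: {overlap['idiosyncratic']}")
# High overlap between estimators on the same ranking problem is a sanity
# signal; on real data the shared core is what one would report.
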