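"""Replay a reduced benchmark grid and print the aggregated table.

One cell (Erdos-Renyi, p=50, n=150) with 4 replicates and two methods;
medians and quartiles over replicates, deterministic for a fixed seed.
"""

from ziln import BenchmarkConfig, run_benchmark
from ziln.benchmark import aggregate_benchmark

cfg = BenchmarkConfig(
    topologies=("erdos_renyi",),
    p_list=(50,),
    n_list=(150,),
    replicates=4,
    methods=("ziln-mb", "none-mb"),
    n_lambda=25,
    seed=4,
)
results = run_benchmark(cfg)
print(aggregate_benchmark(results).to_string(index=False))
# ziln-mb should dominate none-mb in AUPR median; the paper-scale grid
# (p up to 500, n up to 2000, all three topologies) is reachable by flag.
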