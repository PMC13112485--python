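"""Compare five clustering algorithms over repeated seeded runs.

Runs RDBPSO, velocity PSO, k-means, a Gaussian mixture, and Ward
agglomerative clustering on one separation-3 synthetic table across 5
seeds each, then prints the mean and sample standard deviation of every
metric per algorithm — the shape of a multi-run stability study. Swarm
iterations are reduced to keep the example quick; expect the swarm
methods to lead on purity with a small spread.
"""

from rdbpso.benchmark import BenchmarkConfig, run_benchmark, stability_summary
from rdbpso.synthetic import FeatureSimConfig, simulate_feature_table

table = simulate_feature_table(
    FeatureSimConfig(n_healthy=100, n_tumor=100, separation=3.0, seed=0)
)
config = BenchmarkConfig(
    seeds=tuple(range(5)),
    n_particles=30,
    max_iterations=50,
)
report = run_benchmark(table, config)
summary = stability_summary(report)
print(summary.round(4).to_string())
print("\nEach cell is mean/std over the 5 seeded runs; the baselines are "
      "deterministic or near-deterministic, the swarm methods stochastic.")
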