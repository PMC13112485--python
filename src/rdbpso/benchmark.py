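"""Multi-algorithm comparison and stability harness.

Runs a set of clustering algorithms (the two swarm optimizers plus
k-means, Gaussian-mixture, and Ward agglomerative baselines from
scikit-learn) on one labeled feature table across many seeded runs, and
summarizes the five evaluation metrics as mean and sample standard
deviation per algorithm — the shape of a multi-run stability study.

The swarm methods are the package's own; the three classical baselines
are comparators only and delegate to scikit-learn.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.mixture import GaussianMixture

from . import classifier
from .features import apply_standardizer, fit_standardizer
from .metrics import MetricsReport, evaluate_all
from .optimizer import OptimizerConfig

__all__ = ["BenchmarkConfig", "BenchmarkReport", "run_benchmark", "stability_summary"]

logger = logging.getLogger("rdbpso.benchmark")

SWARM_ALGORITHMS = ("rdbpso", "standard_pso")
BASELINE_ALGORITHMS = ("kmeans", "gmm", "hierarchical")
ALL_ALGORITHMS = SWARM_ALGORITHMS + BASELINE_ALGORITHMS

METRIC_NAMES = ("accuracy", "ari", "nmi", "fmi", "purity")


@dataclass
class BenchmarkConfig:
    """Which algorithms to run, on which seeds, with which swarm settings."""

    algorithms: tuple[str, ...] = ALL_ALGORITHMS
    seeds: tuple[int, ...] = tuple(range(10))
    n_particles: int = 30
    max_iterations: int = 100
    k: int = 2
    linkage: str = "ward"  # hierarchical baseline
    covariance_type: str = "full"  # GMM baseline

    def __post_init__(self) -> None:
        unknown = [a for a in self.algorithms if a not in ALL_ALGORITHMS]
        if unknown:
            raise ValueError(f"unknown algorithm(s): {unknown}; choose from {ALL_ALGORITHMS}")


@dataclass
class BenchmarkReport:
    """Per-run metric rows plus traces for the swarm methods."""

    runs: pd.DataFrame  # columns: algorithm, seed, accuracy, ari, nmi, fmi, purity
    traces: dict = field(default_factory=dict)  # (algorithm, seed) -> OptimizationTrace

    def aggregate(self) -> pd.DataFrame:
        return (
            self.runs.groupby("algorithm")[list(METRIC_NAMES)]
            .agg(["mean", "std"])
            .sort_index()
        )


def _cluster_labels(
    algorithm: str, table: pd.DataFrame, seed: int, config: BenchmarkConfig
):
    """Cluster the table into k groups; returns (labels, trace-or-None)."""
    if algorithm in SWARM_ALGORITHMS:
        model = classifier.fit(
            table,
            OptimizerConfig(
                n_particles=config.n_particles,
                max_iterations=config.max_iterations,
                seed=seed,
            ),
            k=config.k,
            algorithm=algorithm,
        )
        return classifier.predict_clusters(model, table), model.training_trace
    Zx = apply_standardizer(fit_standardizer(table), table)
    Zx = Zx[[c for c in Zx.columns if c != "label"]].to_numpy(dtype=float)
    if algorithm == "kmeans":
        return (
            KMeans(n_clusters=config.k, random_state=seed, n_init=10).fit_predict(Zx),
            None,
        )
    if algorithm == "gmm":
        return (
            GaussianMixture(
                n_components=config.k,
                covariance_type=config.covariance_type,
                random_state=seed,
            ).fit_predict(Zx),
            None,
        )
    if algorithm == "hierarchical":
        return (
            AgglomerativeClustering(n_clusters=config.k, linkage=config.linkage).fit_predict(Zx),
            None,
        )
    raise ValueError(f"unknown algorithm {algorithm!r}")


def run_benchmark(table: pd.DataFrame, config: BenchmarkConfig) -> BenchmarkReport:
    """Run every requested algorithm on every seed and collect the five metrics."""
    if "label" not in table.columns:
        raise ValueError("benchmark requires a labeled feature table")
    labels = table["label"].to_numpy(dtype=int)
    rows = []
    traces = {}
    for algorithm in config.algorithms:
        for seed in config.seeds:
            pred, trace = _cluster_labels(algorithm, table, seed, config)
            report: MetricsReport = evaluate_all(pred, labels)
            row = {"algorithm": algorithm, "seed": seed, **report.to_dict()}
            rows.append(row)
            if trace is not None:
                traces[(algorithm, seed)] = trace
                logger.info(
                    "%s seed=%d purity=%.4f evaluations=%d",
                    algorithm,
                    seed,
                    report.purity,
                    int(trace.evaluations_per_iteration.sum()),
                )
            else:
                logger.info("%s seed=%d purity=%.4f", algorithm, seed, report.purity)
    return BenchmarkReport(runs=pd.DataFrame(rows), traces=traces)


def stability_summary(report: BenchmarkReport, boxplot_path=None) -> pd.DataFrame:
    """Mean and sample (n-1) standard deviation per algorithm per metric.

    Optionally writes a per-metric box plot across runs to
    ``boxplot_path`` (PNG).
    """
    if len(report.runs) < 2:
        raise ValueError("stability summary requires at least 2 runs")
    summary = report.aggregate()
    if boxplot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        metrics = list(METRIC_NAMES)
        fig, axes = plt.subplots(1, len(metrics), figsize=(4 * len(metrics), 4))
        for ax, metric in zip(np.atleast_1d(axes), metrics):
            data = [
                group[metric].to_numpy()
                for _, group in report.runs.groupby("algorithm")
            ]
            names = [name for name, _ in report.runs.groupby("algorithm")]
            ax.boxplot(data, tick_labels=names)
            ax.set_title(metric)
            ax.tick_params(axis="x", rotation=45)
        fig.tight_layout()
        fig.savefig(boxplot_path, dpi=120)
        plt.close(fig)
    return summary
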