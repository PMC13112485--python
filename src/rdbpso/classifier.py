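"""Purity-objective cluster-center classification.

Two-class (healthy/tumor) image classification is framed as a global
optimization problem: a candidate solution is a flat vector of k*d
coordinates encoding k cluster centers in the d-dimensional standardized
feature space (k=2, d=16 canonically). The objective is 1 - purity of
the induced nearest-center partition against the training labels, which
the swarm optimizer minimizes. After fitting, each cluster is mapped to
its majority training class and new samples are classified by their
nearest center.

Optimization and evaluation use the full labeled table (no train/test
split): the fitted purity is a training-set quantity, and because purity
is both the objective and a reported metric, the accuracy of the fitted
model equals its purity by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import StandardizationModel, apply_standardizer, fit_standardizer
from .optimizer import (
    Objective,
    OptimizationTrace,
    OptimizerConfig,
    optimize,
    optimize_standard_pso,
)

__all__ = [
    "assign_to_centers",
    "purity_fitness",
    "ClusterModel",
    "fit",
    "predict",
    "save_model",
    "load_model",
]


def assign_to_centers(X: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Index of the Euclidean-nearest center per row; ties go to the lowest index."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if X.shape[1] != centers.shape[1]:
        raise ValueError(
            f"dimension mismatch: rows have {X.shape[1]} features, centers {centers.shape[1]}"
        )
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1)


def _purity(assignments: np.ndarray, labels: np.ndarray, k: int) -> float:
    n = labels.size
    counts = np.zeros((k, int(labels.max()) + 1), dtype=np.int64)
    np.add.at(counts, (assignments, labels), 1)
    return float(counts.max(axis=1).sum() / n)


def purity_fitness(solution: np.ndarray, X: np.ndarray, labels: np.ndarray, k: int = 2) -> float:
    """1 - purity of the nearest-center partition encoded by ``solution``.

    ``solution`` is a flat k*d vector, reshaped row-major into a k-by-d
    center matrix. Empty clusters contribute zero majority count.
    """
    d = X.shape[1]
    centers = np.asarray(solution, dtype=float).reshape(k, d)
    return 1.0 - _purity(assign_to_centers(X, centers), labels, k)


@dataclass
class ClusterModel:
    """Fitted cluster centers, standardizer, and cluster-to-class map."""

    centers: np.ndarray
    standardizer: StandardizationModel
    cluster_to_class: dict[int, int]
    fitness: float
    training_trace: OptimizationTrace | None = None

    @property
    def purity(self) -> float:
        return 1.0 - self.fitness


def fit(
    table: pd.DataFrame,
    config: OptimizerConfig | None = None,
    k: int = 2,
    algorithm: str = "rdbpso",
) -> ClusterModel:
    """Standardize, optimize k*d cluster centers for purity, map clusters to classes.

    Search bounds are the per-dimension min/max of the standardized
    features, tiled over the k centers. A cluster's class is its majority
    training class; a tie maps to healthy (0), the conservative screening
    default. Requires both classes present (with a single class purity is
    trivially 1 and nothing is learned).
    """
    if config is None:
        config = OptimizerConfig()
    if "label" not in table.columns:
        raise ValueError("fit requires a 'label' column")
    labels = table["label"].to_numpy(dtype=int)
    if np.unique(labels).size < 2:
        raise ValueError("fit requires both classes present; purity is trivially 1 otherwise")
    if len(table) < k:
        raise ValueError(f"need at least k={k} rows")

    standardizer = fit_standardizer(table)
    Z = apply_standardizer(standardizer, table)
    X = Z[[c for c in Z.columns if c != "label"]].to_numpy(dtype=float)
    d = X.shape[1]

    lo, hi = X.min(axis=0), X.max(axis=0)
    objective = Objective(
        fn=lambda sol: purity_fitness(sol, X, labels, k),
        lower=np.tile(lo, k),
        upper=np.tile(hi, k),
    )
    runner = {"rdbpso": optimize, "standard_pso": optimize_standard_pso}[algorithm]
    trace = runner(objective, config)
    centers = trace.global_memory.gbest.reshape(k, d)

    assignments = assign_to_centers(X, centers)
    counts = np.zeros((k, int(labels.max()) + 1), dtype=np.int64)
    np.add.at(counts, (assignments, labels), 1)
    # ties map to class 0 (healthy): argmax takes the first maximum
    cluster_to_class = {i: int(counts[i].argmax()) for i in range(k)}
    return ClusterModel(
        centers=centers,
        standardizer=standardizer,
        cluster_to_class=cluster_to_class,
        fitness=float(trace.global_memory.gbest_fitness),
        training_trace=trace,
    )


def predict(model: ClusterModel, X) -> np.ndarray:
    """Class label per row: standardize, assign to nearest center, map to class."""
    if isinstance(X, pd.DataFrame):
        X = X[[c for c in X.columns if c != "label"]].to_numpy(dtype=float)
    Z = model.standardizer.transform(np.atleast_2d(np.asarray(X, dtype=float)))
    assignments = assign_to_centers(Z, model.centers)
    return np.array([model.cluster_to_class[int(a)] for a in assignments])


def predict_clusters(model: ClusterModel, X) -> np.ndarray:
    """Raw cluster index per row (before the class mapping)."""
    if isinstance(X, pd.DataFrame):
        X = X[[c for c in X.columns if c != "label"]].to_numpy(dtype=float)
    Z = model.standardizer.transform(np.atleast_2d(np.asarray(X, dtype=float)))
    return assign_to_centers(Z, model.centers)


def save_model(model: ClusterModel, path) -> None:
    """Persist a fitted model as JSON (centers, standardizer, class map, fitness)."""
    payload = {
        "centers": model.centers.tolist(),
        "standardizer": model.standardizer.to_dict(),
        "cluster_to_class": {str(c): int(l) for c, l in model.cluster_to_class.items()},
        "fitness": model.fitness,
    }
    if model.training_trace is not None:
        payload["seed"] = model.training_trace.seed
        payload["config"] = model.training_trace.config
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> ClusterModel:
    with open(path) as fh:
        payload = json.load(fh)
    return ClusterModel(
        centers=np.asarray(payload["centers"], dtype=float),
        standardizer=StandardizationModel.from_dict(payload["standardizer"]),
        cluster_to_class={int(c): int(l) for c, l in payload["cluster_to_class"].items()},
        fitness=float(payload["fitness"]),
        training_trace=None,
    )
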