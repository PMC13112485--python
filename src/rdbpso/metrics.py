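"""Pair-counting and information-theoretic cluster evaluation.

All five metrics (accuracy, ARI, NMI, FMI, purity) are computed from a
single cluster-by-class contingency table. Accuracy and purity share the
majority-overlap formula ``sum_i max_j n_ij / n`` and therefore always
coincide; both are reported because both names are conventional.

Degenerate conventions: ARI with a zero denominator (both partitions
trivial) is 1 if the partitions agree perfectly and 0 otherwise; NMI of
two trivial partitions is 1; FMI with a zero denominator is 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import comb

__all__ = [
    "contingency",
    "accuracy_and_purity",
    "adjusted_rand_index",
    "normalized_mutual_info",
    "fowlkes_mallows",
    "MetricsReport",
    "evaluate_all",
    "evaluate_table",
]


def contingency(pred, true) -> np.ndarray:
    """Cluster-by-class count matrix ``counts[i, j] = |C_i ∩ L_j|``.

    Labels may be arbitrary hashables; rows/columns follow the sorted
    order of the distinct cluster / class labels.
    """
    pred = np.asarray(pred)
    true = np.asarray(true)
    if pred.shape != true.shape or pred.ndim != 1:
        raise ValueError("pred and true must be 1-D vectors of equal length")
    if pred.size == 0:
        raise ValueError("empty label vectors")
    clusters, ci = np.unique(pred, return_inverse=True)
    classes, li = np.unique(true, return_inverse=True)
    counts = np.zeros((clusters.size, classes.size), dtype=np.int64)
    np.add.at(counts, (ci, li), 1)
    return counts


def _as_counts(t) -> np.ndarray:
    counts = np.asarray(t, dtype=np.int64)
    if counts.ndim != 2 or counts.min() < 0:
        raise ValueError("contingency table must be a 2-D non-negative count matrix")
    return counts


def accuracy_and_purity(t) -> tuple[float, float]:
    """Majority-overlap accuracy and purity (identical by definition)."""
    counts = _as_counts(t)
    n = counts.sum()
    if n < 1:
        raise ValueError("contingency table must contain at least one sample")
    value = float(counts.max(axis=1).sum() / n)
    return value, value


def adjusted_rand_index(t) -> float:
    """Chance-corrected pair-counting agreement between the two partitions."""
    counts = _as_counts(t)
    n = counts.sum()
    if n < 2:
        raise ValueError("ARI requires at least 2 samples")
    T = comb(counts, 2).sum()
    A = comb(counts.sum(axis=1), 2).sum()
    B = comb(counts.sum(axis=0), 2).sum()
    total = comb(n, 2)
    expected = A * B / total
    denom = (A + B) / 2.0 - expected
    if denom == 0.0:
        return 1.0 if T == A == B else 0.0
    return float((T - expected) / denom)


def normalized_mutual_info(t) -> float:
    """Mutual information normalized by the average marginal entropy.

    Natural logarithms throughout; the normalization cancels the base.
    Two trivial (single-block) partitions score 1.
    """
    counts = _as_counts(t)
    n = counts.sum()
    if n < 1:
        raise ValueError("NMI requires at least 1 sample")
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)

    def entropy(marginal: np.ndarray) -> float:
        p = marginal[marginal > 0] / n
        return float(-(p * np.log(p)).sum())

    h_c, h_l = entropy(rows), entropy(cols)
    if h_c + h_l == 0.0:
        return 1.0
    i, j = np.nonzero(counts)
    p_ij = counts[i, j] / n
    mi = float((p_ij * np.log(n * counts[i, j] / (rows[i] * cols[j]))).sum())
    return 2.0 * mi / (h_c + h_l)


def fowlkes_mallows(t) -> float:
    """Geometric mean of pairwise precision and recall over co-clustered pairs."""
    counts = _as_counts(t)
    n = counts.sum()
    if n < 2:
        raise ValueError("FMI requires at least 2 samples")
    tp = comb(counts, 2).sum()
    tp_fp = comb(counts.sum(axis=1), 2).sum()
    tp_fn = comb(counts.sum(axis=0), 2).sum()
    denom = tp_fp * tp_fn
    if denom == 0.0:
        return 0.0
    return float(tp / np.sqrt(denom))


@dataclass
class MetricsReport:
    accuracy: float
    ari: float
    nmi: float
    fmi: float
    purity: float

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "ari": self.ari,
            "nmi": self.nmi,
            "fmi": self.fmi,
            "purity": self.purity,
        }


def evaluate_table(t) -> MetricsReport:
    """All five metrics from one cluster-by-class contingency table."""
    accuracy, purity = accuracy_and_purity(t)
    return MetricsReport(
        accuracy=accuracy,
        ari=adjusted_rand_index(t),
        nmi=normalized_mutual_info(t),
        fmi=fowlkes_mallows(t),
        purity=purity,
    )


def evaluate_all(pred, true) -> MetricsReport:
    """All five metrics from predicted-cluster and true-class label vectors."""
    return evaluate_table(contingency(pred, true))
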