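"""Shared fixtures and independent oracles for the test suite.

The oracle helpers here deliberately avoid the code paths they check:
pair counting loops over all sample pairs, purity counts through plain
dictionaries, and the co-occurrence oracle enumerates pixel pairs
directly.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from rdbpso.optimizer import Objective


@pytest.fixture
def sphere():
    """Fresh 5-D sphere objective on [-5, 5]^5."""
    return Objective(lambda x: float((x**2).sum()), [-5.0] * 5, [5.0] * 5)


def make_sphere(d: int = 5, half_width: float = 5.0) -> Objective:
    return Objective(lambda x: float((x**2).sum()), [-half_width] * d, [half_width] * d)


def pairwise_agreement_counts(pred: np.ndarray, true: np.ndarray) -> tuple[int, int, int, int]:
    """(both-same, pred-same-only, true-same-only, both-different) over all pairs."""
    ss = sd = ds = dd = 0
    n = len(pred)
    for i, j in itertools.combinations(range(n), 2):
        same_pred = pred[i] == pred[j]
        same_true = true[i] == true[j]
        if same_pred and same_true:
            ss += 1
        elif same_pred:
            sd += 1
        elif same_true:
            ds += 1
        else:
            dd += 1
    return ss, sd, ds, dd


def ari_pair_oracle(pred: np.ndarray, true: np.ndarray) -> float:
    """ARI by exhaustive pair counting (adjusted-for-chance Rand index)."""
    ss, sd, ds, dd = pairwise_agreement_counts(pred, true)
    total = ss + sd + ds + dd
    a = ss + sd  # pairs co-clustered in pred
    b = ss + ds  # pairs co-classed in true
    expected = a * b / total
    denom = (a + b) / 2.0 - expected
    if denom == 0.0:
        return 1.0 if ss == a == b else 0.0
    return (ss - expected) / denom


def fmi_pair_oracle(pred: np.ndarray, true: np.ndarray) -> float:
    """FMI by exhaustive pair counting: TP / sqrt((TP+FP)(TP+FN))."""
    ss, sd, ds, _ = pairwise_agreement_counts(pred, true)
    denom = (ss + sd) * (ss + ds)
    if denom == 0:
        return 0.0
    return ss / np.sqrt(denom)


def purity_count_oracle(assignments: np.ndarray, labels: np.ndarray) -> float:
    """Purity by dictionary counting, independent of any array machinery."""
    buckets: dict[int, dict[int, int]] = {}
    for a, l in zip(assignments.tolist(), labels.tolist()):
        buckets.setdefault(a, {}).setdefault(l, 0)
        buckets[a][l] += 1
    majority = sum(max(counts.values()) for counts in buckets.values())
    return majority / len(labels)


def cooccurrence_oracle(img: np.ndarray, offset: tuple[int, int], levels: int) -> np.ndarray:
    """Symmetric normalized co-occurrence matrix by direct pixel-pair enumeration."""
    quantized = (img.astype(np.uint16) * levels // 256).astype(int)
    P = np.zeros((levels, levels))
    dr, dc = offset
    rows, cols = img.shape
    for r in range(rows):
        for c in range(cols):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < rows and 0 <= c2 < cols:
                P[quantized[r, c], quantized[r2, c2]] += 1
                P[quantized[r2, c2], quantized[r, c]] += 1
    return P / P.sum()
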