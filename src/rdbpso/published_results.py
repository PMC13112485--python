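"""Reported confusion matrices for the 800-image brain-cancer MRI benchmark.

Five clustering algorithms were run on a public Kaggle brain-cancer MRI
collection of 800 images (408 healthy, 392 tumor) represented by the
16-descriptor feature set of :mod:`rdbpso.features`. The published 2x2
confusion matrices are reproduced here as cluster-by-class count tables
(rows: predicted-healthy cluster, predicted-tumor cluster; columns: true
healthy, true tumor). They serve as reference inputs for the evaluation
metrics and as regression fixtures: re-deriving accuracy/ARI/NMI/FMI/
purity from these counts must reproduce the published metric table at
four decimal places.
"""

from __future__ import annotations

import numpy as np

__all__ = ["CONFUSION_MATRICES", "PUBLISHED_METRICS", "CLASS_TOTALS"]

# true class totals of the benchmark dataset
CLASS_TOTALS = {"healthy": 408, "tumor": 392}

CONFUSION_MATRICES: dict[str, np.ndarray] = {
    "rdbpso": np.array([[389, 19], [60, 332]]),
    "standard_pso": np.array([[387, 21], [65, 327]]),
    "gmm": np.array([[288, 60], [120, 332]]),
    "kmeans": np.array([[244, 54], [164, 338]]),
    "hierarchical": np.array([[166, 47], [242, 345]]),
}

# published metric table (accuracy, ARI, NMI, FMI, purity), 4 d.p.
PUBLISHED_METRICS: dict[str, dict[str, float]] = {
    "rdbpso": {"accuracy": 0.9012, "ari": 0.6436, "nmi": 0.5511, "fmi": 0.8229, "purity": 0.9012},
    "standard_pso": {"accuracy": 0.8925, "ari": 0.6157, "nmi": 0.5243, "fmi": 0.8093, "purity": 0.8925},
    "gmm": {"accuracy": 0.7750, "ari": 0.3016, "nmi": 0.2410, "fmi": 0.6534, "purity": 0.7750},
    "kmeans": {"accuracy": 0.7275, "ari": 0.2061, "nmi": 0.1777, "fmi": 0.6154, "purity": 0.7275},
    "hierarchical": {"accuracy": 0.6388, "ari": 0.0760, "nmi": 0.0868, "fmi": 0.5860, "purity": 0.6388},
}
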