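"""Handcrafted 16-descriptor feature extraction for grayscale brain MRI.

Every image is reduced to a fixed-order vector of 16 descriptors drawn
from four families:

* five GLCM texture descriptors (contrast, correlation, energy,
  homogeneity, entropy), distance 1, angle-averaged over 0/45/90/135
  degrees, 32 quantized gray levels, symmetric normalized matrix;
* six first-order intensity statistics (mean, population standard
  deviation, Fisher skewness, excess kurtosis, 10th and 90th
  percentiles);
* four single-level Haar wavelet sub-band energies (LL, LH, HL, HH),
  normalized by pixel count;
* Sobel edge density with an adaptive mean + 1*std gradient-magnitude
  threshold.

The canonical order is :data:`FEATURE_NAMES`; every feature table in the
package uses these column names plus an optional binary ``label`` column
(0 = healthy, 1 = tumor).
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np
import pandas as pd
import pywt
from PIL import Image
from scipy import stats
from skimage.feature import graycomatrix, graycoprops
from skimage.filters import sobel

__all__ = [
    "FEATURE_NAMES",
    "CANONICAL_SIZE",
    "preprocess_image",
    "glcm_features",
    "first_order_stats",
    "wavelet_energies",
    "edge_density",
    "extract_features",
    "extract_feature_table",
    "StandardizationModel",
    "fit_standardizer",
    "apply_standardizer",
    "load_feature_table",
    "save_feature_table",
]

FEATURE_NAMES = (
    "glcm_contrast",
    "glcm_correlation",
    "glcm_energy",
    "glcm_homogeneity",
    "glcm_entropy",
    "intensity_mean",
    "intensity_std",
    "skewness",
    "kurtosis",
    "q10",
    "q90",
    "wavelet_energy_LL",
    "wavelet_energy_LH",
    "wavelet_energy_HL",
    "wavelet_energy_HH",
    "edge_density",
)

CANONICAL_SIZE = 256
GLCM_LEVELS = 32
GLCM_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)


def preprocess_image(source) -> np.ndarray:
    """Decode, convert to single-channel luminance, resize to 256x256.

    ``source`` may be a path, raw bytes, a PIL image, or a 2-D uint8
    array (returned resized if needed). Resizing is bilinear.
    """
    if isinstance(source, np.ndarray):
        img = Image.fromarray(np.asarray(source, dtype=np.uint8))
    elif isinstance(source, Image.Image):
        img = source
    elif isinstance(source, (bytes, bytearray)):
        img = Image.open(io.BytesIO(source))
    else:
        path = Path(source)
        try:
            img = Image.open(path)
        except Exception as exc:  # noqa: BLE001 - re-raise with the path
            raise OSError(f"cannot decode image file {path}") from exc
    img = img.convert("L")
    if img.size != (CANONICAL_SIZE, CANONICAL_SIZE):
        img = img.resize((CANONICAL_SIZE, CANONICAL_SIZE), Image.BILINEAR)
    return np.asarray(img, dtype=np.uint8)


def _glcm(img: np.ndarray) -> np.ndarray:
    quantized = (img.astype(np.uint16) * GLCM_LEVELS // 256).astype(np.uint8)
    return graycomatrix(
        quantized,
        distances=[1],
        angles=list(GLCM_ANGLES),
        levels=GLCM_LEVELS,
        symmetric=True,
        normed=True,
    )

def glcm_features(img: np.ndarray) -> np.ndarray:
    """Angle-averaged contrast, correlation, energy (sum p^2), homogeneity, entropy.

    A constant image has a single co-occurrence cell: contrast 0, energy
    1, homogeneity 1, entropy 0, and correlation defined as 1.
    """
    P = _glcm(img)
    contrast = graycoprops(P, "contrast")[0].mean()
    correlation = graycoprops(P, "correlation")[0].mean()
    energy = graycoprops(P, "ASM")[0].mean()
    homogeneity = graycoprops(P, "homogeneity")[0].mean()
    entropies = []
    for a in range(P.shape[3]):
        p = P[:, :, 0, a]
        nz = p[p > 0]
        entropies.append(float(-(nz * np.log2(nz)).sum()))
    return np.array([contrast, correlation, energy, homogeneity, np.mean(entropies)])


def first_order_stats(img: np.ndarray) -> np.ndarray:
    """Mean, population std, skewness, excess kurtosis, q10, q90 of the intensities."""
    v = img.astype(float).ravel()
    std = v.std()
    if std == 0.0:
        skew = kurt = 0.0
    else:
        skew = float(stats.skew(v))
        kurt = float(stats.kurtosis(v))
    q10, q90 = np.percentile(v, [10, 90])
    return np.array([v.mean(), std, skew, kurt, q10, q90])


def wavelet_energies(img: np.ndarray) -> np.ndarray:
    """Per-pixel energies of the single-level Haar sub-bands (LL, LH, HL, HH).

    HL is the vertical-edge (horizontal high-pass) band; a left/right
    step image puts all its detail energy there.
    """
    if img.shape[0] % 2 or img.shape[1] % 2:
        raise ValueError("wavelet decomposition requires even image dimensions")
    a = img.astype(float)
    cA, (cH, cV, cD) = pywt.dwt2(a, "haar")
    n = a.size
    return np.array(
        [(cA**2).sum() / n, (cH**2).sum() / n, (cV**2).sum() / n, (cD**2).sum() / n]
    )


def edge_density(img: np.ndarray) -> float:
    """Fraction of pixels whose Sobel gradient magnitude exceeds mean + 1 std."""
    magnitude = sobel(img.astype(float))
    threshold = magnitude.mean() + magnitude.std()
    return float((magnitude > threshold).mean())


def extract_features(img: np.ndarray) -> np.ndarray:
    """Full 16-entry descriptor vector in canonical :data:`FEATURE_NAMES` order."""
    vec = np.concatenate(
        [
            glcm_features(img),
            first_order_stats(img),
            wavelet_energies(img),
            [edge_density(img)],
        ]
    )
    if not np.all(np.isfinite(vec)):
        bad = [FEATURE_NAMES[i] for i in np.flatnonzero(~np.isfinite(vec))]
        raise ValueError(f"non-finite feature value(s): {bad}")
    return vec


def extract_feature_table(images, labels=None) -> pd.DataFrame:
    """Extract features for a sequence of images into a canonical table."""
    rows = [extract_features(preprocess_image(im)) for im in images]
    table = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    if labels is not None:
        table["label"] = np.asarray(labels, dtype=int)
    return table


class StandardizationModel:
    """Per-feature z-scoring parameters; constant features map to zero."""

    def __init__(self, mean: np.ndarray, std: np.ndarray) -> None:
        self.mean = np.asarray(mean, dtype=float)
        self.std = np.asarray(std, dtype=float)

    def transform(self, X: np.ndarray) -> np.ndarray:
        safe = np.where(self.std > 0, self.std, 1.0)
        Z = (np.asarray(X, dtype=float) - self.mean) / safe
        return np.where(self.std > 0, Z, 0.0)

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "std": self.std.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "StandardizationModel":
        return cls(np.asarray(d["mean"]), np.asarray(d["std"]))


def _feature_matrix(table: pd.DataFrame) -> np.ndarray:
    cols = [c for c in table.columns if c != "label"]
    return table[cols].to_numpy(dtype=float)


def fit_standardizer(table: pd.DataFrame) -> StandardizationModel:
    """Fit per-column mean/std (population std) on a feature table."""
    X = _feature_matrix(table)
    if X.shape[0] < 2:
        raise ValueError("standardization requires at least 2 rows")
    return StandardizationModel(X.mean(axis=0), X.std(axis=0))


def apply_standardizer(model: StandardizationModel, table: pd.DataFrame) -> pd.DataFrame:
    """Z-transform a table with a fitted model, preserving any label column."""
    cols = [c for c in table.columns if c != "label"]
    out = pd.DataFrame(model.transform(table[cols].to_numpy(dtype=float)), columns=cols)
    if "label" in table.columns:
        out["label"] = table["label"].to_numpy()
    return out


def save_feature_table(table: pd.DataFrame, path) -> None:
    # pandas' default float formatting is the shortest round-tripping repr
    table.to_csv(path, index=False)


def load_feature_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in FEATURE_NAMES if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    return table
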