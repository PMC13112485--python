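"""Seeded synthetic inputs: two-class feature tables and phantom MRI images.

Two generators cover the two entry points of the pipeline:

* :func:`simulate_feature_table` emulates the 16-descriptor feature
  table directly as a two-class Gaussian mixture with controllable
  class-mean separation, skipping image analysis entirely.
* :func:`simulate_phantoms` emulates the discriminative structure of the
  MRI benchmark at the pixel level: healthy phantoms are bright with
  strong fine-scale texture (high GLCM contrast), tumor phantoms are
  dimmer, smoother, and carry a dark smooth blob. Running the feature
  extractor on these phantoms therefore reproduces the direction of the
  real data's strongest discriminators (intensity mean and GLCM
  contrast both higher for healthy).

Everything is a deterministic function of its config and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .features import FEATURE_NAMES

__all__ = [
    "FeatureSimConfig",
    "PhantomSimConfig",
    "simulate_feature_table",
    "simulate_phantoms",
]


@dataclass
class FeatureSimConfig:
    """Two-class Gaussian feature-table generator settings.

    ``separation`` is the Euclidean distance between the class means in
    units of the per-dimension noise standard deviation; it is spread
    evenly over the ``n_informative`` leading dimensions so the total
    class-mean distance is ``separation * noise_std`` regardless of how
    many dimensions carry signal.
    """

    n_healthy: int = 100
    n_tumor: int = 100
    separation: float = 3.0
    n_informative: int = 6
    noise_std: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_informative <= 16:
            raise ValueError("n_informative must be in [1, 16]")
        if self.separation < 0:
            raise ValueError("separation must be non-negative")
        if self.noise_std <= 0:
            raise ValueError("noise_std must be positive")


def simulate_feature_table(config: FeatureSimConfig) -> pd.DataFrame:
    """Class-conditional Gaussian rows with the 16 canonical feature columns."""
    rng = np.random.default_rng(config.seed)
    d = len(FEATURE_NAMES)
    shift = np.zeros(d)
    per_dim = config.separation * config.noise_std / np.sqrt(config.n_informative)
    shift[: config.n_informative] = per_dim
    healthy = rng.normal(0.0, config.noise_std, size=(config.n_healthy, d))
    tumor = rng.normal(0.0, config.noise_std, size=(config.n_tumor, d)) + shift
    table = pd.DataFrame(np.vstack([healthy, tumor]), columns=list(FEATURE_NAMES))
    table["label"] = np.concatenate(
        [np.zeros(config.n_healthy, dtype=int), np.ones(config.n_tumor, dtype=int)]
    )
    return table


@dataclass
class PhantomSimConfig:
    """Phantom image generator settings (intensities on the 0-255 scale).

    Healthy phantoms must be brighter and more textured than tumor
    phantoms; the defaults satisfy that with a wide margin.
    """

    n_healthy: int = 20
    n_tumor: int = 20
    size: int = 256
    healthy_mean: float = 180.0
    healthy_texture_amplitude: float = 45.0
    tumor_mean: float = 120.0
    tumor_texture_amplitude: float = 12.0
    blob_radius: float = 40.0
    blob_offset: float = -45.0
    texture_scale: float = 1.5
    noise_std: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.healthy_mean <= self.tumor_mean:
            raise ValueError("healthy phantoms must be brighter than tumor phantoms")
        if self.healthy_texture_amplitude <= self.tumor_texture_amplitude:
            raise ValueError("healthy phantoms must be more textured than tumor phantoms")


def _texture(rng: np.random.Generator, size: int, amplitude: float, scale: float) -> np.ndarray:
    """Band-limited noise: smoothed white noise rescaled to unit std, then amplified."""
    noise = gaussian_filter(rng.standard_normal((size, size)), sigma=scale)
    std = noise.std()
    if std > 0:
        noise /= std
    return amplitude * noise


def _phantom(rng: np.random.Generator, config: PhantomSimConfig, tumor: bool) -> np.ndarray:
    size = config.size
    if tumor:
        img = config.tumor_mean + _texture(
            rng, size, config.tumor_texture_amplitude, config.texture_scale
        )
        # dark smooth blob near the center of the field
        cy, cx = rng.uniform(0.35 * size, 0.65 * size, size=2)
        yy, xx = np.mgrid[0:size, 0:size]
        r2 = (yy - cy) ** 2 + (xx - cx) ** 2
        img += config.blob_offset * np.exp(-r2 / (2.0 * config.blob_radius**2))
    else:
        img = config.healthy_mean + _texture(
            rng, size, config.healthy_texture_amplitude, config.texture_scale
        )
    img += rng.normal(0.0, config.noise_std, size=(size, size))
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def simulate_phantoms(config: PhantomSimConfig) -> tuple[list[np.ndarray], np.ndarray]:
    """Generate phantom images and their labels (0 healthy, 1 tumor)."""
    rng = np.random.default_rng(config.seed)
    images = [_phantom(rng, config, tumor=False) for _ in range(config.n_healthy)]
    images += [_phantom(rng, config, tumor=True) for _ in range(config.n_tumor)]
    labels = np.concatenate(
        [np.zeros(config.n_healthy, dtype=int), np.ones(config.n_tumor, dtype=int)]
    )
    return images, labels
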