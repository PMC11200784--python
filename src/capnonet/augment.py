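"""Training-set augmentation: Gaussian pixel noise and elastic deformation.

Policy: each training image contributes itself, one Gaussian-noised copy
(mean 0, variance 15 in 8-bit intensity units²), and one elastically
deformed copy (alpha 200, sigma 20, alpha_affine 10 pixels), expanding the
training set to exactly three times its size.  Augmentation is applied to
training folds only; validation images never pass through these operators.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

__all__ = [
    "NoiseParams",
    "ElasticParams",
    "add_gaussian_noise",
    "elastic_transform",
    "expand_training_set",
]


@dataclasses.dataclass(frozen=True)
class NoiseParams:
    """Gaussian pixel-noise parameters in 8-bit intensity units."""

    mean: float = 0.0
    variance: float = 15.0

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError("variance must be >= 0")


@dataclasses.dataclass(frozen=True)
class ElasticParams:
    """Elastic-deformation parameters, all in pixels.

    ``alpha`` scales the smoothed random displacement field, ``sigma`` is the
    Gaussian smoothing width of that field, and ``alpha_affine`` bounds the
    random perturbation of the three affine anchor points.
    """

    alpha: float = 200.0
    sigma: float = 20.0
    alpha_affine: float = 10.0

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.alpha_affine < 0:
            raise ValueError("alpha and alpha_affine must be >= 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


def add_gaussian_noise(
    img: np.ndarray, params: NoiseParams = NoiseParams(), seed: int = 0
) -> np.ndarray:
    """Add i.i.d. Gaussian noise per pixel, round and clip back to uint8."""
    rng = np.random.default_rng(seed)
    if params.variance == 0 and params.mean == 0:
        return img.copy()
    noise = rng.normal(params.mean, np.sqrt(params.variance), size=img.shape)
    out = np.rint(img.astype(float) + noise)
    return np.clip(out, 0, 255).astype(np.uint8)


def elastic_transform(
    img: np.ndarray, params: ElasticParams = ElasticParams(), seed: int = 0
) -> np.ndarray:
    """Elastic deformation with a random affine component.

    (1) Per-pixel displacement fields dx, dy ~ U(-1, 1) are smoothed with a
    Gaussian kernel of width ``sigma`` and scaled by ``alpha``; (2) a random
    affine map is obtained by perturbing three anchor corner points by
    U(-alpha_affine, alpha_affine) pixels; (3) the image is resampled with
    bilinear interpolation and reflected borders.  Seeded and deterministic.
    """
    rng = np.random.default_rng(seed)
    h, w = img.shape
    src = np.float64([[0, 0], [w - 1, 0], [0, h - 1]])  # anchor corners (x, y)
    dst = src + rng.uniform(-params.alpha_affine, params.alpha_affine, size=src.shape)
    dx = params.alpha * ndimage.gaussian_filter(
        rng.uniform(-1, 1, size=img.shape), params.sigma
    )
    dy = params.alpha * ndimage.gaussian_filter(
        rng.uniform(-1, 1, size=img.shape), params.sigma
    )

    # affine (x', y') = M [x, y, 1] solved from the three anchor pairs
    ones = np.ones((3, 1))
    M = np.linalg.solve(np.hstack([src, ones]), dst).T  # 2x3
    yy, xx = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float),
                         indexing="ij")
    xa = M[0, 0] * xx + M[0, 1] * yy + M[0, 2]
    ya = M[1, 0] * xx + M[1, 1] * yy + M[1, 2]
    coords = np.stack([ya + dy, xa + dx])  # (row, col) sample positions
    out = ndimage.map_coordinates(
        img.astype(float), coords, order=1, mode="reflect"
    )
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def expand_training_set(
    images: list[np.ndarray],
    labels: list,
    seed: int = 0,
    noise: NoiseParams = NoiseParams(),
    elastic: ElasticParams = ElasticParams(),
) -> tuple[list[np.ndarray], list]:
    """Expand a training set to exactly 3× its size.

    Output order: all originals, then one noised copy of each, then one
    elastically deformed copy of each; labels carried over per source image.
    """
    if not images:
        raise ValueError("cannot augment an empty training set")
    if len(images) != len(labels):
        raise ValueError("images and labels must have equal length")
    rng = np.random.default_rng(seed)
    noise_seeds = rng.integers(0, 2**31, size=len(images))
    elastic_seeds = rng.integers(0, 2**31, size=len(images))
    out_images = [img.copy() for img in images]
    out_labels = list(labels)
    for img, s in zip(images, noise_seeds):
        out_images.append(add_gaussian_noise(img, noise, seed=int(s)))
    out_labels.extend(labels)
    for img, s in zip(images, elastic_seeds):
        out_images.append(elastic_transform(img, elastic, seed=int(s)))
    out_labels.extend(labels)
    return out_images, out_labels
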