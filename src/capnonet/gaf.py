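"""Gramian angular field encoding of breath sequences.

A series ``x`` is min-max normalized to ``[-1, 1]``,

    x̃_i = 2 (x_i - min X) / (max X - min X) - 1,

then mapped to polar coordinates, φ_i = arccos x̃_i and r_i = t_i / N with
t_i = i + 1 (the radius preserves temporal order but does not enter the
matrices).  Two Gramian images follow:

    GASF[i, j] = cos(φ_i + φ_j)   (summation field, symmetric)
    GADF[i, j] = sin(φ_i - φ_j)   (difference field, antisymmetric)

which admit the equivalent matrix forms x̃ᵀx̃ - √(1-x̃²)ᵀ√(1-x̃²) and
√(1-x̃²)ᵀx̃ - x̃ᵀ√(1-x̃²).  Entries in [-1, 1] are quantized linearly to
8-bit grayscale for the CNN.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "PolarSeries",
    "normalize_minmax",
    "to_polar",
    "gasf_matrix",
    "gadf_matrix",
    "quantize_gray",
    "encode_image",
]

_DOMAIN_TOL = 1e-12


@dataclasses.dataclass(frozen=True)
class PolarSeries:
    """Polar encoding of a normalized series: angles φ ∈ [0, π], radii t_i/N."""

    phi: np.ndarray
    r: np.ndarray


def normalize_minmax(values: np.ndarray) -> np.ndarray:
    """Min-max normalize to [-1, 1]; endpoints map exactly to ±1.

    Raises on a constant series (degenerate breath: the normalization
    denominator vanishes).
    """
    x = np.asarray(values, dtype=float)
    lo, hi = x.min(), x.max()
    if hi <= lo:
        raise ValueError("cannot normalize a constant series (max == min)")
    out = 2.0 * (x - lo) / (hi - lo) - 1.0
    # guard rounding at the endpoints so arccos stays in-domain
    return np.clip(out, -1.0, 1.0)


def to_polar(norm: np.ndarray) -> PolarSeries:
    """Angles φ_i = arccos x̃_i and radii r_i = (i + 1) / n."""
    x = np.asarray(norm, dtype=float)
    if x.min() < -1.0 - _DOMAIN_TOL or x.max() > 1.0 + _DOMAIN_TOL:
        raise ValueError("normalized values must lie in [-1, 1]")
    x = np.clip(x, -1.0, 1.0)
    n = len(x)
    return PolarSeries(phi=np.arccos(x), r=np.arange(1, n + 1) / n)


def gasf_matrix(polar: PolarSeries) -> np.ndarray:
    """Gramian angular summation field: entry (i, j) = cos(φ_i + φ_j)."""
    phi = polar.phi
    return np.cos(phi[:, None] + phi[None, :])


def gadf_matrix(polar: PolarSeries) -> np.ndarray:
    """Gramian angular difference field: entry (i, j) = sin(φ_i - φ_j)."""
    phi = polar.phi
    return np.sin(phi[:, None] - phi[None, :])


def gasf_outer_form(norm: np.ndarray) -> np.ndarray:
    """Matrix form x̃ᵀ·x̃ - √(1-x̃²)ᵀ·√(1-x̃²) (cross-check for the angle form)."""
    x = np.asarray(norm, dtype=float)
    s = np.sqrt(np.clip(1.0 - x**2, 0.0, None))
    return np.outer(x, x) - np.outer(s, s)


def gadf_outer_form(norm: np.ndarray) -> np.ndarray:
    """Matrix form √(1-x̃²)ᵀ·x̃ - x̃ᵀ·√(1-x̃²) (cross-check for the angle form)."""
    x = np.asarray(norm, dtype=float)
    s = np.sqrt(np.clip(1.0 - x**2, 0.0, None))
    return np.outer(s, x) - np.outer(x, s)


def quantize_gray(matrix: np.ndarray) -> np.ndarray:
    """Linear map [-1, 1] → [0, 255], rounded half-to-even, as uint8."""
    m = np.asarray(matrix, dtype=float)
    if m.min() < -1.0 - _DOMAIN_TOL or m.max() > 1.0 + _DOMAIN_TOL:
        raise ValueError("GAF entries must lie in [-1, 1]")
    levels = np.rint((np.clip(m, -1.0, 1.0) + 1.0) * (255.0 / 2.0))
    return levels.astype(np.uint8)


def encode_image(values: np.ndarray, kind: str = "gasf") -> np.ndarray:
    """Encode a breath series as an 8-bit grayscale GAF image.

    ``kind`` is ``"gasf"`` or ``"gadf"``.  A 224-sample input yields a
    224×224 image.
    """
    polar = to_polar(normalize_minmax(values))
    if kind == "gasf":
        mat = gasf_matrix(polar)
    elif kind == "gadf":
        mat = gadf_matrix(polar)
    else:
        raise ValueError(f"kind must be 'gasf' or 'gadf', got {kind!r}")
    return quantize_gray(mat)
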