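"""File formats: raw record CSV, cohort manifest CSV, 8-bit grayscale PNG, run config.

All writers are deterministic — identical inputs produce byte-identical files
(fixed CSV float formatting, PNG without timestamps or ancillary chunks).
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from PIL import Image

__all__ = [
    "read_raw_record",
    "write_raw_record",
    "read_manifest",
    "write_gray_png",
    "read_gray_png",
    "load_config",
    "dump_config",
]

RAW_COLUMNS = ("t", "co2", "flow")
MANIFEST_COLUMNS = ("subject_id", "label", "grade", "record_path")


class FormatError(ValueError):
    """Raised when a file does not match the expected on-disk format."""


def validate_raw_record(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a raw record: columns, length, finiteness, monotone time."""
    for col in RAW_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"raw record missing column {col!r}")
    df = df.loc[:, list(RAW_COLUMNS)]
    if len(df) < 8:
        raise FormatError(f"raw record too short: {len(df)} samples (< 8)")
    arr = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(arr)):
        raise FormatError("raw record contains non-finite values")
    t = arr[:, 0]
    if not np.all(np.diff(t) > 0):
        raise FormatError("raw record time column must be strictly increasing")
    return df


def read_raw_record(path: str | Path) -> pd.DataFrame:
    """Read and validate a raw record CSV with header ``t,co2,flow``."""
    df = pd.read_csv(path)
    return validate_raw_record(df)


def write_raw_record(df: pd.DataFrame, path: str | Path) -> None:
    """Write a raw record CSV (header ``t,co2,flow``, 9 significant digits)."""
    df.loc[:, list(RAW_COLUMNS)].to_csv(path, index=False, float_format="%.9g")


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in MANIFEST_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"manifest missing column {col!r}")
    return df


def _validate_gray(pixels: np.ndarray) -> np.ndarray:
    pixels = np.asarray(pixels)
    if pixels.ndim != 2 or pixels.shape[0] != pixels.shape[1]:
        raise ValueError(f"grayscale image must be square 2-D, got {pixels.shape}")
    if pixels.min() < 0 or pixels.max() > 255:
        raise ValueError(
            f"intensities must lie in [0, 255], got range "
            f"[{pixels.min()}, {pixels.max()}]"
        )
    return pixels.astype(np.uint8)


def write_gray_png(pixels: np.ndarray, path: str | Path) -> None:
    """Write a single-channel 8-bit grayscale PNG; read-back is exact."""
    img = Image.fromarray(_validate_gray(pixels), mode="L")
    img.save(path, format="PNG", optimize=False)


def read_gray_png(path: str | Path) -> np.ndarray:
    with Image.open(path) as img:
        if img.mode != "L":
            raise FormatError(f"expected 8-bit grayscale PNG, got mode {img.mode!r}")
        return np.asarray(img, dtype=np.uint8)


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError("run config must be a mapping")
    return cfg


def dump_config(cfg: dict[str, Any], path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
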