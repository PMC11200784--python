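"""Raw capnogram → standardized 224-sample CO2-vs-volume breath sequences.

Pipeline: temporal alignment and resampling to a uniform 200 Hz grid,
zero-phase third-order Butterworth low-pass filtering, exhalation
segmentation on the expiratory-flow signal, conversion to the volume domain
by trapezoidal integration of flow, and piecewise aggregate approximation
(PAA) down to a fixed 224-sample series.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import integrate, signal

logger = logging.getLogger(__name__)

__all__ = [
    "AlignedRecord",
    "BreathSegment",
    "VCapCurve",
    "align_resample",
    "lowpass_filter",
    "segment_exhalations",
    "to_volume_domain",
    "paa_reduce",
    "preprocess_record",
]

PAA_LENGTH = 224
MIN_SEGMENT_SAMPLES = 16
MIN_CO2_RISE = 1.0  # % CO2; gates out degenerate "breaths"
FLOW_THRESHOLD = 0.02  # L/s


@dataclasses.dataclass(frozen=True)
class AlignedRecord:
    """Uniformly sampled, temporally aligned CO2 and flow."""

    rate: float
    co2: np.ndarray
    flow: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        if len(self.co2) != len(self.flow):
            raise ValueError("co2 and flow must have equal length")

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.co2)) / self.rate


@dataclasses.dataclass(frozen=True)
class BreathSegment:
    """Index range (inclusive start, exclusive end) of one exhalation."""

    start_idx: int
    end_idx: int

    def __post_init__(self) -> None:
        if not 0 <= self.start_idx < self.end_idx:
            raise ValueError("need 0 <= start_idx < end_idx")


@dataclasses.dataclass(frozen=True)
class VCapCurve:
    """CO2 (%) paired with cumulative exhaled volume (mL) for one breath."""

    volume: np.ndarray
    co2: np.ndarray

    def __post_init__(self) -> None:
        if len(self.volume) != len(self.co2):
            raise ValueError("volume and co2 must have equal length")
        if len(self.volume) and abs(self.volume[0]) > 1e-9:
            raise ValueError("volume must start at 0")
        if np.any(np.diff(self.volume) < -1e-9):
            raise ValueError("volume must be non-decreasing")


def align_resample(raw: pd.DataFrame, rate: float = 200.0) -> AlignedRecord:
    """Linearly interpolate CO2 and flow onto a shared uniform grid.

    The grid spans the record's own time range (endpoints clamped), so no
    extrapolation occurs.
    """
    t = raw["t"].to_numpy(dtype=float)
    if t[-1] - t[0] < 0.1:
        raise ValueError(f"record duration {t[-1] - t[0]:.3f} s too short (< 0.1 s)")
    n = int(np.floor((t[-1] - t[0]) * rate)) + 1
    grid = t[0] + np.arange(n) / rate
    co2 = np.interp(grid, t, raw["co2"].to_numpy(dtype=float))
    flow = np.interp(grid, t, raw["flow"].to_numpy(dtype=float))
    return AlignedRecord(rate=rate, co2=co2, flow=flow, t0=float(t[0]))


def lowpass_filter(
    rec: AlignedRecord, order: int = 3, cutoff_hz: float = 10.0
) -> AlignedRecord:
    """Zero-phase Butterworth low-pass on both channels.

    Applied forward-backward (``filtfilt``) so breath morphology — in
    particular the phase II/III slopes — is not phase-distorted; the
    effective magnitude response is the squared Butterworth magnitude.
    """
    if cutoff_hz >= rec.rate / 2:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must be below Nyquist {rec.rate / 2} Hz"
        )
    sos = signal.butter(order, cutoff_hz, btype="low", fs=rec.rate, output="sos")
    co2 = signal.sosfiltfilt(sos, rec.co2)
    flow = signal.sosfiltfilt(sos, rec.flow)
    return AlignedRecord(rate=rec.rate, co2=co2, flow=flow, t0=rec.t0)


def segment_exhalations(
    rec: AlignedRecord,
    flow_threshold: float = FLOW_THRESHOLD,
    min_len: int = MIN_SEGMENT_SAMPLES,
    min_rise: float = MIN_CO2_RISE,
) -> list[BreathSegment]:
    """Detect exhalations as maximal positive-flow runs.

    Each run of ``flow > flow_threshold`` is trimmed to start at the CO2
    trough immediately preceding the run and to end at the CO2 peak
    (end-tidal point) inside the run.  Runs shorter than ``min_len`` samples
    or with CO2 rise below ``min_rise`` % are discarded as invalid breaths.
    """
    above = rec.flow > flow_threshold
    if not above.any():
        return []
    edges = np.diff(above.astype(np.int8))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    ends = list(np.nonzero(edges == -1)[0] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(above))

    segments: list[BreathSegment] = []
    prev_end = 0
    for run_start, run_end in zip(starts, ends):
        # last CO2 trough before the run: local minimum over the quiet gap
        gap = rec.co2[prev_end:run_start + 1]
        start = prev_end + int(np.argmin(gap)) if len(gap) else run_start
        # end-tidal point: CO2 maximum within the run
        end = run_start + int(np.argmax(rec.co2[run_start:run_end])) + 1
        prev_end = run_end
        if end - start < min_len:
            continue
        rise = float(rec.co2[start:end].max() - rec.co2[start])
        if rise < min_rise:
            continue
        segments.append(BreathSegment(start, end))
    return segments


def to_volume_domain(rec: AlignedRecord, seg: BreathSegment) -> VCapCurve:
    """CO2 vs cumulative exhaled volume (mL) over one segment.

    Volume is the cumulative trapezoidal integral of flow from the segment
    start.  Negative flow inside the segment is clipped to zero (volume must
    not decrease during exhalation) with a logged warning.
    """
    if seg.end_idx > len(rec.co2):
        raise ValueError("segment extends past record end")
    flow = rec.flow[seg.start_idx : seg.end_idx]
    if np.any(flow < 0):
        logger.warning(
            "clipped %d negative flow samples inside exhalation segment",
            int(np.sum(flow < 0)),
        )
        flow = np.maximum(flow, 0.0)
    dt = 1.0 / rec.rate
    vol_ml = integrate.cumulative_trapezoid(flow * 1000.0, dx=dt, initial=0.0)
    return VCapCurve(volume=vol_ml, co2=rec.co2[seg.start_idx : seg.end_idx].copy())


def paa_reduce(values: np.ndarray, m: int = PAA_LENGTH) -> np.ndarray:
    """Piecewise aggregate approximation to exactly ``m`` values.

    For input length ``n >= m``, output value ``j`` is the mean of the samples
    in frame ``j``, the frames partitioning ``[0, n)`` with exact width
    ``n / m``; samples straddling a boundary contribute fractionally to both
    frames, so no sample is dropped.  For ``n < m`` the series is linearly
    interpolated up to length ``m``.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError(f"need at least 2 samples for PAA, got {n}")
    if n == m:
        return x.copy()
    if n < m:
        return np.interp(np.linspace(0, n - 1, m), np.arange(n), x)
    # fractional overlap of sample i = [i, i+1) with frame j = [j*w, (j+1)*w)
    w = n / m
    bounds = np.arange(m + 1) * w
    out = np.empty(m)
    csum = np.concatenate([[0.0], np.cumsum(x)])

    def partial(b: float) -> float:
        """Integral of the piecewise-constant series over [0, b)."""
        i = int(np.floor(b))
        if i >= n:
            return csum[n]
        return csum[i] + (b - i) * x[i]

    for j in range(m):
        out[j] = (partial(bounds[j + 1]) - partial(bounds[j])) / w
    return out


def curve_values(curve: VCapCurve) -> np.ndarray:
    """The CO2 samples of a curve in volume (= exhalation time) order."""
    return curve.co2


def preprocess_record(
    raw: pd.DataFrame,
    rate: float = 200.0,
    cutoff_hz: float = 10.0,
    m: int = PAA_LENGTH,
) -> list[np.ndarray]:
    """Full preprocessing of a raw record: one 224-sample series per breath.

    Composition: align/resample → low-pass → segment exhalations → volume
    domain → PAA.  Returns an empty list when no valid breath is found.
    """
    rec = lowpass_filter(align_resample(raw, rate=rate), cutoff_hz=cutoff_hz)
    series = []
    for seg in segment_exhalations(rec):
        curve = to_volume_domain(rec, seg)
        series.append(paa_reduce(curve_values(curve), m=m))
    return series
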