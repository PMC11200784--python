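"""Synthetic volumetric-capnogram cohorts with GOLD-graded obstruction severity.

A volumetric capnogram (CO2 concentration vs cumulative exhaled volume) has
three phases: a near-zero dead-space baseline (phase I), a sigmoidal ascending
branch where dead-space and alveolar gas mix (phase II), and an alveolar
plateau (phase III) whose slope steepens with airflow obstruction.  The
generator produces raw device-style records (time, CO2 %, expiratory flow)
whose noise-free CO2-vs-volume shape is

    co2(v) = A * s(v) + m * max(v - v_d, 0) / 1000,
    s(v)   = 1 / (1 + exp(-k * (v - v_d))),

with v in mL, dead-space volume ``v_d``, phase II steepness ``k`` (1/mL),
phase III slope ``m`` (% CO2 per L), and ``A`` fixed so the curve reaches the
prescribed end-tidal CO2 at end of exhalation.  Flow is a non-negative
half-sine whose integral equals the tidal volume.  Severity is expressed by a
steeper phase III slope and a shallower phase II — the two capnographic
features that track obstruction.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GRADES",
    "BreathParams",
    "CohortConfig",
    "grade_morphology",
    "simulate_breath",
    "simulate_cohort",
]

#: Recognised class labels, ordered by increasing obstruction severity.
GRADES = ("normal", "GOLD1", "GOLD2", "GOLD3", "GOLD4")


@dataclasses.dataclass(frozen=True)
class BreathParams:
    """Physiological parameters of one simulated exhalation.

    Parameters
    ----------
    dead_space_volume : float
        Anatomical dead-space volume in mL; exhaled first with near-zero CO2.
    tidal_volume : float
        Total exhaled volume in mL.
    etco2 : float
        End-tidal CO2 concentration in %.
    phase2_steepness : float
        Sigmoid slope of the ascending branch, per mL.
    phase3_slope : float
        Alveolar-plateau slope in % CO2 per L.
    exhale_duration : float
        Exhalation length in seconds.
    noise_sd : float
        Standard deviation of additive Gaussian device noise on CO2, in %.
    sample_rate : float
        Device sampling rate in Hz.
    """

    dead_space_volume: float
    tidal_volume: float
    etco2: float
    phase2_steepness: float
    phase3_slope: float
    exhale_duration: float
    noise_sd: float = 0.05
    sample_rate: float = 80.0

    def __post_init__(self) -> None:
        if not 0 < self.dead_space_volume < self.tidal_volume:
            raise ValueError(
                "dead_space_volume must satisfy 0 < dead_space_volume < tidal_volume, "
                f"got {self.dead_space_volume} vs tidal {self.tidal_volume}"
            )
        if not 0 < self.etco2 <= 10:
            raise ValueError(f"etco2 must be in (0, 10] % CO2, got {self.etco2}")
        if self.phase3_slope < 0:
            raise ValueError("phase3_slope must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")
        if self.exhale_duration <= 0:
            raise ValueError("exhale_duration must be > 0")
        if self.phase2_steepness <= 0:
            raise ValueError("phase2_steepness must be > 0")


@dataclasses.dataclass(frozen=True)
class CohortConfig:
    """Layout of a synthetic cohort: classes, sizes and the master seed."""

    n_per_class: int
    class_set: Sequence[str] = GRADES
    breaths_per_subject: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.breaths_per_subject < 1:
            raise ValueError("breaths_per_subject must be >= 1")
        for grade in self.class_set:
            if grade not in GRADES:
                raise ValueError(
                    f"unknown grade {grade!r}; expected one of {GRADES}"
                )


# Baseline morphology per grade.  Severity raises the plateau slope (%/L),
# flattens phase II, prolongs exhalation and mildly raises EtCO2 (air
# trapping); dead space and tidal volume are held fixed so slope/steepness
# remain the discriminating features.
_GRADE_TABLE = {
    #         vd     VT   etco2     k   slope    T
    "normal": (150.0, 500.0, 5.0, 0.200, 0.4, 2.0),
    "GOLD1": (150.0, 500.0, 5.2, 0.150, 0.9, 2.2),
    "GOLD2": (150.0, 500.0, 5.4, 0.115, 1.6, 2.4),
    "GOLD3": (150.0, 500.0, 5.7, 0.085, 2.5, 2.7),
    "GOLD4": (150.0, 500.0, 6.0, 0.060, 3.6, 3.0),
}


def grade_morphology(grade: str) -> BreathParams:
    """Deterministic baseline breath parameters for a severity grade.

    Phase III slope strictly increases and phase II steepness strictly
    decreases from ``normal`` to ``GOLD4``.
    """
    try:
        vd, vt, etco2, k, slope, dur = _GRADE_TABLE[grade]
    except KeyError:
        raise ValueError(
            f"unknown grade {grade!r}; expected one of {GRADES}"
        ) from None
    return BreathParams(
        dead_space_volume=vd,
        tidal_volume=vt,
        etco2=etco2,
        phase2_steepness=k,
        phase3_slope=slope,
        exhale_duration=dur,
    )


def co2_of_volume(volume_ml: np.ndarray, params: BreathParams) -> np.ndarray:
    """Noise-free CO2 concentration (%) at cumulative exhaled volume (mL)."""
    v = np.asarray(volume_ml, dtype=float)
    k = params.phase2_steepness
    vd = params.dead_space_volume
    m_ml = params.phase3_slope / 1000.0  # % per mL
    sig = 1.0 / (1.0 + np.exp(-k * (v - vd)))
    ramp = m_ml * np.maximum(v - vd, 0.0)
    sig_end = 1.0 / (1.0 + np.exp(-k * (params.tidal_volume - vd)))
    amp = (params.etco2 - m_ml * (params.tidal_volume - vd)) / sig_end
    return amp * sig + ramp


def simulate_breath(params: BreathParams, seed: int = 0) -> pd.DataFrame:
    """Simulate one exhalation as a raw device record.

    Returns a DataFrame with columns ``t`` (s), ``co2`` (%), ``flow`` (L/s).
    Flow is a half-sine over the exhalation whose integral equals the tidal
    volume; short zero-flow pads precede and follow it (baseline CO2 before,
    end-tidal CO2 held after).  Gaussian noise of sd ``noise_sd`` is added to
    CO2.  Identical ``params`` and ``seed`` give identical records.
    """
    rng = np.random.default_rng(seed)
    dt = 1.0 / params.sample_rate
    dur = params.exhale_duration
    pad = max(0.2, 8 * dt)  # zero-flow margins so segmentation sees run edges

    t = np.arange(0.0, pad + dur + pad + dt / 2, dt)
    flow_lps = np.zeros_like(t)
    in_ex = (t >= pad) & (t <= pad + dur)
    tau = t[in_ex] - pad
    # half-sine with exact analytic integral = tidal volume
    peak_mlps = np.pi * params.tidal_volume / (2.0 * dur)
    flow_lps[in_ex] = peak_mlps * np.sin(np.pi * tau / dur) / 1000.0

    vol_ml = np.zeros_like(t)
    vol_ml[in_ex] = params.tidal_volume * (1 - np.cos(np.pi * tau / dur)) / 2.0
    vol_ml[t > pad + dur] = params.tidal_volume

    co2 = co2_of_volume(vol_ml, params)
    if params.noise_sd > 0:
        co2 = co2 + rng.normal(0.0, params.noise_sd, size=co2.shape)
    return pd.DataFrame({"t": t, "co2": co2, "flow": flow_lps})


def _jitter(rng: np.random.Generator, value: float, cv: float = 0.10) -> float:
    """Lognormal multiplicative jitter with the given coefficient of variation."""
    sigma = np.sqrt(np.log(1 + cv**2))
    return float(value * rng.lognormal(-sigma**2 / 2, sigma))


def subject_params(grade: str, rng: np.random.Generator) -> BreathParams:
    """Per-subject parameters: grade baseline with 10% CV lognormal jitter."""
    base = grade_morphology(grade)
    vt = _jitter(rng, base.tidal_volume)
    vd = min(_jitter(rng, base.dead_space_volume), 0.8 * vt)
    return BreathParams(
        dead_space_volume=vd,
        tidal_volume=vt,
        etco2=min(_jitter(rng, base.etco2), 10.0),
        phase2_steepness=_jitter(rng, base.phase2_steepness),
        phase3_slope=_jitter(rng, base.phase3_slope),
        exhale_duration=_jitter(rng, base.exhale_duration),
        noise_sd=base.noise_sd,
        sample_rate=base.sample_rate,
    )


def simulate_cohort(
    cfg: CohortConfig, out_dir: str | Path | None = None
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Simulate a full cohort.

    Returns ``(manifest, records)`` where ``manifest`` has one row per record
    with columns ``subject_id, label, grade, record_path`` and ``records``
    maps record path to its raw DataFrame.  ``label`` is ``normal`` or
    ``COPD`` (any GOLD grade); ``grade`` is the simulated severity class.
    When ``out_dir`` is given, record CSVs and ``manifest.csv`` are written
    there.  Same config (including seed) gives byte-identical output.
    """
    from . import vcap_io

    master = np.random.default_rng(cfg.seed)
    rows = []
    records: dict[str, pd.DataFrame] = {}
    sid = 0
    for grade in cfg.class_set:
        for _ in range(cfg.n_per_class):
            subject_id = f"S{sid:04d}"
            sid += 1
            srng = np.random.default_rng(master.integers(0, 2**31))
            params = subject_params(grade, srng)
            label = "normal" if grade == "normal" else "COPD"
            for b in range(cfg.breaths_per_subject):
                path = f"{subject_id}_b{b}.csv"
                rec = simulate_breath(params, seed=int(srng.integers(0, 2**31)))
                records[path] = rec
                rows.append(
                    {
                        "subject_id": subject_id,
                        "label": label,
                        "grade": grade,
                        "record_path": path,
                    }
                )
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for path, rec in records.items():
            vcap_io.write_raw_record(rec, out / path)
        manifest.to_csv(out / "manifest.csv", index=False)
    return manifest, records
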