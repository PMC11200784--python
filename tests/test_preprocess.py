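import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from capnonet import preprocess, synthetic
from capnonet.preprocess import (
    AlignedRecord,
    align_resample,
    lowpass_filter,
    paa_reduce,
    preprocess_record,
    segment_exhalations,
    to_volume_domain,
)


def _uniform_record(co2, flow, rate):
    n = len(co2)
    return pd.DataFrame({"t": np.arange(n) / rate, "co2": co2, "flow": flow})


class TestAlignResample:
    def test_identity_on_uniform_200hz(self, rng):
        co2 = rng.uniform(0, 6, 100)
        flow = rng.uniform(0, 1, 100)
        rec = align_resample(_uniform_record(co2, flow, 200.0), rate=200.0)
        np.testing.assert_allclose(rec.co2, co2, atol=1e-9)
        np.testing.assert_allclose(rec.flow, flow, atol=1e-9)

    def test_constant_preserved_across_rates(self):
        rec = align_resample(_uniform_record(np.full(80, 5.0), np.zeros(80), 80.0))
        assert rec.rate == 200.0
        np.testing.assert_allclose(rec.co2, 5.0, atol=1e-12)

    def test_linear_ramp_exact(self):
        t = np.arange(51) / 50.0
        raw = pd.DataFrame({"t": t, "co2": t, "flow": 0.0})
        rec = align_resample(raw, rate=200.0)
        np.testing.assert_allclose(rec.co2, rec.t, atol=1e-9)

    def test_too_short_rejected(self):
        raw = _uniform_record(np.zeros(10), np.zeros(10), 200.0)
        raw["t"] *= 0.01  # total span 0.45 ms
        with pytest.raises(ValueError, match="short"):
            align_resample(raw)


class TestLowpassFilter:
    def test_dc_gain_unity(self):
        rec = AlignedRecord(rate=200.0, co2=np.full(400, 5.0), flow=np.zeros(400))
        out = lowpass_filter(rec)
        np.testing.assert_allclose(out.co2, 5.0, atol=1e-6)

    def test_stopband_attenuation_matches_analytic_butterworth(self):
        """A 50 Hz mains tone is crushed below the two-pass analytic magnitude.

        |H(50 Hz)| = (1 + (50/10)^6)^{-1/2} per third-order Butterworth,
        squared by forward-backward application.
        """
        n = 2000
        tone = np.sin(2 * np.pi * 50 * np.arange(n) / 200.0)
        out = lowpass_filter(AlignedRecord(rate=200.0, co2=tone, flow=np.zeros(n)))
        amp = np.abs(out.co2[500:1500]).max()
        h2 = (1 + (50 / 10) ** 6) ** -1  # two-pass power response
        assert amp < 0.01
        assert amp <= h2 * 2  # steady-state bound with margin for windowing

    def test_passband_preserved(self):
        n = 2000
        tone = np.sin(2 * np.pi * 1 * np.arange(n) / 200.0)
        out = lowpass_filter(AlignedRecord(rate=200.0, co2=tone, flow=np.zeros(n)))
        amp = np.abs(out.co2[500:1500]).max()
        assert amp == pytest.approx(1.0, rel=0.01)

    def test_cutoff_at_nyquist_rejected(self):
        rec = AlignedRecord(rate=200.0, co2=np.zeros(100), flow=np.zeros(100))
        with pytest.raises(ValueError, match="Nyquist"):
            lowpass_filter(rec, cutoff_hz=100.0)


class TestSegmentation:
    def test_single_breath_covers_exhale_window(self, normal_breath_noisefree):
        params, raw = normal_breath_noisefree
        rec = lowpass_filter(align_resample(raw))
        segs = segment_exhalations(rec)
        assert len(segs) == 1
        t = rec.t
        # the simulator pads 0.2 s of zero flow before the exhalation
        lo, hi = 0.2, 0.2 + params.exhale_duration
        covered = min(t[segs[0].end_idx - 1], hi) - max(t[segs[0].start_idx], lo)
        assert covered >= 0.9 * params.exhale_duration

    def test_zero_flow_yields_no_segments(self, rng):
        rec = AlignedRecord(
            rate=200.0, co2=rng.normal(0, 0.1, 400), flow=np.zeros(400)
        )
        assert segment_exhalations(rec) == []

    def test_two_breaths_two_segments(self, normal_breath_noisefree):
        _, raw = normal_breath_noisefree
        shifted = raw.copy()
        shifted["t"] += raw["t"].iloc[-1] + 0.01
        two = pd.concat([raw, shifted], ignore_index=True)
        rec = lowpass_filter(align_resample(two))
        assert len(segment_exhalations(rec)) == 2


class TestVolumeDomain:
    def test_unit_flow_integrates_to_liter(self):
        n = 201  # 1 s at 200 Hz
        rec = AlignedRecord(rate=200.0, co2=np.linspace(0, 5, n), flow=np.ones(n))
        seg = preprocess.BreathSegment(0, n)
        curve = to_volume_domain(rec, seg)
        assert curve.volume[0] == 0.0
        assert curve.volume[-1] == pytest.approx(1000.0, rel=0.005)

    def test_zero_flow_zero_volume(self):
        rec = AlignedRecord(rate=200.0, co2=np.linspace(0, 5, 100), flow=np.zeros(100))
        curve = to_volume_domain(rec, preprocess.BreathSegment(0, 100))
        assert (curve.volume == 0).all()

    def test_linearity_in_flow(self, rng):
        flow = rng.uniform(0, 1, 150)
        rec1 = AlignedRecord(rate=200.0, co2=np.linspace(0, 5, 150), flow=flow)
        rec2 = AlignedRecord(rate=200.0, co2=np.linspace(0, 5, 150), flow=2 * flow)
        seg = preprocess.BreathSegment(0, 150)
        v1 = to_volume_domain(rec1, seg).volume[-1]
        v2 = to_volume_domain(rec2, seg).volume[-1]
        assert v2 == pytest.approx(2 * v1, rel=1e-12)

    def test_negative_flow_clipped(self, caplog):
        flow = np.ones(100)
        flow[40:45] = -0.3
        rec = AlignedRecord(rate=200.0, co2=np.linspace(0, 5, 100), flow=flow)
        with caplog.at_level("WARNING"):
            curve = to_volume_domain(rec, preprocess.BreathSegment(0, 100))
        assert np.all(np.diff(curve.volume) >= 0)
        assert any("clipped" in r.message for r in caplog.records)


class TestPAA:
    def test_exact_halves(self):
        np.testing.assert_allclose(paa_reduce([1, 2, 3, 4], 2), [1.5, 3.5])

    def test_fractional_frames(self):
        """Frame width 1.5: weights (1, 0.5 | 0.5, 1) give [4/3, 8/3]."""
        np.testing.assert_allclose(paa_reduce([1, 2, 3], 2), [4 / 3, 8 / 3])

    def test_constant_series(self):
        out = paa_reduce(np.full(1000, 3.7), 224)
        assert len(out) == 224
        np.testing.assert_allclose(out, 3.7, atol=1e-12)

    def test_upsampling_by_interpolation(self):
        out = paa_reduce([0.0, 1.0], 5)
        np.testing.assert_allclose(out, np.linspace(0, 1, 5))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            paa_reduce([1.0], 224)

    @given(
        n=st.integers(2, 40).map(lambda k: 224 * k // 28),  # keeps runtime bounded
        seed=st.integers(0, 2**16),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_mean_preserved_when_m_divides_n(self, n, seed):
        m = 4
        n = max(m, (n // m) * m)
        x = np.random.default_rng(seed).normal(size=n)
        out = paa_reduce(x, m)
        assert out.mean() == pytest.approx(x.mean(), abs=1e-9)

    @given(seed=st.integers(0, 2**16), n=st.integers(10, 300))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_monotone_input_monotone_output(self, seed, n):
        x = np.sort(np.random.default_rng(seed).normal(size=n))
        out = paa_reduce(x, 8)
        assert np.all(np.diff(out) >= -1e-12)


class TestPipeline:
    def test_normal_record_yields_224_series(self, normal_breath_noisefree):
        _, raw = normal_breath_noisefree
        series = preprocess_record(raw)
        assert len(series) >= 1
        assert all(len(s) == 224 and np.isfinite(s).all() for s in series)

    def test_deterministic(self, normal_breath_noisefree):
        _, raw = normal_breath_noisefree
        a = preprocess_record(raw)
        b = preprocess_record(raw)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_zero_flow_record_empty(self, rng):
        raw = _uniform_record(rng.normal(0, 0.05, 200), np.zeros(200), 200.0)
        assert preprocess_record(raw) == []

    def test_volume_invariant_to_device_rate(self):
        """The same breath sampled at 80 vs 200 Hz yields volumes within 1%."""
        base = dataclasses.replace(synthetic.grade_morphology("GOLD2"), noise_sd=0.0)
        finals = []
        for rate in (80.0, 200.0):
            p = dataclasses.replace(base, sample_rate=rate)
            raw = synthetic.simulate_breath(p, seed=5)
            rec = lowpass_filter(align_resample(raw))
            seg = segment_exhalations(rec)[0]
            finals.append(to_volume_domain(rec, seg).volume[-1])
        assert finals[0] == pytest.approx(finals[1], rel=0.01)
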