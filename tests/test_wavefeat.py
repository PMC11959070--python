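"""Pressure-landmark extraction and foot-to-foot transit timing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pulsesv.wavefeat import (
    PressureWaveform,
    WaveformError,
    cfpwv,
    clinical_path_length,
    detect_foot_intersecting_tangent,
    extract_bp_features,
    transit_time,
)

FS = 1000.0  # Hz


def _wave(pressure, period, n_cycles=1):
    t = np.arange(len(pressure)) / FS
    return PressureWaveform(t, np.asarray(pressure, float), period, n_cycles)


def _ramp_pulse(t0, n_cycles=1, period=1.0, base=80.0, slope=400.0,
                rise=0.1):
    """Flat baseline, linear upstroke of the given slope at t0 (per
    cycle), then a flat plateau: the tangent construction is exact."""
    t = np.arange(int(n_cycles * period * FS)) / FS
    tc = t % period
    p = base + slope * np.clip(tc - t0, 0.0, rise)
    return PressureWaveform(t, p, period, n_cycles)


class TestBPFeatures:
    def test_constant_wave(self):
        bp = extract_bp_features(_wave(np.full(1000, 90.0), 1.0))
        assert (bp.sbp, bp.dbp, bp.pp, bp.map) == (90.0, 90.0, 0.0, 90.0)

    def test_sinusoid_closed_form(self):
        t = np.arange(2000) / FS
        bp = extract_bp_features(
            _wave(100 + 20 * np.sin(2 * np.pi * t), 1.0, 2)
        )
        assert bp.sbp == pytest.approx(120.0, abs=0.01)
        assert bp.dbp == pytest.approx(80.0, abs=0.01)
        assert bp.pp == pytest.approx(40.0, abs=0.02)
        assert bp.map == pytest.approx(100.0, abs=0.1)

    def test_nonuniform_sampling_rejected(self):
        t = np.array([0.0, 0.1, 0.15, 0.4, 0.5])
        with pytest.raises(WaveformError, match="uniform"):
            PressureWaveform(t, np.ones(5), 0.5, 1)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_map_bounded_by_extremes(self, seed):
        rng = np.random.default_rng(seed)
        p = 90 + np.cumsum(rng.normal(0, 0.5, 800))
        bp = extract_bp_features(_wave(p, 0.8))
        assert bp.dbp <= bp.map <= bp.sbp
        assert bp.pp == pytest.approx(bp.sbp - bp.dbp)


class TestIntersectingTangent:
    def test_piecewise_linear_upstroke_is_exact(self):
        foot = detect_foot_intersecting_tangent(_ramp_pulse(0.10))
        assert foot == pytest.approx(0.10, abs=1e-9)

    def test_time_shift_equivariance(self):
        foot = detect_foot_intersecting_tangent(_ramp_pulse(0.15))
        assert foot == pytest.approx(0.15, abs=1e-9)

    @settings(max_examples=25, deadline=None)
    @given(scale=st.floats(0.1, 50.0), offset=st.floats(-50.0, 200.0))
    def test_affine_pressure_invariance(self, scale, offset):
        w = _ramp_pulse(0.12)
        w2 = PressureWaveform(
            w.time, scale * w.pressure + offset, w.period, w.n_cycles
        )
        f1 = detect_foot_intersecting_tangent(w)
        f2 = detect_foot_intersecting_tangent(w2)
        assert f2 == pytest.approx(f1, abs=1e-9)

    def test_half_sine_upstroke_foot_near_onset(self):
        # quarter-sine rise of amplitude 40 starting at t0=0.2, 0.1 s rise
        t = np.arange(1000) / FS
        p = np.where(
            t < 0.2, 80.0,
            np.where(t < 0.3, 80 + 40 * np.sin(np.pi * (t - 0.2) / 0.2), 120.0),
        )
        w = PressureWaveform(t, p, 1.0, 1)
        foot = detect_foot_intersecting_tangent(w)
        # brute-force oracle: steepest tangent of the analytic curve
        tt = np.linspace(0.2, 0.3, 20001)
        slopes = 40 * (np.pi / 0.2) * np.cos(np.pi * (tt - 0.2) / 0.2)
        k = np.argmax(slopes)
        oracle = tt[k] - (40 * np.sin(np.pi * (tt[k] - 0.2) / 0.2)) / slopes[k]
        # one sample of slack on the onset edge: the discrete smoothed
        # slope mixes the kink sample into the tangent estimate
        assert 0.2 - 1.0 / FS <= foot <= 0.22
        assert foot == pytest.approx(oracle, abs=0.005)

    def test_no_upstroke_rejected(self):
        falling = _wave(np.linspace(120, 80, 1000), 1.0)
        with pytest.raises(WaveformError):
            detect_foot_intersecting_tangent(falling)


class TestTransitTime:
    def test_pure_delay_recovered(self):
        prox = _ramp_pulse(0.10, n_cycles=10)
        dist = _ramp_pulse(0.16, n_cycles=10)
        res = transit_time(prox, dist)
        assert res.n_cycles_used == 10
        assert res.mean_delta_t == pytest.approx(0.060, abs=1.0 / FS)

    def test_fewer_than_min_cycles_rejected(self):
        with pytest.raises(WaveformError, match="cycles"):
            transit_time(_ramp_pulse(0.1, 4), _ramp_pulse(0.16, 4))

    def test_zero_delay_is_degenerate(self):
        w = _ramp_pulse(0.1, 10)
        with pytest.raises(WaveformError, match="usable"):
            transit_time(w, w)

    def test_jittered_delays_average_inside_band(self):
        rng = np.random.default_rng(3)
        delays = rng.uniform(0.055, 0.065, 10)
        t = np.arange(int(10 * FS)) / FS
        prox = _ramp_pulse(0.10, 10)
        p = np.empty_like(t)
        for k in range(10):
            tc = t[int(k * FS):int((k + 1) * FS)] % 1.0
            p[int(k * FS):int((k + 1) * FS)] = 80 + 400 * np.clip(
                tc - (0.10 + delays[k]), 0.0, 0.1
            )
        dist = PressureWaveform(t, p, 1.0, 10)
        res = transit_time(prox, dist)
        assert 0.055 <= res.mean_delta_t <= 0.065
        assert res.mean_delta_t == pytest.approx(delays.mean(), abs=2.0 / FS)

    def test_delay_wrapping_across_cycle_boundary(self):
        # distal foot lands early in the *next* nominal cycle; pairing
        # must still report a positive sub-period delay
        prox = _ramp_pulse(0.92, 10)
        dist = _ramp_pulse(0.02, 10)
        res = transit_time(prox, dist)
        assert res.mean_delta_t == pytest.approx(0.10, abs=2.0 / FS)


class TestPWV:
    def test_ratio_and_scale_invariance(self):
        assert cfpwv(0.5, 0.0625) == pytest.approx(8.0)
        assert cfpwv(0.4, 0.05) == cfpwv(0.8, 0.10)
        with pytest.raises(ValueError):
            cfpwv(-0.1, 0.05)
        with pytest.raises(ValueError):
            cfpwv(0.5, 0.0)

    def test_clinical_path_length_correction(self):
        assert clinical_path_length(0.625) == pytest.approx(0.5)
        assert clinical_path_length(0.7) == pytest.approx(0.56)
        assert clinical_path_length(0.7, correction=1.0) == pytest.approx(0.7)
        with pytest.raises(ValueError):
            clinical_path_length(0.0)


class TestWaveformIO:
    def test_csv_roundtrip_preserves_metadata(self, tmp_path):
        from pulsesv.wavefeat import read_waveform_csv, write_waveform_csv

        w = _ramp_pulse(0.1, n_cycles=3)
        path = tmp_path / "wave.csv"
        write_waveform_csv(w, path)
        header = path.read_text().splitlines()[0]
        assert header.startswith("# sampling_rate_hz:")
        back = read_waveform_csv(path)
        assert back.period == pytest.approx(w.period)
        assert back.n_cycles == w.n_cycles
        assert np.allclose(back.pressure, w.pressure, atol=1e-5)

    def test_minima_segmenter_recovers_period(self, tmp_path):
        from pulsesv.wavefeat import segment_cycles

        t = np.arange(int(6.3 * FS)) / FS
        tc = t % 0.9
        # continuous across the cycle wrap: systolic sin^2 lobe plus a
        # full-period cosine baseline sway
        p = (
            75
            + 45 * np.sin(np.pi * np.clip(tc, 0, 0.35) / 0.35) ** 2
            + 3 * np.cos(2 * np.pi * tc / 0.9)
        )
        seg = segment_cycles(t, p)
        assert seg.period == pytest.approx(0.9, abs=2.0 / FS)
        assert seg.n_cycles >= 5
        # segmented cycles start at a diastolic minimum, so foot
        # detection works per cycle
        from pulsesv.wavefeat import detect_foot_intersecting_tangent

        feet = [
            detect_foot_intersecting_tangent(seg, k) % seg.period
            for k in range(seg.n_cycles)
        ]
        assert np.std(np.asarray(feet) % seg.period) < 0.01

    def test_headerless_trace_is_segmented(self, tmp_path):
        t = np.arange(int(4.5 * FS)) / FS
        tc = t % 0.9
        p = 75 + 45 * np.sin(np.pi * np.clip(tc, 0, 0.35) / 0.35) ** 2
        path = tmp_path / "raw.csv"
        path.write_text(
            "time_s,pressure_mmHg\n"
            + "\n".join(f"{a:.6f},{b:.6f}" for a, b in zip(t, p))
            + "\n"
        )
        from pulsesv.wavefeat import read_waveform_csv

        w = read_waveform_csv(path)
        assert w.period == pytest.approx(0.9, abs=2.0 / FS)
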