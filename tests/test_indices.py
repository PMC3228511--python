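"""Per-beat index computations against brute-force and analytic oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import bisect

from lvpress import (AnalysisConfig, PressureRecording, analyze_recording,
                     compute_beat_metrics, compute_dpdt_extrema,
                     compute_lvedp, compute_lvsp, compute_tau66, compute_vmax,
                     estimate_derivative, simulate, solve_tau_exp)
from lvpress.detect import BeatAnnotation, DerivativeSeries

from conftest import clean_config

RATE = 500.0


def rec_of(samples):
    return PressureRecording(np.asarray(samples, dtype=float), RATE)


def beat(onset, dmax, peak, neg, end, rr=None):
    rr = rr if rr is not None else (end - onset) / RATE
    return BeatAnnotation(onset, dmax, peak, neg, end, rr)


def decay_beat(tau_s=0.025, lvsp=110.0, lvedp=20.0, floor=None, n_dec=250):
    """Linear upstroke to LVSP, then monoexponential decay toward ``floor``.

    Returns (recording, annotation); the -dP/dt_max fiducial sits exactly at
    the first decay sample.
    """
    floor = lvedp if floor is None else floor
    up = np.linspace(lvedp, lvsp, 11)
    t = np.arange(n_dec) / RATE
    down = floor + (lvsp - floor) * np.exp(-t / tau_s)
    p = np.concatenate([up, down[1:]])
    # onset at 0, dP/dt_max mid-upstroke, peak just before the LVSP sample,
    # -dP/dt_max fiducial exactly at the decay's first sample (P = LVSP)
    return rec_of(p), beat(0, 5, 9, 10, len(p))


class TestLvsp:
    def test_triangular_toy_beat(self):
        p = np.concatenate([np.linspace(20, 100, 21), np.linspace(100, 20, 21)[1:]])
        assert compute_lvsp(beat(0, 10, 20, 30, 41), rec_of(p)) == 100.0

    @given(st.integers(0, 10_000))
    def test_equals_bruteforce_window_max(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.normal(60, 25, 120)
        b = beat(0, 20, 50, 90, 120)
        expected = max(p[i] for i in range(20, 91))
        assert compute_lvsp(b, rec_of(p)) == expected

    def test_configured_systolic_pressures_recovered(self):
        """Noise-free simulations across the reported 99-114 mmHg span."""
        for lvsp in (99.0, 107.0, 114.0):
            rec, _ = simulate(clean_config(duration_s=10.0, lvsp_mmHg=lvsp))
            res = analyze_recording(rec)
            assert res.metrics.lvsp_mmHg.median() == pytest.approx(lvsp, abs=0.5)


class TestLvedp:
    def test_is_exactly_the_onset_sample(self, rng):
        p = rng.normal(50, 10, 100)
        b = beat(7, 20, 50, 80, 100)
        assert compute_lvedp(b, rec_of(p)) == p[7]

    def test_configured_end_diastolic_pressures_recovered(self):
        for lvedp in (17.0, 20.5, 24.0):
            rec, _ = simulate(clean_config(
                duration_s=10.0, lvedp_mmHg=lvedp,
                diastolic_floor_mmHg=lvedp - 6.0))
            res = analyze_recording(rec)
            assert res.metrics.lvedp_mmHg.median() == pytest.approx(lvedp, abs=0.5)


class TestDpdtExtrema:
    def test_symmetric_triangle_has_equal_extrema(self):
        p = np.concatenate([np.linspace(20, 100, 21), np.linspace(100, 20, 21)[1:]])
        r = rec_of(p)
        d = estimate_derivative(r)
        up, down = compute_dpdt_extrema(beat(0, 10, 20, 30, 41), d)
        assert up == pytest.approx(down)

    def test_sine_extrema_match_analytic(self):
        t = np.arange(0, 1.0, 1 / RATE)
        f, amp = 4.0, 50.0
        r = rec_of(60 + amp * np.sin(2 * np.pi * f * t))
        d = estimate_derivative(r)
        i_up = int(np.argmax(d.values[2:-2])) + 2
        i_dn = int(np.argmin(d.values[2:-2])) + 2
        up, down = compute_dpdt_extrema(beat(0, i_up, 60, i_dn, len(t)), d)
        assert up == pytest.approx(2 * np.pi * f * amp, rel=1e-3)
        assert down == pytest.approx(2 * np.pi * f * amp, rel=1e-3)


class TestVmax:
    def test_invariant_to_uniform_pressure_scaling(self):
        rec, _ = simulate(clean_config(duration_s=6.0))
        d = estimate_derivative(rec)
        from lvpress import detect_beats
        ann = detect_beats(rec, d)
        b = ann[2]
        v1 = compute_vmax(b, rec, d, pressure_floor=1e-6)
        scaled = rec_of(3.0 * rec.samples)
        d3 = estimate_derivative(scaled)
        v3 = compute_vmax(b, scaled, d3, pressure_floor=1e-6)
        assert v3 == pytest.approx(v1, rel=1e-9)

    def test_matches_dense_grid_oracle_on_template(self):
        """Sampled V_max agrees with a dense evaluation of (dP/dt)/P on the
        analytic template."""
        from lvpress.template import BeatParams, BeatGeometry
        geo = BeatGeometry(BeatParams(110.0, 20.0, 14.0, 3000.0, 2500.0, 0.03))
        oracle = geo.vmax(grid_hz=100_000.0)
        rec, _ = simulate(clean_config(duration_s=10.0, lvsp_mmHg=110.0))
        res = analyze_recording(rec)
        assert res.metrics.vmax_per_s.median() == pytest.approx(oracle, rel=0.02)

    def test_nonpositive_window_flags_not_crashes(self):
        p = np.concatenate([np.full(20, -5.0), np.linspace(-5, 100, 30)])
        b = beat(0, 25, 40, 45, 50)
        r = rec_of(p)
        v = compute_vmax(b, r, estimate_derivative(r))
        assert np.isfinite(v) or np.isnan(v)


class TestTau66:
    def test_monoexponential_matches_analytic_crossing(self):
        """P = 20 + 90 exp(-t/25 ms): target 50.6 mmHg, crossing at
        25*ln(90/30.6) ~ 26.97 ms; bisection oracle agrees."""
        r, b = decay_beat(tau_s=0.025)
        tau = compute_tau66(b, r)
        expected = 25.0 * np.log(90.0 / 30.6)
        assert tau == pytest.approx(expected, abs=0.2)

        f = lambda t_ms: 20 + 90 * np.exp(-t_ms / 25.0) - (110 - 0.66 * 90)
        assert bisect(f, 1.0, 200.0, xtol=1e-9) == pytest.approx(expected,
                                                                 abs=1e-6)

    def test_linear_decay_gives_two_thirds_of_duration(self):
        up = np.linspace(20, 110, 11)
        down = np.linspace(110, 20, 101)  # 200 ms linear fall
        p = np.concatenate([up, down[1:]])
        b = beat(0, 5, 9, 10, len(p))
        tau = compute_tau66(b, rec_of(p))
        assert tau == pytest.approx(0.66 * 200.0, abs=0.5)

    @pytest.mark.parametrize("tau_exp_ms", [10.0, 25.0, 50.0, 75.0, 100.0])
    def test_solver_estimator_identity(self, tau_exp_ms):
        """solve_tau_exp applied to the measured tau66 returns the decay's
        true exponential constant."""
        r, b = decay_beat(tau_s=tau_exp_ms / 1e3, floor=14.0, n_dec=400)
        tau66 = compute_tau66(b, r)
        back = solve_tau_exp(tau66, 110.0, 110.0, 20.0, 14.0)
        assert back == pytest.approx(tau_exp_ms, abs=2.0)

    def test_no_crossing_flags_unmeasurable(self):
        p = np.concatenate([np.linspace(20, 110, 11), np.full(30, 108.0)])
        b = beat(0, 5, 10, 12, len(p))
        assert np.isnan(compute_tau66(b, rec_of(p)))

    def test_configured_tau_range_recovered(self):
        for tau in (22.0, 38.0, 54.0):
            rec, _ = simulate(clean_config(duration_s=10.0, tau66_ms=tau))
            res = analyze_recording(rec)
            assert res.metrics.tau66_ms.median() == pytest.approx(tau, abs=2.0)


class TestBeatMetrics:
    def test_heart_rate_is_sixty_over_rr(self):
        rec, _ = simulate(clean_config(duration_s=6.0))
        res = analyze_recording(rec)
        m = res.metrics
        assert np.allclose(m.heart_rate_bpm, 60.0 / m.rr_s)
        assert m.heart_rate_bpm.median() == pytest.approx(240.0, abs=0.5)

    def test_mean_lvp_equals_bruteforce_mean(self):
        rec, _ = simulate(clean_config(duration_s=6.0))
        d = estimate_derivative(rec)
        from lvpress import detect_beats
        ann = detect_beats(rec, d)
        b = ann[3]
        m = compute_beat_metrics(b, rec, d)
        expected = np.mean(rec.samples[b.onset_idx:b.end_idx])
        assert m.mean_lvp_mmHg == pytest.approx(expected, rel=1e-12)

    def test_ordering_invariant_on_valid_beats(self, noisy_recording):
        rec, _ = noisy_recording
        m = analyze_recording(rec).metrics
        ok = m[m.valid]
        assert (ok.lvedp_mmHg <= ok.mean_lvp_mmHg + 1e-9).all()
        assert (ok.mean_lvp_mmHg <= ok.lvsp_mmHg + 1e-9).all()

    def test_time_shift_invariance(self):
        """Prepending quiet diastole does not change interior beat indices."""
        rec, _ = simulate(clean_config(duration_s=10.0))
        pad = np.full(500, 20.0)
        shifted = PressureRecording(np.concatenate([pad, rec.samples]), RATE)
        m0 = analyze_recording(rec).metrics
        m1 = analyze_recording(shifted).metrics
        a = m0.iloc[1:-1].reset_index(drop=True)
        onset_shift = m1.onset_s - 1.0
        sel = m1[(onset_shift - a.onset_s.iloc[0]).abs() < 0.02].index[0]
        b = m1.iloc[sel:sel + len(a)].reset_index(drop=True)
        for c in ["lvsp_mmHg", "lvedp_mmHg", "dpdt_max_mmHg_per_s",
                  "neg_dpdt_max_mmHg_per_s", "tau66_ms"]:
            assert np.allclose(a[c], b[c], atol=1e-6), c

    def test_mean_lvp_in_reported_band_for_baseline_config(self):
        """Configured from the reported baseline pressures, the waveform's
        duty cycle puts mean LVP inside the printed 52-63 mmHg band."""
        rec, truth = simulate(clean_config(duration_s=10.0))
        m = analyze_recording(rec).metrics
        assert 52.0 < m.mean_lvp_mmHg.median() < 63.0
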