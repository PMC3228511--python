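"""Waveform text format, results tables, and transmitter calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from lvpress import (CalibrationRecord, PressureRecording, apply_calibration,
                     fit_calibration, read_metrics_table, read_recording,
                     simulate, write_metrics_table, write_recording)
from lvpress.errors import AlignmentError, CalibrationError, ParseError

from conftest import clean_config


class TestCalibration:
    def test_identity_device(self):
        cmap = fit_calibration(
            CalibrationRecord((750.0, 850.0, 950.0), (750.0, 850.0, 950.0)))
        assert cmap.slope == pytest.approx(1.0, abs=1e-12)
        assert cmap.intercept == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(cmap.residuals_mmHg, 0.0, atol=1e-9)

    def test_affine_device_recovered_exactly(self):
        """f = 2p + 10 at the three chamber pressures inverts to
        slope 0.5, intercept -5; cross-checked against a grid search."""
        p = np.array([750.0, 850.0, 950.0])
        f = 2.0 * p + 10.0
        cmap = fit_calibration(CalibrationRecord(tuple(p), tuple(f)))
        assert cmap.slope == pytest.approx(0.5, rel=1e-12)
        assert cmap.intercept == pytest.approx(-5.0, abs=1e-9)

        # brute-force grid oracle: no (slope, intercept) nearby fits better
        best_sse = np.sum((p - cmap(f)) ** 2)
        for s in np.linspace(0.45, 0.55, 41):
            for b in np.linspace(-25.0, 15.0, 41):
                assert np.sum((p - (s * f + b)) ** 2) >= best_sse - 1e-9

    def test_two_points_interpolated(self):
        cmap = fit_calibration(CalibrationRecord((750.0, 950.0), (100.0, 300.0)))
        assert cmap(100.0) == pytest.approx(750.0)
        assert cmap(300.0) == pytest.approx(950.0)

    def test_collinear_three_points_zero_residuals(self):
        cmap = fit_calibration(
            CalibrationRecord((750.0, 850.0, 950.0), (10.0, 20.0, 30.0)))
        assert np.allclose(cmap.residuals_mmHg, 0.0, atol=1e-9)

    def test_nonlinear_device_reports_residuals(self):
        cmap = fit_calibration(
            CalibrationRecord((750.0, 850.0, 950.0), (10.0, 21.0, 30.0)))
        assert max(abs(r) for r in cmap.residuals_mmHg) > 0.1

    def test_insufficient_or_degenerate_records(self):
        with pytest.raises(CalibrationError):
            CalibrationRecord((750.0,), (10.0,))
        with pytest.raises(CalibrationError):
            CalibrationRecord((750.0, 750.0), (10.0, 20.0))
        with pytest.raises(CalibrationError):
            fit_calibration(CalibrationRecord((750.0, 850.0), (5.0, 5.0)))


class TestApplyCalibration:
    def test_identity_map_minus_barometric(self):
        ident = fit_calibration(
            CalibrationRecord((750.0, 950.0), (750.0, 950.0)))
        raw = PressureRecording(np.array([870.0, 880.0]), 500.0, units="raw")
        gauge = apply_calibration(raw, ident, ambient=760.0)
        assert gauge.samples == pytest.approx([110.0, 120.0])
        assert gauge.units == "mmHg"

    def test_zero_ambient_is_pure_affine(self):
        cmap = fit_calibration(
            CalibrationRecord((750.0, 950.0), (1500.0, 1900.0)))
        raw = PressureRecording(np.array([1700.0]), 500.0, units="raw")
        assert apply_calibration(raw, cmap, 0.0).samples[0] == pytest.approx(850.0)

    def test_calibrate_then_apply_round_trip(self):
        """Simulated gauge pressures pushed through a synthetic transmitter
        (affine response + barometric offset) come back unchanged."""
        rec, _ = simulate(clean_config(duration_s=4.0))
        slope_true, icept_true, baro = 0.8, -40.0, 762.0
        raw_freq = ((rec.samples + baro) - icept_true) / slope_true
        chamber = np.array([750.0, 850.0, 950.0])
        record = CalibrationRecord(tuple(chamber),
                                   tuple((chamber - icept_true) / slope_true))
        cmap = fit_calibration(record)
        gauge = apply_calibration(
            PressureRecording(raw_freq, 500.0, units="raw"), cmap, baro)
        assert np.allclose(gauge.samples, rec.samples, atol=1e-8)

    def test_ambient_series_alignment(self):
        cmap = fit_calibration(
            CalibrationRecord((750.0, 950.0), (750.0, 950.0)))
        raw = PressureRecording(np.full(1000, 870.0), 500.0, units="raw")
        ambient = PressureRecording(np.full(10, 760.0), 5.0)
        gauge = apply_calibration(raw, cmap, ambient)
        assert np.allclose(gauge.samples, 110.0)
        with pytest.raises(AlignmentError):
            apply_calibration(raw, cmap, ambient, resample=False)


class TestWaveformFile:
    def test_header_and_length(self, tmp_path):
        path = tmp_path / "w.txt"
        rec = PressureRecording(np.linspace(0, 1, 1000), 500.0)
        write_recording(rec, path)
        back = read_recording(path)
        assert len(back) == 1000
        assert back.duration_s == pytest.approx(2.0)
        assert back.sampling_rate_hz == 500.0

    def test_round_trip_is_text_fixed_point(self, tmp_path):
        rec, _ = simulate(SimulatedShort.cfg)
        rec.gap_mask[50:53] = True
        rec.samples[50:53] = np.nan
        p1, p2 = tmp_path / "a.txt", tmp_path / "b.txt"
        write_recording(rec, p1)
        back = read_recording(p1)
        write_recording(back, p2)
        assert p1.read_text() == p2.read_text()
        assert np.array_equal(back.gap_mask, rec.gap_mask)
        ok = ~rec.gap_mask
        assert np.allclose(back.samples[ok], rec.samples[ok], rtol=1e-9)

    def test_parse_errors_name_line_numbers(self, tmp_path):
        bad = tmp_path / "bad.txt"
        bad.write_text("# sampling_rate_hz: 500\n# units: mmHg\n"
                       "# start_time: 2026-01-01T00:00:00\n1.0\nbogus\n")
        with pytest.raises(ParseError, match="line 5"):
            read_recording(bad)

        missing = tmp_path / "missing.txt"
        missing.write_text("# units: mmHg\n1.0\n")
        with pytest.raises(ParseError, match="sampling_rate_hz"):
            read_recording(missing)

        neg = tmp_path / "neg.txt"
        neg.write_text("# sampling_rate_hz: -5\n# units: mmHg\n"
                       "# start_time: 2026-01-01T00:00:00\n1.0\n")
        with pytest.raises(ParseError, match="positive"):
            read_recording(neg)

    def test_na_lines_become_gaps(self, tmp_path):
        p = tmp_path / "g.txt"
        p.write_text("# sampling_rate_hz: 500\n# units: mmHg\n"
                     "# start_time: 2026-01-01T00:00:00\n1.0\nNA\n2.0\n")
        rec = read_recording(p)
        assert list(rec.gap_mask) == [False, True, False]


class SimulatedShort:
    cfg = clean_config(duration_s=2.0)


class TestMetricsTable:
    def test_row_count_and_round_trip(self, tmp_path, rng):
        df = pd.DataFrame({
            "onset_s": np.sort(rng.uniform(0, 100, 80)),
            "tau66_ms": rng.uniform(20, 50, 80),
            "lvsp_mmHg": rng.uniform(99, 114, 80),
        })
        path = tmp_path / "m.csv"
        write_metrics_table(df, path)
        text = path.read_bytes().decode()
        assert text.count("\r\n") == 81  # header + 80 rows
        back = read_metrics_table(path)
        for c in df.columns:
            assert np.allclose(back[c], df[c], rtol=1e-6)

    def test_mixed_type_collections_rejected(self, tmp_path):
        from lvpress import BeatMetrics

        m = BeatMetrics(240.0, 55.0, 107.0, 20.0, 3000.0, 68.0, 2500.0, 29.0)
        with pytest.raises(TypeError, match="mixed"):
            write_metrics_table([m, object()], tmp_path / "x.csv")
        with pytest.raises(ValueError):
            write_metrics_table([], tmp_path / "x.csv")

    def test_dataclass_rows_serialise(self, tmp_path):
        from lvpress import BeatMetrics

        rows = [BeatMetrics(240.0, 55.0, 107.0, 20.0, 3000.0, 68.0,
                            2500.0, 29.0)] * 3
        write_metrics_table(rows, tmp_path / "b.csv")
        back = read_metrics_table(tmp_path / "b.csv")
        assert len(back) == 3
        assert back.tau66_ms.iloc[0] == pytest.approx(29.0)


@given(st.lists(st.floats(min_value=-1e3, max_value=1e3,
                          allow_nan=False), min_size=2, max_size=40))
def test_affine_fit_never_beaten_by_candidates(raw):
    """Property: the least-squares affine calibration has minimal SSE among
    random affine candidates."""
    raw = np.asarray(raw)
    if np.ptp(raw) == 0:
        return
    p = np.linspace(700.0, 1000.0, len(raw))
    cmap = fit_calibration(CalibrationRecord(tuple(p), tuple(raw)))
    sse = np.sum((p - cmap(raw)) ** 2)
    rng = np.random.default_rng(0)
    for _ in range(20):
        s = cmap.slope + rng.normal(0, 0.1)
        b = cmap.intercept + rng.normal(0, 5.0)
        assert np.sum((p - (s * raw + b)) ** 2) >= sse - 1e-6
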