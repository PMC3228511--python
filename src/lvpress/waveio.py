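"""Waveform and results I/O, plus transmitter calibration.

Waveform file format: UTF-8 text, ``#``-prefixed header lines
(``# sampling_rate_hz: 500``, ``# units: mmHg``, ``# start_time: ...``),
then one sample per line; ``NA`` marks a missing/invalid sample.

Convention used everywhere in the package: sample ``i`` of a recording is at
``start_time + i / sampling_rate_hz`` (0-based), and time windows are
half-open ``[start, end)``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AlignmentError, CalibrationError, ParseError

__all__ = [
    "PressureRecording", "CalibrationRecord", "CalibrationMap",
    "fit_calibration", "apply_calibration",
    "read_recording", "write_recording",
    "write_metrics_table", "read_metrics_table",
]

_DEFAULT_START = datetime(2026, 1, 1, 0, 0, 0)


@dataclass
class PressureRecording:
    """A uniformly sampled pressure series.

    ``samples`` are gauge mmHg after calibration (or raw transmitter
    frequency units before it); ``gap_mask`` is True where a sample is
    missing or invalid. Gap samples hold NaN.
    """

    samples: np.ndarray
    sampling_rate_hz: float
    start_time: datetime = _DEFAULT_START
    units: str = "mmHg"
    gap_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.gap_mask is None:
            self.gap_mask = ~np.isfinite(self.samples)
        else:
            self.gap_mask = np.asarray(self.gap_mask, dtype=bool)
        if self.gap_mask.shape != self.samples.shape:
            raise ValueError("samples and gap_mask must have the same length")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sampling_rate_hz

    def times_s(self) -> np.ndarray:
        """Sample times in seconds since ``start_time``."""
        return np.arange(len(self.samples)) / self.sampling_rate_hz


@dataclass(frozen=True)
class CalibrationRecord:
    """Chamber calibration points: applied absolute pressure vs raw output.

    The transmitter is calibrated in a sealed chamber; the standard protocol
    uses three points at 750, 850 and 950 mmHg absolute.
    """

    pressures_mmHg: tuple
    raw_values: tuple

    def __post_init__(self):
        p = np.asarray(self.pressures_mmHg, dtype=float)
        r = np.asarray(self.raw_values, dtype=float)
        if p.shape != r.shape:
            raise CalibrationError("pressures and raw values differ in length")
        if len(np.unique(p)) < 2:
            raise CalibrationError("need at least 2 distinct pressure points")
        if not np.all(np.diff(p) > 0):
            raise CalibrationError("pressures must be strictly increasing")


@dataclass(frozen=True)
class CalibrationMap:
    """Affine raw -> absolute-pressure map with per-point residuals."""

    slope: float
    intercept: float
    residuals_mmHg: tuple

    def __call__(self, raw):
        return self.slope * np.asarray(raw, dtype=float) + self.intercept


def fit_calibration(record: CalibrationRecord) -> CalibrationMap:
    """Least-squares affine fit of applied pressure on raw output.

    With exactly two points the fit interpolates them; with three or more,
    residuals report how far the device departs from affine behaviour.
    """
    p = np.asarray(record.pressures_mmHg, dtype=float)
    r = np.asarray(record.raw_values, dtype=float)
    if np.ptp(r) == 0:
        raise CalibrationError("raw output has zero spread across pressures")
    slope, intercept = np.polyfit(r, p, 1)
    resid = p - (slope * r + intercept)
    return CalibrationMap(float(slope), float(intercept), tuple(resid))


def apply_calibration(recording: PressureRecording, cmap: CalibrationMap,
                      ambient=0.0, resample: bool = True) -> PressureRecording:
    """Convert a raw recording to gauge pressure: affine map minus ambient.

    ``ambient`` may be a scalar (mmHg absolute, e.g. barometric) or a
    :class:`PressureRecording` from an ambient reference monitor; a series on
    a different time base is linearly interpolated onto the recording unless
    ``resample=False``, in which case a length mismatch raises
    :class:`AlignmentError`.
    """
    absolute = cmap(recording.samples)
    if isinstance(ambient, PressureRecording):
        if len(ambient) == len(recording) and \
                ambient.sampling_rate_hz == recording.sampling_rate_hz:
            amb = ambient.samples
        elif resample:
            amb = np.interp(recording.times_s(), ambient.times_s(),
                            ambient.samples)
        else:
            raise AlignmentError(
                "ambient series does not align with the recording and "
                "resampling is disabled")
    else:
        amb = float(ambient)
    gauge = absolute - amb
    return PressureRecording(gauge, recording.sampling_rate_hz,
                             recording.start_time, "mmHg",
                             recording.gap_mask.copy())


# -- waveform text format --------------------------------------------------

_REQUIRED_HEADER = ("sampling_rate_hz", "units", "start_time")


def write_recording(recording: PressureRecording, path) -> None:
    path = Path(path)
    lines = [
        f"# sampling_rate_hz: {recording.sampling_rate_hz:.10g}",
        f"# units: {recording.units}",
        f"# start_time: {recording.start_time.isoformat()}",
    ]
    body = np.where(recording.gap_mask, "NA",
                    np.char.mod("%.10g", recording.samples))
    path.write_text("\n".join(lines) + "\n" + "\n".join(body.tolist()) + "\n",
                    encoding="utf-8")


def read_recording(path) -> PressureRecording:
    path = Path(path)
    header: dict[str, str] = {}
    values: list[float] = []
    gaps: list[bool] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                values.append(np.nan)
                gaps.append(True)
                continue
            if line.startswith("#"):
                if values:
                    raise ParseError("header line after samples began", lineno)
                key, sep, val = line[1:].partition(":")
                if not sep:
                    raise ParseError("malformed header line", lineno)
                header[key.strip()] = val.strip()
                continue
            if line.upper() == "NA":
                values.append(np.nan)
                gaps.append(True)
                continue
            try:
                values.append(float(line))
            except ValueError as exc:
                raise ParseError(f"non-numeric sample {line!r}", lineno) from exc
            gaps.append(False)

    missing = [k for k in _REQUIRED_HEADER if k not in header]
    if missing:
        raise ParseError(f"missing header field(s): {', '.join(missing)}")
    try:
        rate = float(header["sampling_rate_hz"])
    except ValueError as exc:
        raise ParseError("sampling_rate_hz is not numeric") from exc
    if rate <= 0:
        raise ParseError("sampling_rate_hz must be positive")
    try:
        start = datetime.fromisoformat(header["start_time"])
    except ValueError as exc:
        raise ParseError("start_time is not ISO-8601") from exc
    return PressureRecording(np.asarray(values), rate, start,
                             header["units"], np.asarray(gaps))


# -- results tables --------------------------------------------------------

def write_metrics_table(table, path) -> None:
    """Write a beats/epochs/trend table as RFC-4180 CSV.

    Accepts a DataFrame, or a homogeneous list of dataclass instances
    (mixed types are rejected). Units are embedded in the column names
    (``tau66_ms``, ``dpdt_max_mmHg_per_s``, ...).
    """
    if isinstance(table, pd.DataFrame):
        df = table
    else:
        rows = list(table)
        if not rows:
            raise ValueError("refusing to write an empty table")
        kinds = {type(r) for r in rows}
        if len(kinds) > 1:
            raise TypeError(
                f"mixed-type collection: {sorted(k.__name__ for k in kinds)}")
        if not dataclasses.is_dataclass(rows[0]):
            raise TypeError("rows must be dataclass instances or a DataFrame")
        df = pd.DataFrame([dataclasses.asdict(r) for r in rows])
    if df.empty:
        raise ValueError("refusing to write an empty table")
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\r\n")


def read_metrics_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
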