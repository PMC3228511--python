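"""Beat detection, fiducial annotation, and recording-level quality control.

Detection is derivative-triggered: candidate beats are local maxima of dP/dt
above an adaptive threshold (a fraction of the rolling 10-s derivative
maximum), separated by a refractory period. Fiducials per beat:

  onset (end-diastole)  last upward crossing of ``onset_frac`` x that beat's
                        dP/dt_max before the dP/dt_max sample
  dP/dt_max             earliest sample attaining the interval maximum of dP/dt
  systolic peak         maximum pressure between dP/dt_max and the next candidate
  -dP/dt_max            earliest sample attaining the interval minimum of dP/dt
  end                   next beat's onset (recording end for the final beat)

Ties resolve to the earliest sample throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter1d
from scipy.signal import find_peaks, savgol_filter

from .config import AnalysisConfig
from .errors import EmptySignalError
from .waveio import PressureRecording

__all__ = ["DerivativeSeries", "estimate_derivative", "estimate_noise_sd",
           "BeatAnnotation", "BeatAnnotations", "detect_beats",
           "QCReport", "qc_recording"]

#: default absolute floor under the adaptive threshold, mmHg/s; rejects
#: "beats" found in signal-free noise while sitting far below any
#: physiological upstroke
MIN_DPDT_FLOOR = 250.0


@dataclass
class DerivativeSeries:
    """dP/dt aligned sample-for-sample with its recording."""

    values: np.ndarray
    sampling_rate_hz: float
    method: str
    window: int | None = None
    gap_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.gap_mask is None:
            self.gap_mask = ~np.isfinite(self.values)

    def __len__(self) -> int:
        return len(self.values)


def estimate_noise_sd(samples: np.ndarray) -> float:
    """Robust broadband noise SD (mmHg) from the second difference.

    The second difference of a smooth waveform is tiny next to that of white
    noise (variance 6 sigma^2); the median absolute value is immune to the
    brief spikes contributed by upstrokes.
    """
    x = samples[np.isfinite(samples)]
    if len(x) < 3:
        return 0.0
    dd = np.diff(x, 2)
    return float(1.4826 * np.median(np.abs(dd)) / np.sqrt(6.0))


def estimate_derivative(recording: PressureRecording, method: str = "central",
                        window: int | None = None, polyorder: int = 3,
                        ) -> DerivativeSeries:
    """Estimate dP/dt.

    ``central`` is the exact 3-point stencil ``(P[i+1]-P[i-1]) * rate / 2``
    with one-sided differences at the edges. ``savgol`` fits a local
    polynomial (Savitzky-Golay) and differentiates it, trading a little
    smoothing bias for a large noise reduction; ``window`` defaults to 9
    samples. Gap samples yield gaps, which spread to the stencil width.
    """
    p = np.where(recording.gap_mask, np.nan, recording.samples)
    if np.isfinite(p).sum() < 3:
        raise EmptySignalError("need at least 3 non-gap samples")
    rate = recording.sampling_rate_hz
    if method == "central":
        d = np.empty_like(p)
        d[1:-1] = (p[2:] - p[:-2]) * (rate / 2.0)
        d[0] = (p[1] - p[0]) * rate
        d[-1] = (p[-1] - p[-2]) * rate
    elif method == "savgol":
        if window is None:
            window = 9
        d = savgol_filter(p, window, polyorder, deriv=1, delta=1.0 / rate)
    else:
        raise ValueError(f"unknown derivative method {method!r}")
    d[recording.gap_mask] = np.nan  # a gap sample has no derivative either
    return DerivativeSeries(d, rate, method, window)


@dataclass(frozen=True)
class BeatAnnotation:
    """Fiducial sample indices for one beat (0-based, strictly increasing)."""

    onset_idx: int
    dpdt_max_idx: int
    systolic_peak_idx: int
    neg_dpdt_max_idx: int
    end_idx: int
    rr_s: float
    flags: tuple = ()


class BeatAnnotations:
    """Column-wise container of per-beat fiducials.

    Indexing yields :class:`BeatAnnotation`; ``to_frame()`` gives the CSV
    layout (one row per beat, indices plus times in seconds).
    """

    _FIELDS = ("onset_idx", "dpdt_max_idx", "systolic_peak_idx",
               "neg_dpdt_max_idx", "end_idx")

    def __init__(self, onset_idx, dpdt_max_idx, systolic_peak_idx,
                 neg_dpdt_max_idx, end_idx, rr_s, flags,
                 sampling_rate_hz: float):
        self.onset_idx = np.asarray(onset_idx, dtype=np.int64)
        self.dpdt_max_idx = np.asarray(dpdt_max_idx, dtype=np.int64)
        self.systolic_peak_idx = np.asarray(systolic_peak_idx, dtype=np.int64)
        self.neg_dpdt_max_idx = np.asarray(neg_dpdt_max_idx, dtype=np.int64)
        self.end_idx = np.asarray(end_idx, dtype=np.int64)
        self.rr_s = np.asarray(rr_s, dtype=float)
        self.flags = list(flags)
        self.sampling_rate_hz = sampling_rate_hz

    def __len__(self) -> int:
        return len(self.onset_idx)

    def __getitem__(self, i: int) -> BeatAnnotation:
        return BeatAnnotation(
            int(self.onset_idx[i]), int(self.dpdt_max_idx[i]),
            int(self.systolic_peak_idx[i]), int(self.neg_dpdt_max_idx[i]),
            int(self.end_idx[i]), float(self.rr_s[i]), tuple(self.flags[i]))

    def __iter__(self):
        return (self[i] for i in range(len(self)))

    def onset_times_s(self) -> np.ndarray:
        return self.onset_idx / self.sampling_rate_hz

    def to_frame(self) -> pd.DataFrame:
        r = self.sampling_rate_hz
        return pd.DataFrame({
            "onset_idx": self.onset_idx,
            "dpdt_max_idx": self.dpdt_max_idx,
            "systolic_peak_idx": self.systolic_peak_idx,
            "neg_dpdt_max_idx": self.neg_dpdt_max_idx,
            "end_idx": self.end_idx,
            "onset_s": self.onset_idx / r,
            "rr_s": self.rr_s,
            "flags": [";".join(f) for f in self.flags],
        })

    @staticmethod
    def empty(sampling_rate_hz: float) -> "BeatAnnotations":
        return BeatAnnotations([], [], [], [], [], [], [], sampling_rate_hz)


def detect_beats(recording: PressureRecording, derivative: DerivativeSeries,
                 config: AnalysisConfig | None = None) -> BeatAnnotations:
    """Locate beats and their fiducials. Returns an empty set, not an error,
    when no candidate upstrokes exist (e.g. a flat recording)."""
    if config is None:
        config = AnalysisConfig()
    if len(derivative) != len(recording):
        raise ValueError("derivative is not aligned to the recording")
    rate = recording.sampling_rate_hz
    n = len(recording)
    p = np.where(recording.gap_mask, np.nan, recording.samples)
    d = np.where(np.isfinite(derivative.values), derivative.values, -np.inf)

    win = max(int(round(config.rolling_window_s * rate)) | 1, 3)
    rolling_max = maximum_filter1d(d, size=win, mode="nearest")
    height = np.maximum(config.threshold_frac * rolling_max, MIN_DPDT_FLOOR)
    distance = max(int(round(config.refractory_s * rate)), 1)
    candidates, _ = find_peaks(d, height=height, distance=distance)
    if len(candidates) == 0:
        return BeatAnnotations.empty(rate)

    refine = max(int(round(0.025 * rate)), 1)
    onsets, onset_ts, dmaxs, peaks, negs, flags = [], [], [], [], [], []
    bounds = np.append(candidates, n)
    back_limit = int(round(0.25 * rate))
    for j, c in enumerate(candidates):
        lo = max(c - refine, 0 if j == 0 else bounds[j - 1])
        hi = min(c + refine + 1, bounds[j + 1])
        dm = lo + int(np.argmax(d[lo:hi]))
        nb = bounds[j + 1]
        if dm + 1 >= nb:
            continue
        pk = dm + int(np.argmax(p[dm:nb]))
        if pk + 1 >= nb:
            continue
        ng = pk + 1 + int(np.argmin(d[pk + 1:nb]))
        thr = config.onset_frac * d[dm]
        seg_lo = max(dm - back_limit, 0)
        below = np.flatnonzero(d[seg_lo:dm] < thr)
        if len(below) == 0:
            continue  # upstroke truncated at the recording start
        onset = seg_lo + below[-1] + 1
        # sub-sample crossing time; keeps RR free of sample quantisation
        d0, d1 = d[onset - 1], d[onset]
        frac = (thr - d0) / (d1 - d0) if d1 > d0 else 0.0
        onsets.append(onset)
        onset_ts.append((onset - 1 + frac) / rate)
        dmaxs.append(dm)
        peaks.append(pk)
        negs.append(ng)
        flags.append([])

    if not onsets:
        return BeatAnnotations.empty(rate)

    ends = onsets[1:] + [n]
    end_ts = onset_ts[1:] + [n / rate]
    keep_onsets, keep_dm, keep_pk, keep_ng, keep_end, keep_rr, keep_fl = \
        [], [], [], [], [], [], []
    for i, (o, dm, pk, ng, e) in enumerate(
            zip(onsets, dmaxs, peaks, negs, ends)):
        if not (o < dm < pk < ng < e):
            continue
        fl = list(flags[i])
        if i == len(onsets) - 1:
            fl.append("last_beat")
        if recording.gap_mask[o:e].any():
            fl.append("gap")
        keep_onsets.append(o)
        keep_dm.append(dm)
        keep_pk.append(pk)
        keep_ng.append(ng)
        keep_end.append(e)
        keep_rr.append(end_ts[i] - onset_ts[i])
        keep_fl.append(fl)

    return BeatAnnotations(keep_onsets, keep_dm, keep_pk, keep_ng, keep_end,
                           keep_rr, keep_fl, rate)


@dataclass
class QCReport:
    """Recording-level quality summary and the exclusion verdict."""

    n_beats: int
    n_irregular: int
    irregular_fraction: float
    artifact_fraction: float
    artifact_intervals: list
    excluded: bool
    reasons: list
    beat_irregular: np.ndarray = field(default=None, repr=False)  # type: ignore
    beat_artifact: np.ndarray = field(default=None, repr=False)  # type: ignore

    def to_dict(self) -> dict:
        return {
            "n_beats": self.n_beats,
            "n_irregular": self.n_irregular,
            "irregular_fraction": self.irregular_fraction,
            "artifact_fraction": self.artifact_fraction,
            "artifact_intervals": [list(map(float, iv))
                                   for iv in self.artifact_intervals],
            "excluded": self.excluded,
            "reasons": self.reasons,
        }


def _mask_to_intervals(mask: np.ndarray, rate: float) -> list:
    if not mask.any():
        return []
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return [(s / rate, e / rate) for s, e in zip(idx[::2], idx[1::2])]


def qc_recording(annotations: BeatAnnotations, recording: PressureRecording,
                 config: AnalysisConfig | None = None,
                 derivative: DerivativeSeries | None = None,
                 precomputed_bad: np.ndarray | None = None) -> QCReport:
    """Flag irregular beats and artifact time; decide exclusion.

    A beat is irregular when its RR deviates more than ``rr_deviation_frac``
    from the median RR of the surrounding ``rr_context_s``. Artifact samples
    are gaps, pressures outside the physiological bounds, or |dP/dt| above the
    wall-contact spike threshold (dilated by 50 ms). The recording is excluded
    when the irregular fraction exceeds ``irregular_max_frac`` or artifact
    time exceeds ``artifact_max_frac`` of its duration — the same judgement a
    telemetry study applies when a surgically provoked arrhythmia makes an
    animal's trace unusable.
    """
    if config is None:
        config = AnalysisConfig()
    rate = recording.sampling_rate_hz
    n = len(recording)
    n_beats = len(annotations)

    if n_beats == 0:
        return QCReport(0, 0, 0.0, 1.0, [(0.0, n / rate)], True, ["no beats"],
                        np.zeros(0, dtype=bool), np.zeros(0, dtype=bool))

    rr = pd.Series(annotations.rr_s,
                   index=pd.to_timedelta(annotations.onset_times_s(), unit="s"))
    local_med = rr.rolling(pd.Timedelta(seconds=config.rr_context_s),
                           center=True, min_periods=1).median().to_numpy()
    rr_v = annotations.rr_s
    irregular = np.abs(rr_v - local_med) > config.rr_deviation_frac * local_med

    if precomputed_bad is not None:
        sample_bad = precomputed_bad
    else:
        sample_bad = recording.gap_mask.copy()
        p = recording.samples
        with np.errstate(invalid="ignore"):
            sample_bad |= (p < config.pressure_min_mmHg) \
                | (p > config.pressure_max_mmHg)
            if derivative is not None:
                sample_bad |= np.abs(derivative.values) \
                    > config.spike_dpdt_mmHg_per_s
        if sample_bad.any():
            dil = max(int(round(0.05 * rate)), 1)
            sample_bad = maximum_filter1d(sample_bad.view(np.int8),
                                          size=2 * dil + 1).astype(bool)

    beat_artifact = np.zeros(n_beats, dtype=bool)
    if sample_bad.any():
        csum = np.concatenate(([0], np.cumsum(sample_bad)))
        o = annotations.onset_idx
        e = annotations.end_idx
        beat_artifact = (csum[e] - csum[o]) > 0
    for i, fl in enumerate(annotations.flags):
        if "gap" in fl:
            beat_artifact[i] = True

    artifact_fraction = float(sample_bad.mean())
    irregular_fraction = float(irregular.mean())
    reasons = []
    if irregular_fraction > config.irregular_max_frac:
        reasons.append(
            f"irregular rhythm: {irregular_fraction:.1%} of beats deviate "
            f">{config.rr_deviation_frac:.0%} from the local median RR")
    if artifact_fraction > config.artifact_max_frac:
        reasons.append(
            f"artifact time: {artifact_fraction:.1%} of the recording")
    return QCReport(
        n_beats=n_beats,
        n_irregular=int(irregular.sum()),
        irregular_fraction=irregular_fraction,
        artifact_fraction=artifact_fraction,
        artifact_intervals=_mask_to_intervals(sample_bad, rate),
        excluded=bool(reasons),
        reasons=reasons,
        beat_irregular=irregular,
        beat_artifact=beat_artifact,
    )
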