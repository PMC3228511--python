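"""Per-beat contractility and relaxation indices.

The eight monitored parameters: heart rate, mean LVP, LVSP, LVEDP,
+dP/dt_max, V_max, -dP/dt_max (reported as a magnitude), and Tau66.

Conventions:

* LVSP is the peak pressure after the detected dP/dt_max (searched over
  ``[dpdt_max_idx, neg_dpdt_max_idx]``), LVEDP the pressure at the onset
  fiducial, mean LVP the average over the half-open beat ``[onset, end)``.
* Tau66 is the time from the -dP/dt_max point to the first downward crossing
  of ``P_tgt = LVSP - 0.66 * (LVSP - LVEDP)``, with linear interpolation
  between the bracketing samples. When a derivative series is supplied, the
  reference time is refined to the earliest (interpolated) attainment of the
  beat's -dP/dt_max within a small tolerance band, which removes the
  half-sample bias a discrete argmin carries on a flat derivative extremum.
* V_max is the peak of (dP/dt) / max(P, floor) during isovolumic contraction
  (onset to dP/dt_max). The vendor software behind the printed values never
  documents its V_max formula; this pressure-normalised form matches the
  printed 1/s units but not necessarily the vendor's normalisation — treat
  absolute V_max values as internally consistent only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .detect import BeatAnnotation, BeatAnnotations, DerivativeSeries
from .errors import InvalidBeatError
from .waveio import PressureRecording

__all__ = ["BeatMetrics", "compute_lvsp", "compute_lvedp",
           "compute_dpdt_extrema", "compute_vmax", "compute_tau66",
           "compute_beat_metrics", "compute_all_metrics"]


@dataclass(frozen=True)
class BeatMetrics:
    """The eight monitored parameters for one beat (units in field names)."""

    heart_rate_bpm: float
    mean_lvp_mmHg: float
    lvsp_mmHg: float
    lvedp_mmHg: float
    dpdt_max_mmHg_per_s: float
    vmax_per_s: float
    neg_dpdt_max_mmHg_per_s: float
    tau66_ms: float
    onset_s: float = np.nan
    rr_s: float = np.nan
    valid: bool = True
    flags: tuple = ()


def compute_lvsp(beat: BeatAnnotation, recording: PressureRecording) -> float:
    """Peak pressure between dP/dt_max and -dP/dt_max (earliest on ties)."""
    lo, hi = beat.dpdt_max_idx, beat.neg_dpdt_max_idx + 1
    if hi <= lo:
        raise InvalidBeatError("empty systolic window")
    window = recording.samples[lo:hi]
    if not np.isfinite(window).any():
        raise InvalidBeatError("systolic window is all gaps")
    return float(np.nanmax(window))


def compute_lvedp(beat: BeatAnnotation, recording: PressureRecording) -> float:
    """Pressure at end-diastole (the onset fiducial)."""
    v = recording.samples[beat.onset_idx]
    if not np.isfinite(v):
        raise InvalidBeatError("onset sample is a gap")
    return float(v)


def compute_dpdt_extrema(beat: BeatAnnotation,
                         derivative: DerivativeSeries) -> tuple[float, float]:
    """(dP/dt at the dP/dt_max fiducial, |dP/dt| at the -dP/dt_max fiducial).

    On a smoothed (Savitzky-Golay) derivative the single argmax sample is
    biased high — noise makes the extremum a max-statistic, and the
    polynomial fit overshoots at the edges of a flat derivative extremum —
    so the smoothed branch reads a 3-sample local mean at the fiducial
    instead of the point value. The exact central-difference branch reads
    the sample itself.
    """
    d = derivative.values

    def read(idx: int, sign: float) -> float:
        if derivative.method == "savgol":
            lo = max(idx - 1, 0)
            window = d[lo:idx + 2]
            window = window[np.isfinite(window)]
            if len(window):
                return sign * float(np.mean(window))
        return sign * float(d[idx])

    return (read(beat.dpdt_max_idx, 1.0),
            abs(read(beat.neg_dpdt_max_idx, -1.0)))


def compute_vmax(beat: BeatAnnotation, recording: PressureRecording,
                 derivative: DerivativeSeries,
                 pressure_floor: float = 1.0) -> float:
    """Peak pressure-normalised dP/dt during isovolumic contraction (1/s).

    Returns NaN (undefined, not an error) when no positive pressure exists in
    the window.
    """
    lo, hi = beat.onset_idx, beat.dpdt_max_idx + 1
    p = recording.samples[lo:hi]
    d = derivative.values[lo:hi]
    ok = np.isfinite(p) & np.isfinite(d)
    if not ok.any() or np.nanmax(p) <= 0:
        return float("nan")
    ratio = d[ok] / np.maximum(p[ok], pressure_floor)
    return float(np.max(ratio))


def _refined_neg_time_s(beat: BeatAnnotation, derivative: DerivativeSeries,
                        band_frac: float) -> float:
    """Earliest interpolated attainment of the beat's -dP/dt_max.

    On a waveform whose derivative holds its minimum over a short span, the
    argmin sample lands up to two samples after the span begins; walking back
    through a ``band_frac`` tolerance band and interpolating the band entry
    recovers the start of the extremum to sub-sample resolution.
    """
    d = derivative.values
    rate = derivative.sampling_rate_hz
    i = beat.neg_dpdt_max_idx
    level = d[i] * (1.0 - band_frac)  # slightly less negative than the min
    j = i
    lo = beat.systolic_peak_idx
    while j > lo and np.isfinite(d[j - 1]) and d[j - 1] <= level:
        j -= 1
    if j == 0 or not np.isfinite(d[j - 1]) or d[j - 1] <= level:
        return j / rate
    frac = (d[j - 1] - level) / (d[j - 1] - d[j])
    return (j - 1 + frac) / rate


def compute_tau66(beat: BeatAnnotation, recording: PressureRecording,
                  derivative: DerivativeSeries | None = None,
                  band_frac: float = 0.005) -> float:
    """Relaxation time constant by the 66%-drop rule, in ms.

    NaN when the pressure never crosses the target before the beat ends
    (unmeasurable, flagged rather than raised).
    """
    lvsp = compute_lvsp(beat, recording)
    lvedp = compute_lvedp(beat, recording)
    p_tgt = lvsp - 0.66 * (lvsp - lvedp)
    rate = recording.sampling_rate_hz
    if derivative is not None:
        t_ref = _refined_neg_time_s(beat, derivative, band_frac)
    else:
        t_ref = beat.neg_dpdt_max_idx / rate

    p = recording.samples
    i = beat.neg_dpdt_max_idx
    end = beat.end_idx
    seg = p[i:end]
    below = seg < p_tgt
    k = np.argmax(below) if below.any() else 0
    if k == 0:
        # either already below at the reference (degenerate) or no crossing
        return float("nan")
    j = i + k  # first sample below target; j-1 is >= target
    frac = (p[j - 1] - p_tgt) / (p[j - 1] - p[j])
    t_cross = (j - 1 + frac) / rate
    return float((t_cross - t_ref) * 1e3)


def compute_beat_metrics(beat: BeatAnnotation, recording: PressureRecording,
                         derivative: DerivativeSeries,
                         config: AnalysisConfig | None = None) -> BeatMetrics:
    """Assemble all eight parameters for one beat, propagating quality flags."""
    if config is None:
        config = AnalysisConfig()
    rate = recording.sampling_rate_hz
    flags = list(beat.flags)

    lvsp = compute_lvsp(beat, recording)
    lvedp = compute_lvedp(beat, recording)
    dpdt_max, neg_dpdt_max = compute_dpdt_extrema(beat, derivative)
    vmax = compute_vmax(beat, recording, derivative,
                        config.vmax_pressure_floor_mmHg)
    tau = compute_tau66(beat, recording, derivative,
                        config.extremum_band_frac)
    mean_lvp = float(np.nanmean(recording.samples[beat.onset_idx:beat.end_idx]))

    if not np.isfinite(vmax):
        flags.append("vmax_undefined")
    if not np.isfinite(tau):
        flags.append("tau_unmeasurable")
    if not (lvedp <= mean_lvp <= lvsp):
        flags.append("ordering_violation")
    valid = not ({"gap", "tau_unmeasurable", "ordering_violation"} & set(flags))

    return BeatMetrics(
        heart_rate_bpm=60.0 / beat.rr_s,
        mean_lvp_mmHg=mean_lvp,
        lvsp_mmHg=lvsp,
        lvedp_mmHg=lvedp,
        dpdt_max_mmHg_per_s=dpdt_max,
        vmax_per_s=vmax,
        neg_dpdt_max_mmHg_per_s=neg_dpdt_max,
        tau66_ms=tau,
        onset_s=beat.onset_idx / rate,
        rr_s=beat.rr_s,
        valid=valid,
        flags=tuple(flags),
    )


def compute_all_metrics(annotations: BeatAnnotations,
                        recording: PressureRecording,
                        derivative: DerivativeSeries,
                        config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Metrics for every annotated beat, one row per beat."""
    if config is None:
        config = AnalysisConfig()
    rows = []
    for beat in annotations:
        try:
            m = compute_beat_metrics(beat, recording, derivative, config)
        except InvalidBeatError:
            continue
        rows.append(m)
    cols = ["onset_s", "rr_s", "heart_rate_bpm", "mean_lvp_mmHg", "lvsp_mmHg",
            "lvedp_mmHg", "dpdt_max_mmHg_per_s", "vmax_per_s",
            "neg_dpdt_max_mmHg_per_s", "tau66_ms", "valid", "flags"]
    if not rows:
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame([{
        "onset_s": m.onset_s, "rr_s": m.rr_s,
        "heart_rate_bpm": m.heart_rate_bpm, "mean_lvp_mmHg": m.mean_lvp_mmHg,
        "lvsp_mmHg": m.lvsp_mmHg, "lvedp_mmHg": m.lvedp_mmHg,
        "dpdt_max_mmHg_per_s": m.dpdt_max_mmHg_per_s,
        "vmax_per_s": m.vmax_per_s,
        "neg_dpdt_max_mmHg_per_s": m.neg_dpdt_max_mmHg_per_s,
        "tau66_ms": m.tau66_ms, "valid": m.valid,
        "flags": ";".join(m.flags),
    } for m in rows])
    return df[cols]
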