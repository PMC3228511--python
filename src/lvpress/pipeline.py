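"""End-to-end analysis: waveform in, beats + per-beat metrics + QC out.

``analyze_recording`` wires the stages together and makes one adaptive
choice: how to estimate dP/dt. On a clean signal the exact central difference
is unbeatable; under broadband sensor noise the raw difference amplifies it
by ~rate/sqrt(2), so the pipeline switches to a Savitzky-Golay derivative and
reads pressures off a Savitzky-Golay-smoothed copy of the recording. The
switch is driven by a robust noise estimate, not by configuration flags, so
the same defaults serve both regimes; ``derivative_method`` can still be
forced.

Long recordings can be processed in fixed-length chunks with a small overlap;
beats are attributed to the chunk holding their onset, so the result is
independent of the chunk length (this also caps peak memory on multi-day
telemetry).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .config import AnalysisConfig
from .detect import (BeatAnnotations, DerivativeSeries, QCReport,
                     detect_beats, estimate_derivative, estimate_noise_sd,
                     qc_recording)
from .indices import compute_all_metrics
from .waveio import PressureRecording

__all__ = ["AnalysisResult", "analyze_recording", "summarize_metrics"]

_CHUNK_OVERLAP_S = 2.0


@dataclass
class AnalysisResult:
    annotations: BeatAnnotations
    metrics: pd.DataFrame
    qc: QCReport
    noise_sd_mmHg: float
    derivative_method: str


def _choose_method(recording: PressureRecording,
                   config: AnalysisConfig) -> tuple[str, float]:
    noise = estimate_noise_sd(recording.samples)
    if config.derivative_method != "auto":
        return config.derivative_method, noise
    return ("savgol" if noise > config.noise_switch_mmHg else "central"), noise


def _readout_recording(recording: PressureRecording, method: str,
                       config: AnalysisConfig) -> PressureRecording:
    """Pressure copy used for value readouts (smoothed iff derivative is)."""
    if method != "savgol":
        return recording
    p = np.where(recording.gap_mask, np.nan, recording.samples)
    smooth = savgol_filter(p, config.savgol_window, config.savgol_polyorder)
    return PressureRecording(smooth, recording.sampling_rate_hz,
                             recording.start_time, recording.units,
                             recording.gap_mask.copy())


def _analyze_whole(recording: PressureRecording, config: AnalysisConfig,
                   method: str) -> tuple[BeatAnnotations, pd.DataFrame,
                                         DerivativeSeries]:
    derivative = estimate_derivative(
        recording, method=method,
        window=config.savgol_window if method == "savgol" else None,
        polyorder=config.savgol_polyorder)
    annotations = detect_beats(recording, derivative, config)
    readout = _readout_recording(recording, method, config)
    metrics = compute_all_metrics(annotations, readout, derivative, config)
    return annotations, metrics, derivative


def analyze_recording(recording: PressureRecording,
                      config: AnalysisConfig | None = None,
                      chunk_s: float | None = None) -> AnalysisResult:
    """Detect beats, compute the eight indices per beat, and run QC."""
    if config is None:
        config = AnalysisConfig()
    method, noise = _choose_method(recording, config)

    if chunk_s is None or recording.duration_s <= chunk_s + 2 * _CHUNK_OVERLAP_S:
        annotations, metrics, derivative = _analyze_whole(
            recording, config, method)
        qc = qc_recording(annotations, recording, config, derivative)
        return AnalysisResult(annotations, metrics, qc, noise, method)

    rate = recording.sampling_rate_hz
    n = len(recording)
    step = int(round(chunk_s * rate))
    pad = int(round(_CHUNK_OVERLAP_S * rate))
    parts_ann, parts_met = [], []
    sample_bad = np.zeros(n, dtype=bool)

    for core_lo in range(0, n, step):
        core_hi = min(core_lo + step, n)
        lo = max(core_lo - pad, 0)
        hi = min(core_hi + pad, n)
        chunk = PressureRecording(recording.samples[lo:hi], rate,
                                  recording.start_time, recording.units,
                                  recording.gap_mask[lo:hi])
        ann, met, deriv = _analyze_whole(chunk, config, method)
        qc_chunk = qc_recording(ann, chunk, config, deriv)
        for s0, s1 in qc_chunk.artifact_intervals:
            i0, i1 = int(s0 * rate), int(s1 * rate)
            i0, i1 = max(i0 + lo, core_lo), min(i1 + lo, core_hi)
            if i1 > i0:
                sample_bad[i0:i1] = True
        keep = ((ann.onset_idx + lo >= core_lo)
                & (ann.onset_idx + lo < core_hi)
                & (ann.end_idx + lo <= hi))
        if core_hi < n:
            # beats cut by the chunk tail re-appear whole in the next chunk
            keep &= ann.end_idx < (hi - lo)
        idx = np.flatnonzero(keep)
        if len(idx) == 0:
            continue
        parts_ann.append(BeatAnnotations(
            ann.onset_idx[idx] + lo, ann.dpdt_max_idx[idx] + lo,
            ann.systolic_peak_idx[idx] + lo, ann.neg_dpdt_max_idx[idx] + lo,
            ann.end_idx[idx] + lo, ann.rr_s[idx],
            [ann.flags[i] for i in idx], rate))
        met = met.iloc[idx].copy()
        met["onset_s"] += lo / rate
        parts_met.append(met)

    if parts_ann:
        annotations = BeatAnnotations(
            np.concatenate([a.onset_idx for a in parts_ann]),
            np.concatenate([a.dpdt_max_idx for a in parts_ann]),
            np.concatenate([a.systolic_peak_idx for a in parts_ann]),
            np.concatenate([a.neg_dpdt_max_idx for a in parts_ann]),
            np.concatenate([a.end_idx for a in parts_ann]),
            np.concatenate([a.rr_s for a in parts_ann]),
            sum((a.flags for a in parts_ann), []), rate)
        metrics = pd.concat(parts_met, ignore_index=True)
    else:
        annotations = BeatAnnotations.empty(rate)
        metrics = compute_all_metrics(annotations, recording,
                                      DerivativeSeries(np.zeros(0), rate, method),
                                      config)
    qc = qc_recording(annotations, recording, config,
                      precomputed_bad=sample_bad)
    return AnalysisResult(annotations, metrics, qc, noise, method)


def summarize_metrics(metrics: pd.DataFrame) -> pd.Series:
    """Robust per-recording summary: median of each index over valid beats."""
    params = ["heart_rate_bpm", "mean_lvp_mmHg", "lvsp_mmHg", "lvedp_mmHg",
              "dpdt_max_mmHg_per_s", "vmax_per_s", "neg_dpdt_max_mmHg_per_s",
              "tau66_ms"]
    if metrics.empty:
        return pd.Series({p: np.nan for p in params})
    valid = metrics[metrics["valid"]] if "valid" in metrics else metrics
    if valid.empty:
        valid = metrics
    return valid[params].median()
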