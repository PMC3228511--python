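"""Figures for telemetry reports: multi-day trends and waveform snippets."""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .trend import PARAMETERS
from .waveio import PressureRecording

__all__ = ["trend_figure", "waveform_snippet_figure"]

_LABELS = {
    "heart_rate_bpm": "Heart rate (bpm)",
    "mean_lvp_mmHg": "Mean LVP (mmHg)",
    "lvsp_mmHg": "LVSP (mmHg)",
    "lvedp_mmHg": "LVEDP (mmHg)",
    "dpdt_max_mmHg_per_s": "dP/dt$_{max}$ (mmHg/s)",
    "vmax_per_s": "V$_{max}$ (1/s)",
    "neg_dpdt_max_mmHg_per_s": "-dP/dt$_{max}$ (mmHg/s)",
    "tau66_ms": "Tau (ms)",
}


def trend_figure(trend: pd.DataFrame, parameters: list | None = None,
                 max_error_bars: int = 48):
    """Moving-average traces with SEM error bars, one panel per parameter."""
    if parameters is None:
        parameters = [p for p in PARAMETERS if p in trend.columns]
    ncols = 2
    nrows = (len(parameters) + 1) // ncols
    fig, axes = plt.subplots(nrows, ncols, figsize=(10, 2.4 * nrows),
                             squeeze=False, sharex=True)
    t_h = trend["t_center_s"].to_numpy() / 3600.0
    stride = max(len(trend) // max_error_bars, 1)
    for ax, p in zip(axes.flat, parameters):
        ax.plot(t_h, trend[p], lw=1.0, color="tab:blue")
        sem = trend.get(p + "_sem")
        if sem is not None:
            ax.errorbar(t_h[::stride], trend[p].to_numpy()[::stride],
                        yerr=sem.to_numpy()[::stride], fmt="none",
                        ecolor="tab:blue", alpha=0.5, capsize=2)
        ax.set_ylabel(_LABELS.get(p, p), fontsize=8)
        ax.tick_params(labelsize=8)
    for ax in axes.flat[len(parameters):]:
        ax.set_visible(False)
    for ax in axes[-1]:
        ax.set_xlabel("Time (h)")
    fig.tight_layout()
    return fig


def waveform_snippet_figure(recording: PressureRecording, t_start_s: float = 0.0,
                            duration_s: float = 3.0):
    """Pressure waveform over a short interval (default 3 s)."""
    rate = recording.sampling_rate_hz
    i0 = max(int(t_start_s * rate), 0)
    i1 = min(int((t_start_s + duration_s) * rate), len(recording))
    t = np.arange(i0, i1) / rate
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.plot(t, recording.samples[i0:i1], lw=0.8, color="tab:red")
    ax.set_xlabel("Time (s)")
    ax.set_ylabel(f"LVP ({recording.units})")
    fig.tight_layout()
    return fig
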