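"""Epoch, moving-average, and daily reduction of per-beat metrics.

The acquisition scheme this mirrors records continuously and summarises the
stream in contiguous 20-s epochs; 1-h moving averages (mean with standard
error over the epochs inside the window) are what multi-day baseline figures
plot, and per-24-h-day mean +/- SEM tables are how the indices are reported.

Conventions: epochs tile ``[0, duration)`` half-open and beats belong to the
epoch holding their onset; the moving window is trailing (right-aligned) and
emitted only when complete; missing epochs (no valid beats) are excluded from
window and day means rather than zero-filled; SEM = sd / sqrt(n) over epoch
means, with sd the n-1 sample standard deviation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigError

__all__ = ["PARAMETERS", "epoch_summarize", "moving_average",
           "daily_summary", "daily_summary_table"]

#: the eight monitored parameters, in reporting order
PARAMETERS = ["heart_rate_bpm", "mean_lvp_mmHg", "lvsp_mmHg", "lvedp_mmHg",
              "dpdt_max_mmHg_per_s", "vmax_per_s", "neg_dpdt_max_mmHg_per_s",
              "tau66_ms"]


def epoch_summarize(metrics: pd.DataFrame, epoch_s: float = 20.0,
                    duration_s: float | None = None) -> pd.DataFrame:
    """Reduce per-beat metrics to fixed-length epoch means.

    Beats flagged invalid by QC are excluded from the means and counted in
    ``artifact_fraction``; epochs without valid beats carry NaN means. The
    epoch grid covers ``[0, duration_s)`` (defaulting to the end of the last
    beat, rounded up to a whole epoch).
    """
    if epoch_s <= 0:
        raise ConfigError("epoch length must be positive")
    if metrics.empty and duration_s is None:
        raise ConfigError("cannot infer the epoch grid from an empty table")
    if duration_s is None:
        duration_s = float(metrics.onset_s.max()) + 1e-9
    n_epochs = int(np.ceil(duration_s / epoch_s - 1e-9))

    base = pd.DataFrame({
        "epoch_idx": np.arange(n_epochs),
        "start_s": np.arange(n_epochs) * epoch_s,
        "end_s": (np.arange(n_epochs) + 1) * epoch_s,
    })
    if metrics.empty:
        out = base
        out["n_beats"] = 0
        out["artifact_fraction"] = 0.0
        for p in PARAMETERS:
            out[p] = np.nan
        return out

    idx = np.floor(metrics.onset_s.to_numpy() / epoch_s).astype(int)
    idx = np.clip(idx, 0, n_epochs - 1)
    valid = metrics["valid"].to_numpy() if "valid" in metrics \
        else np.ones(len(metrics), dtype=bool)

    g_all = pd.Series(1, index=idx).groupby(level=0).size()
    g_bad = pd.Series((~valid).astype(int), index=idx).groupby(level=0).sum()
    mv = metrics.loc[valid, PARAMETERS].copy()
    mv.index = idx[valid]
    g_mean = mv.groupby(level=0).mean()

    out = base.set_index("epoch_idx")
    out["n_beats"] = g_all.reindex(out.index, fill_value=0) \
        - g_bad.reindex(out.index, fill_value=0)
    total = g_all.reindex(out.index, fill_value=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out["artifact_fraction"] = np.where(
            total > 0, g_bad.reindex(out.index, fill_value=0) / total, 0.0)
    for p in PARAMETERS:
        out[p] = g_mean[p].reindex(out.index) if p in g_mean else np.nan
    return out.reset_index()


def moving_average(epochs: pd.DataFrame, window_s: float = 3600.0,
                   alignment: str = "trailing") -> pd.DataFrame:
    """Sliding mean and SEM over epoch means; complete windows only.

    Each output row covers the ``window_s`` ending at that epoch (trailing
    alignment); ``t_center_s`` marks the window centre for plotting. Missing
    epochs inside a window are skipped, and ``n_epochs`` counts the epochs
    that did contribute.
    """
    if alignment != "trailing":
        raise ConfigError("only trailing alignment is implemented")
    if epochs.empty:
        return pd.DataFrame()
    epoch_s = float(epochs.end_s.iloc[0] - epochs.start_s.iloc[0])
    w = int(round(window_s / epoch_s))
    if w < 1:
        raise ConfigError("window must cover at least one epoch")
    if len(epochs) < w:
        return pd.DataFrame()

    out = pd.DataFrame({
        "t_start_s": epochs.start_s.to_numpy()[w - 1:] - (w - 1) * epoch_s,
        "t_center_s": epochs.end_s.to_numpy()[w - 1:] - window_s / 2.0,
        "t_end_s": epochs.end_s.to_numpy()[w - 1:],
    })
    n_any = None
    for p in PARAMETERS:
        s = epochs[p]
        roll = s.rolling(w, min_periods=1)
        cnt = roll.count().to_numpy()[w - 1:]
        mean = roll.mean().to_numpy()[w - 1:]
        sd = s.rolling(w, min_periods=2).std(ddof=1).to_numpy()[w - 1:]
        with np.errstate(invalid="ignore", divide="ignore"):
            sem = np.where(cnt > 0, sd / np.sqrt(cnt), np.nan)
        out[p] = np.where(cnt > 0, mean, np.nan)
        out[p + "_sem"] = sem
        if n_any is None:
            n_any = cnt
    out["n_epochs"] = n_any.astype(int)
    return out


def daily_summary(epochs: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SEM of each parameter per 24-h day (long format).

    One row per (day, parameter); a trailing partial day is reported with its
    actual epoch count and ``partial=True``.
    """
    if epochs.empty:
        return pd.DataFrame(columns=["day", "parameter", "mean", "sem",
                                     "n_epochs", "partial"])
    epoch_s = float(epochs.end_s.iloc[0] - epochs.start_s.iloc[0])
    day = np.floor(epochs.start_s.to_numpy() / 86400.0).astype(int)
    per_day = int(round(86400.0 / epoch_s))
    total_epochs = len(epochs)

    rows = []
    for d in np.unique(day):
        sel = epochs[day == d]
        spanned = min((d + 1) * per_day, total_epochs) - d * per_day
        partial = spanned < per_day
        for p in PARAMETERS:
            vals = sel[p].dropna()
            rows.append({
                "day": int(d) + 1,
                "parameter": p,
                "mean": float(vals.mean()) if len(vals) else np.nan,
                "sem": float(vals.std(ddof=1) / np.sqrt(len(vals)))
                       if len(vals) > 1 else np.nan,
                "n_epochs": int(len(vals)),
                "partial": bool(partial),
            })
    return pd.DataFrame(rows)


def daily_summary_table(daily: pd.DataFrame, precision: int = 1) -> pd.DataFrame:
    """Pivot the daily summary into a parameter x day grid of 'mean ± sem'."""
    if daily.empty:
        return pd.DataFrame()

    def fmt(row):
        if not np.isfinite(row["mean"]):
            return "–"
        return f"{row['mean']:.{precision}f} ± {row['sem']:.{precision}f}"

    tab = daily.copy()
    tab["cell"] = tab.apply(fmt, axis=1)
    wide = tab.pivot(index="parameter", columns="day", values="cell")
    wide = wide.reindex(PARAMETERS)
    wide.columns = [f"day_{c}" for c in wide.columns]
    return wide
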