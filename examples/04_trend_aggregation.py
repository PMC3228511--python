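"""From per-beat metrics to 20-s epochs, 1-h moving averages, daily tables.

Simulates two hours of baseline telemetry, analyses it in chunks, and
reduces the beats to the reporting shapes multi-day studies use.
"""

from lvpress import (SimConfig, analyze_recording, daily_summary,
                     daily_summary_table, epoch_summarize, moving_average,
                     simulate)

cfg = SimConfig(duration_s=7200.0, noise_sd_mmHg=0.5, rr_cv=0.02, seed=4)
recording, _ = simulate(cfg)
result = analyze_recording(recording, chunk_s=1800.0)

epochs = epoch_summarize(result.metrics, epoch_s=20.0, duration_s=7200.0)
trend = moving_average(epochs, window_s=3600.0)
daily = daily_summary(epochs)

print(f"{len(result.metrics)} beats -> {len(epochs)} epochs of 20 s "
      f"(~{epochs.n_beats.median():.0f} beats each)")
print(f"1-h moving average: {len(trend)} points "
      f"(first complete window ends at t={trend.t_end_s.iloc[0]:.0f} s)")
hr = trend.heart_rate_bpm
print(f"HR trend {hr.min():.1f}-{hr.max():.1f} bpm, "
      f"SEM ~{trend.heart_rate_bpm_sem.median():.2f} bpm — a flat baseline")
print("\nPer-day mean ± SEM (partial trailing day flagged in daily.partial):")
print(daily_summary_table(daily).to_string())
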