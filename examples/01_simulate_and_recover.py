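"""Simulate baseline LVP telemetry and recover its physiology blind.

Builds a 10-minute recording for a synthetic resting animal, analyses it
without peeking at the truth, and compares the recovered per-beat indices
to the configured values.
"""

from lvpress import SimConfig, analyze_recording, simulate, summarize_metrics

cfg = SimConfig(duration_s=600.0, heart_rate_bpm=250.0, lvsp_mmHg=104.0,
                lvedp_mmHg=18.0, diastolic_floor_mmHg=12.0,
                dpdt_max_mmHg_per_s=3300.0, neg_dpdt_max_mmHg_per_s=2700.0,
                tau66_ms=33.0, noise_sd_mmHg=0.5, seed=7)
recording, truth = simulate(cfg)
result = analyze_recording(recording)
recovered = summarize_metrics(result.metrics)

print(f"{truth.n_beats} true beats, {len(result.annotations)} detected, "
      f"derivative method: {result.derivative_method}")
print(f"{'index':<26}{'configured':>12}{'recovered':>12}")
for name, true in [("heart_rate_bpm", 250.0), ("lvsp_mmHg", 104.0),
                   ("lvedp_mmHg", 18.0), ("dpdt_max_mmHg_per_s", 3300.0),
                   ("neg_dpdt_max_mmHg_per_s", 2700.0), ("tau66_ms", 33.0)]:
    print(f"{name:<26}{true:>12.1f}{recovered[name]:>12.1f}")
print("\nEach row compares the ground-truth physiology driving the")
print("simulator with the median per-beat estimate from the blind analysis.")
print("The design target is 1 bpm / 0.5 mmHg / 2% / 2 ms on noise-free")
print("data; the 0.5 mmHg sensor noise here roughly doubles the residuals.")
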