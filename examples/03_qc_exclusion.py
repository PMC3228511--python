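"""Quality control: an arrhythmic recording is excluded, a clean one kept.

Telemetry studies drop animals whose traces carry frequent ectopy (e.g. an
arrhythmia provoked by the implantation surgery). Here the same synthetic
animal is simulated twice — once clean, once with a 20% ectopic beat
fraction — and run through QC.
"""

from lvpress import SimConfig, analyze_recording, simulate

for label, rate in (("clean", 0.0), ("arrhythmic", 0.2)):
    cfg = SimConfig(duration_s=120.0, ectopic_rate=rate,
                    noise_sd_mmHg=0.5, seed=5)
    recording, truth = simulate(cfg)
    qc = analyze_recording(recording).qc
    verdict = "EXCLUDED" if qc.excluded else "retained"
    print(f"{label:<11} beats={qc.n_beats:<4} "
          f"irregular={qc.irregular_fraction:.1%} -> {verdict}"
          + (f"  ({'; '.join(qc.reasons)})" if qc.reasons else ""))

print("\nA beat is irregular when its RR deviates >25% from the local")
print("median; a recording is excluded above 5% irregular beats (or 10%")
print("artifact time), mirroring how an arrhythmic animal is dropped from")
print("a baseline cohort.")
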