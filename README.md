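# lvpress

Analysis of continuously telemetered **left-ventricular pressure (LVP)**,
built for the small-animal setting: a conscious, unrestrained animal (the
reference preparation is the rabbit) carrying an implanted pressure catheter
whose transmitter streams LVP at 500 Hz for days at a time. From the raw
samples the package produces, per beat, the standard contractility and
relaxation indices, and reduces days of beats to the epoch / moving-average /
daily summaries such studies report.

The eight monitored parameters are heart rate, mean LVP, LVSP, LVEDP,
dP/dt_max, V_max, −dP/dt_max and Tau, with

* **LVSP** the peak pressure after the detected dP/dt_max and **LVEDP** the
  pressure at end-diastole,
* **dP/dt_max** (and the magnitude **−dP/dt_max**) the extreme pressure
  slopes of isovolumic contraction and relaxation,
* **V_max** the peak pressure-normalised dP/dt during isovolumic
  contraction (1/s),
* **Tau** the relaxation time from −dP/dt_max to the point where pressure
  has dropped 66% of the systolic-to-diastolic distance:
  the first crossing of `P_tgt = LVSP − 0.66·(LVSP − LVEDP)`.

Because telemetry of this kind is rarely published as raw data, the package
includes a first-class **waveform simulator** (`lvpress.sim`) whose beats
are assembled from an analytic template: every index above has a closed-form
value and location on the template, so the whole pipeline can be validated
end-to-end against known truth — including RR jitter, sensor noise,
circadian drift, ectopic beats and catheter wall-contact artifacts.

Also included: transmitter calibration (affine fit of the 750/850/950 mmHg
chamber points, ambient-pressure subtraction), beat detection with QC and an
arrhythmia exclusion rule, and a text waveform format with lossless
round-trips.

## Worked example

```python
from lvpress import (SimConfig, simulate, analyze_recording,
                     summarize_metrics, epoch_summarize, daily_summary_table,
                     daily_summary)

# a baseline "animal": 10 minutes at 240 bpm, LVSP 107 / LVEDP 20 mmHg,
# dP/dt_max 3000 mmHg/s, Tau66 30 ms, 0.5 mmHg sensor noise
cfg = SimConfig(duration_s=600.0, seed=1)
recording, truth = simulate(cfg)

result = analyze_recording(recording)
print(len(result.annotations), "beats;",
      "excluded" if result.qc.excluded else "retained")
print(summarize_metrics(result.metrics).round(2))
```

prints

```
2401 beats; retained
heart_rate_bpm              240.08
mean_lvp_mmHg                55.38
lvsp_mmHg                   107.52
lvedp_mmHg                   20.28
dpdt_max_mmHg_per_s        3034.95
vmax_per_s                   67.89
neg_dpdt_max_mmHg_per_s    2535.68
tau66_ms                     27.65
dtype: float64
```

i.e. the analysis recovers the configured physiology: heart rate within a
fraction of a bpm, pressures within ~0.5 mmHg, slopes within ~1.5% and Tau
within ~2.5 ms of the 30 ms truth under 0.5 mmHg noise (the residuals come
from the noise-adaptive smoothing). Reducing the beats to the reporting
shapes:

```python
epochs = epoch_summarize(result.metrics, epoch_s=20.0, duration_s=600.0)
print(daily_summary_table(daily_summary(epochs)))   # mean ± SEM per day
```

The `examples/` directory holds one short script per capability
(simulation & recovery, calibration, QC/exclusion, trend aggregation,
waveform morphology); each prints the numbers it computes and what they
mean. A thin CLI wraps the same functions:

```sh
lvpress simulate --seed 7 --duration 600 --out-dir run/
lvpress analyze run/waveform.txt --out-dir run/
lvpress trend run/metrics.csv --duration 600 --out-dir run/
lvpress report run/ --waveform run/waveform.txt
```

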