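# Methods

## Scope and model

`lvpress` analyses continuously telemetered left-ventricular pressure (LVP)
from small animals — the setting is a conscious, unrestrained rabbit with a
fluid-filled intraventricular catheter sampled at 500 Hz — and reduces it to
the eight routinely monitored indices per beat:

| index | definition used here | units |
|---|---|---|
| heart rate | 60 / RR, RR from onset to onset | bpm |
| mean LVP | average pressure over the half-open beat [onset, end) | mmHg |
| LVSP | peak pressure between dP/dt_max and −dP/dt_max | mmHg |
| LVEDP | pressure at the onset (end-diastole) fiducial | mmHg |
| dP/dt_max | maximum rate of pressure rise (isovolumic contraction) | mmHg/s |
| V_max | peak of (dP/dt)/max(P, 1 mmHg) over onset→dP/dt_max | 1/s |
| −dP/dt_max | magnitude of the steepest pressure fall (isovolumic relaxation) | mmHg/s |
| Tau66 | time from −dP/dt_max to the first crossing of LVSP − 0.66·(LVSP − LVEDP), linearly interpolated between samples | ms |

Two of these required a design decision because the acquisition vendors do
not document their formulas:

* **V_max.** We use the peak pressure-normalised derivative during
  isovolumic contraction, the standard load-independent contractility index
  with the right units. With end-diastolic pressures of 17–24 mmHg the
  denominator never approaches zero, so values come out of order 10² 1/s.
  Published tables from vendor software print order 10³, which would require
  normalising by a near-zero (e.g. developed) pressure; absolute V_max values
  from different software are therefore not comparable, and ours should be
  read as internally consistent only.
* **"Diastolic" in the 66% rule.** Taken to be the same beat's LVEDP (not
  the relaxation asymptote); it is measurable per beat and keeps the rule
  self-contained.

## Synthetic telemetry with closed-form ground truth

No public recordings exist for this preparation, so validation rests on a
simulator whose every index is analytic. One beat is a piecewise-smooth
template:

1. diastolic hold at LVEDP (12 ms);
2. upstroke whose *slope profile* is a sin² ease-in, a 6 ms constant span at
   exactly dP/dt_max, and a symmetric ease-out — the total rise is
   LVSP − LVEDP, which fixes the ease duration at Δ/dP/dt_max − 6 ms;
3. a systolic hold at LVSP (40 ms) giving the waveform its dome; without it
   the duty cycle is too lean and mean LVP falls below the 52–63 mmHg band
   real baseline rabbits show;
4. a fall mirroring the rise: sin² ease-in of duration `a_f`, 6 ms at
   exactly −dP/dt_max, then an ease-out to a fraction β of −dP/dt_max;
5. a monoexponential tail toward a configurable diastolic floor whose
   constant is `(P_join − floor)/(β·|−dP/dt_max|)` (slope-continuous join);
6. a raised-cosine refill back to LVEDP at the next onset.

The free fall parameters `(a_f, β)` are solved per configuration so the 66%
target is crossed exactly `tau66` after the −dP/dt_max point. The solver
scans `a_f` upward from 10 ms and takes the smallest value admitting a
β ∈ [0.02, 0.98] (Brent root find). Preferring small `a_f` keeps the
−dP/dt_max point high on the pressure span, so the tail crosses the target
at a healthy slope; deep-drop solutions exist too but leave a nearly flat
tail at the target, where any readout bias converts to milliseconds of Tau
error. The constant-slope spans exist so a sampled finite-difference
analyser can attain the configured extrema exactly; the earliest attainment
time is the fiducial truth.

Some index combinations are geometrically impossible — e.g. 300 bpm with the
widest pressure span, the slowest upstroke and a 54 ms Tau does not fit in a
200 ms RR interval, and a very short Tau with a slow fall cannot drop 66% of
the span in time. These raise an infeasible-beat error; sweeps over the
physiological box reject and redraw such corners (about 1–2% of draws).

Around the template: lognormal RR jitter (configurable CV), additive white
Gaussian sensor noise, a 24-h sinusoidal drift standing in for circadian
variation, premature (ectopic) beats — onset pulled to 65% of the prior RR,
systolic pressure attenuated to 75% of developed pressure, followed by the
compensatory pause; the next onset is unchanged so injection is local — and
catheter wall-contact bursts (50 Hz, 35 mmHg, 0.2–2 s, Poisson arrivals).
Every random element draws from a tagged RNG sub-stream derived from the
seed, so toggling one artifact type never shifts another.

What the generator does *not* emulate: beat-to-beat morphology variation
beyond RR and artifacts, respiratory modulation, baroreflex dynamics,
catheter resonance/damping, or inter-animal template differences. Passing
round-trip tests therefore demonstrates correctness of the estimators on
waveforms with known truth, not robustness to every pathology of real
telemetry.

## Analysis pipeline

**Derivative.** Central difference `(P[i+1] − P[i−1])·rate/2` (one-sided at
edges) is exact on the template's constant-slope spans. Under broadband
noise it amplifies by rate/√2, so the pipeline's `auto` mode estimates the
noise SD robustly from the second difference (`1.4826·MAD/√6`) and switches
to a Savitzky–Golay derivative (window 9, order 3) above 0.1 mmHg; pressure
readouts then come from the equally smoothed signal. Extremum *values* on
the smoothed branch are read as a 3-sample local mean at the fiducial: the
single argmax sample of a noisy series is a max-statistic (biased high), and
the polynomial fit also overshoots at the edges of a flat extremum.

**Detection.** Candidate beats are local maxima of dP/dt above
0.3 × the rolling 10-s derivative maximum (with a 250 mmHg/s absolute
floor), separated by a 150 ms refractory period. Onset is the last upward
crossing of 4% of the beat's dP/dt_max before it — 4% rather than a larger
fraction because on a smooth upstroke the crossing pressure grows with the
threshold; at 4% it sits within ~0.3 mmHg of true end-diastole. RR intervals
use sub-sample interpolated crossing times, removing the ±1-sample
quantisation that otherwise costs up to 1 bpm at 300 bpm. The systolic peak
is the earliest maximum pressure between dP/dt_max and the next candidate;
−dP/dt_max the earliest interval minimum of dP/dt.

**Tau66 reference refinement.** A discrete argmin on a flat derivative
extremum lands up to two samples after the extremum begins. The estimator
walks back through a 1% tolerance band and linearly interpolates the band
entry, recovering the start of the extremum to sub-sample resolution; the
66% crossing itself is linearly interpolated. Residual bias is ≲1 ms at
500 Hz.

**QC.** A beat is irregular if its RR deviates >25% from the median RR of
the surrounding 30 s. Artifact samples are gaps, pressures outside
0–250 mmHg, or |dP/dt| > 8000 mmHg/s (above any physiological upstroke,
below wall-contact bursts), dilated by 50 ms. A recording is excluded when
irregular beats exceed 5% or artifact time exceeds 10% — the judgement
applied when a surgically provoked arrhythmia makes an animal unusable. The
thresholds are conventions, exposed in `AnalysisConfig` and echoed in the
QC report.

**Aggregation.** Beats → contiguous 20-s epochs (mean per parameter over
QC-valid beats; invalid beats counted in an artifact fraction) → trailing
1-h moving average with SEM = sd/√n over the epochs in the window (emitted
only for complete windows) → per-24-h-day mean ± SEM rows, the layout used
for multi-day baseline tables. Epochs tile [0, duration) half-open; a beat
belongs to the epoch containing its onset; missing epochs are skipped, not
zero-filled. Long recordings are analysed in fixed chunks with a 2-s
overlap, beats attributed to the chunk holding their onset; results are
independent of the chunk length.

## Numerical choices and degenerate inputs

* Ties in every argmax/argmin resolve to the earliest sample.
* 0-based sample indexing; sample *i* at `start_time + i/rate`; all windows
  half-open.
* Calibration is an affine least-squares fit of pressure on raw transmitter
  output; three chamber points (750/850/950 mmHg) over-determine the line
  and the residuals are reported as a device health check rather than
  silently absorbed. Fewer than two distinct points, or zero output spread,
  is an error. Gauge pressure = affine(raw) − ambient, with the ambient
  series linearly resampled onto the recording grid when rates differ.
* A beat whose Tau target is never crossed, or whose V_max window has no
  positive pressure, is flagged (NaN) rather than raised; flagged beats are
  excluded from epoch means.
* Waveform text I/O writes `%.10g`, making serialise→parse→serialise a text
  fixed point; `NA` lines are gaps and gaps propagate through the
  derivative stencil.

## Problem sizes

Default validation runs use 10-minute recordings (≈2,400 beats at 240 bpm)
for parameter-recovery sweeps, 2-minute recordings for QC behaviour, and one
full 72-h simulation (≈1.0×10⁶ beats, 1.3×10⁸ samples, analysed in 1-h
chunks) to exercise the complete reporting structure: 12,960 epochs, a
12,781-point 1-h moving-average trend, and three daily rows per parameter.

## Known limitations

* The template is one morphology; real animals differ in waveform shape,
  and indices whose value depends on shape details (V_max especially) will
  track those differences.
* Tau66 is a threshold-crossing statistic, not a regression fit; on
  non-monoexponential relaxations it measures the literal 66% time, which
  is the intended definition but not comparable to regression-based τ.
* The QC irregularity test detects rhythm disturbances via RR deviation
  only; it does not classify arrhythmias.
* Calibration assumes an affine transmitter response; the residual report
  is the only guard against curvature.
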