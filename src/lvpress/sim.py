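"""Synthetic LVP telemetry with analytically known ground truth.

The simulator stands in for undeposited animal telemetry: it concatenates
analytic beat templates (:mod:`lvpress.template`) with lognormal RR jitter,
additive Gaussian sensor noise and a slow sinusoidal circadian drift, sampled
on the acquisition grid. Every monitored index of every beat is known in
closed form and reported in the ground-truth beat table, which is what the
round-trip recovery tests measure the analysis pipeline against.

Artifact injection emulates the two failure modes a telemetered ventricular
catheter actually shows: premature (ectopic) beats that disturb the RR
rhythm, and transient high-frequency pressure deflections from catheter
contact with the ventricular wall.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import SimConfig
from .errors import InfeasibleBeatError
from .template import BeatGeometry, BeatParams, geometry_for, solve_tau_exp
from .waveio import PressureRecording

__all__ = ["GroundTruth", "beat_template", "simulate_recording",
           "inject_artifacts", "simulate", "solve_tau_exp"]


def beat_template(config: "SimConfig", rr_s: float) -> BeatGeometry:
    """Solved continuous-time pressure template for one beat.

    The returned geometry evaluates pressure and slope at arbitrary times
    (``geo.pressure(u, rr_s)``) and carries the analytic index values and
    fiducial times the ground truth reports. Raises
    :class:`InfeasibleBeatError` when the morphology cannot fit in ``rr_s``.
    """
    return geometry_for(_params_from_config(config), rr_s)

# RNG sub-stream tags, so toggling one randomness source never shifts another
_RNG_RR, _RNG_NOISE, _RNG_ECTOPIC, _RNG_SPLICE, _RNG_WALL = range(5)

_ECTOPIC_EARLY = 0.65       # premature onset at this fraction of the prior RR
_ECTOPIC_LVSP_FRAC = 0.75   # developed-pressure attenuation of the ectopic
_ECTOPIC_DPDT_FRAC = 0.80
_ECTOPIC_NEG_FRAC = 0.85
_WALL_FREQ_HZ = 50.0
_WALL_AMP_MMHG = 35.0


@dataclass
class GroundTruth:
    """Per-beat truth table, artifact intervals, and the generating config.

    ``beats`` has one row per complete beat: onset time, RR, and the true
    value of each monitored index for that beat (including drift).
    ``artifacts`` is a list of ``(start_s, end_s, kind)`` intervals.
    """

    beats: pd.DataFrame
    artifacts: list = field(default_factory=list)
    config: SimConfig = None  # type: ignore[assignment]

    @property
    def n_beats(self) -> int:
        return len(self.beats)

    def to_files(self, beats_path, sidecar_path) -> None:
        """CSV beat table plus a JSON sidecar of config and artifacts."""
        self.beats.to_csv(beats_path, index=False, float_format="%.10g")
        payload = {
            "config": self.config.model_dump() if self.config else None,
            "artifacts": [
                {"start_s": s, "end_s": e, "kind": k}
                for s, e, k in self.artifacts
            ],
        }
        with open(sidecar_path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)


def _params_from_config(config: SimConfig) -> BeatParams:
    return BeatParams(
        lvsp=config.lvsp_mmHg,
        lvedp=config.lvedp_mmHg,
        floor=config.diastolic_floor_mmHg,
        dpdt_max=config.dpdt_max_mmHg_per_s,
        neg_dpdt_max=config.neg_dpdt_max_mmHg_per_s,
        tau66_s=config.tau66_ms / 1e3,
    )


class _GeometryCache:
    """Geometry solve is ~1 ms; beats reuse it keyed by (params, min rr ok)."""

    def __init__(self):
        self._store: dict = {}

    def get(self, params: BeatParams, rr_s: float) -> BeatGeometry:
        geo = self._store.get(params)
        if geo is None or rr_s < geo.min_rr:
            geo = geometry_for(params, rr_s)
            # keep the most permissive geometry seen for these params
            self._store[params] = geo
        return geo


def _render_beat(samples: np.ndarray, geo: BeatGeometry, onset_s: float,
                 rr_s: float, rate: float) -> None:
    n = len(samples)
    i0 = int(np.ceil(onset_s * rate - 1e-9))
    i1 = min(int(np.ceil((onset_s + rr_s) * rate - 1e-9)), n)
    if i1 <= i0:
        return
    u = np.arange(i0, i1) / rate - onset_s
    samples[i0:i1] = geo.pressure(u, rr_s)


def _truth_row(geo: BeatGeometry, onset_s: float, rr_s: float, drift: float,
               vmax: float, ectopic: bool) -> dict:
    p = geo.params
    return {
        "onset_s": onset_s,
        "rr_s": rr_s,
        "heart_rate_bpm": 60.0 / rr_s,
        "mean_lvp_mmHg": geo.mean_pressure(rr_s) + drift,
        "lvsp_mmHg": p.lvsp + drift,
        "lvedp_mmHg": p.lvedp + drift,
        "dpdt_max_mmHg_per_s": p.dpdt_max,
        "vmax_per_s": vmax,
        "neg_dpdt_max_mmHg_per_s": p.neg_dpdt_max,
        "tau66_ms": p.tau66_s * 1e3,
        "t_dpdt_max_s": onset_s + geo.t_rise1,
        "t_peak_s": onset_s + geo.t_peak,
        "t_neg_dpdt_max_s": onset_s + geo.t_f1,
        "is_ectopic": ectopic,
    }


def _drift(config: SimConfig, t):
    if config.drift_amplitude_mmHg == 0:
        return np.zeros_like(np.asarray(t, dtype=float))
    return config.drift_amplitude_mmHg * np.sin(
        2 * np.pi * np.asarray(t, dtype=float) / (config.drift_period_h * 3600.0))


def simulate_recording(config: SimConfig) -> tuple[PressureRecording, GroundTruth]:
    """Render a clean recording (noise + drift, no artifacts) with its truth.

    Deterministic given ``config.seed``: the RR sequence and the sensor noise
    come from independent, tagged RNG sub-streams.
    """
    rate = config.sampling_rate_hz
    duration = config.duration_s
    n = int(round(duration * rate))
    samples = np.empty(n)

    params = _params_from_config(config)
    cache = _GeometryCache()
    mean_rr = 60.0 / config.heart_rate_bpm

    rng_rr = np.random.default_rng([config.seed, _RNG_RR])
    if config.rr_cv > 0:
        sigma = np.sqrt(np.log1p(config.rr_cv ** 2))
        mu = np.log(mean_rr) - 0.5 * sigma ** 2
        # draw generously; HR < 600 bpm guarantees < duration/0.1 beats
        n_max = int(duration / (mean_rr * 0.5)) + 20
        rr_draws = rng_rr.lognormal(mu, sigma, size=n_max)
    else:
        n_max = int(np.ceil(duration / mean_rr)) + 2
        rr_draws = np.full(n_max, mean_rr)

    rows = []
    onset = 0.0
    vmax_memo: dict[int, float] = {}
    for k in range(n_max):
        if onset >= duration - 1e-9:
            break
        rr = float(rr_draws[k])
        geo = cache.get(params, rr)
        rr = max(rr, geo.min_rr)
        _render_beat(samples, geo, onset, rr, rate)
        if onset + rr <= duration + 1e-9:
            vmax = vmax_memo.get(id(geo))
            if vmax is None:
                vmax = geo.vmax(grid_hz=20_000.0)
                vmax_memo[id(geo)] = vmax
            drift = float(_drift(config, onset))
            rows.append(_truth_row(geo, onset, rr, drift, vmax, False))
        onset += rr

    t = np.arange(n) / rate
    samples += _drift(config, t)
    if config.noise_sd_mmHg > 0:
        rng_noise = np.random.default_rng([config.seed, _RNG_NOISE])
        samples += rng_noise.normal(0.0, config.noise_sd_mmHg, size=n)

    recording = PressureRecording(samples, rate, units="mmHg",
                                  gap_mask=np.zeros(n, dtype=bool))
    truth = GroundTruth(pd.DataFrame(rows), [], config)
    return recording, truth


def _ectopic_params(params: BeatParams) -> BeatParams:
    lvsp_e = params.lvedp + _ECTOPIC_LVSP_FRAC * (params.lvsp - params.lvedp)
    return replace(params,
                   lvsp=lvsp_e,
                   dpdt_max=_ECTOPIC_DPDT_FRAC * params.dpdt_max,
                   neg_dpdt_max=_ECTOPIC_NEG_FRAC * params.neg_dpdt_max)


def inject_artifacts(recording: PressureRecording, config: SimConfig,
                     seed: int | None = None,
                     truth: GroundTruth | None = None,
                     ) -> tuple[PressureRecording, GroundTruth]:
    """Insert ectopic beats and wall-contact transients, logging both.

    Ectopic beats are chosen by a per-beat Bernoulli draw at
    ``config.ectopic_rate``: the chosen beat is re-rendered prematurely (onset
    pulled to 65% of the preceding RR, systolic pressure and dP/dt attenuated)
    and is followed by the resulting compensatory pause; the next onset is
    unchanged, so the rest of the recording is untouched. Wall-contact events
    arrive as a Poisson process at ``config.wall_contact_rate`` per hour and
    superimpose a 0.2-2 s burst of high-frequency, high-amplitude deflection.

    With both rates zero the recording is returned unchanged (same sample
    values). Requires the ground truth from :func:`simulate_recording` when
    ``ectopic_rate > 0``.
    """
    if seed is None:
        seed = config.seed
    if truth is None:
        if config.ectopic_rate > 0:
            raise ValueError("ectopic injection needs the simulation ground truth")
        truth = GroundTruth(pd.DataFrame(), [], config)

    rate = recording.sampling_rate_hz
    samples = recording.samples.copy()
    beats = truth.beats.copy()
    artifacts = list(truth.artifacts)

    if config.ectopic_rate > 0 and len(beats) >= 3:
        rng_e = np.random.default_rng([seed, _RNG_ECTOPIC])
        flags = rng_e.random(len(beats)) < config.ectopic_rate
        rng_splice = np.random.default_rng([seed, _RNG_SPLICE])
        params = _params_from_config(config)
        params_e = _ectopic_params(params)
        cache = _GeometryCache()
        busy_until = -1
        vmax_e = None
        for k in np.flatnonzero(flags):
            if k < 1 or k >= len(beats) - 1 or k - 1 <= busy_until:
                continue
            prev = beats.iloc[k - 1]
            nxt = beats.iloc[k + 1]
            rr_prev_new = _ECTOPIC_EARLY * prev.rr_s
            onset_e = prev.onset_s + rr_prev_new
            rr_e = nxt.onset_s - onset_e
            try:
                geo_prev = cache.get(params, rr_prev_new)
                geo_e = cache.get(params_e, rr_e)
            except InfeasibleBeatError:
                continue
            _render_beat(samples, geo_prev, prev.onset_s, rr_prev_new, rate)
            _render_beat(samples, geo_e, onset_e, rr_e, rate)
            i0 = int(np.ceil(prev.onset_s * rate - 1e-9))
            i1 = min(int(np.ceil(nxt.onset_s * rate - 1e-9)), len(samples))
            tseg = np.arange(i0, i1) / rate
            samples[i0:i1] += _drift(config, tseg)
            if config.noise_sd_mmHg > 0:
                samples[i0:i1] += rng_splice.normal(
                    0.0, config.noise_sd_mmHg, size=i1 - i0)
            if vmax_e is None:
                vmax_e = geo_e.vmax(grid_hz=20_000.0)
            d_prev = float(_drift(config, prev.onset_s))
            d_e = float(_drift(config, onset_e))
            beats.iloc[k - 1] = _truth_row(
                geo_prev, prev.onset_s, rr_prev_new, d_prev,
                beats.iloc[k - 1].vmax_per_s, False)
            beats.iloc[k] = _truth_row(geo_e, onset_e, rr_e, d_e, vmax_e, True)
            artifacts.append((float(prev.onset_s), float(nxt.onset_s), "ectopic"))
            busy_until = k

    if config.wall_contact_rate > 0:
        rng_w = np.random.default_rng([seed, _RNG_WALL])
        duration = recording.duration_s
        n_events = rng_w.poisson(config.wall_contact_rate * duration / 3600.0)
        for _ in range(n_events):
            ev_dur = rng_w.uniform(0.2, 2.0)
            start = rng_w.uniform(0.0, max(duration - ev_dur, 0.0))
            phase = rng_w.uniform(0.0, 2 * np.pi)
            i0 = int(np.ceil(start * rate))
            i1 = min(int(np.ceil((start + ev_dur) * rate)), len(samples))
            tt = np.arange(i0, i1) / rate - start
            envelope = np.sin(np.pi * np.minimum(tt / ev_dur, 1.0)) ** 2
            samples[i0:i1] += _WALL_AMP_MMHG * envelope * np.sin(
                2 * np.pi * _WALL_FREQ_HZ * tt + phase)
            artifacts.append((float(start), float(start + ev_dur), "wall_contact"))

    out = PressureRecording(samples, rate, recording.start_time,
                            recording.units, recording.gap_mask.copy())
    return out, GroundTruth(beats, artifacts, config)


def simulate(config: SimConfig) -> tuple[PressureRecording, GroundTruth]:
    """Full simulation: clean recording plus any configured artifacts."""
    recording, truth = simulate_recording(config)
    if config.ectopic_rate > 0 or config.wall_contact_rate > 0:
        recording, truth = inject_artifacts(recording, config,
                                            seed=config.seed, truth=truth)
    return recording, truth
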