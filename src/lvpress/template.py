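"""Analytic single-beat pressure template.

One beat is a piecewise-smooth curve assembled so that every monitored index
has a closed-form value and location:

  diastolic hold (LVEDP)
  -> systolic upstroke: sin^2 slope ease-in, a short constant-slope span at
     exactly +dP/dt_max, symmetric ease-out into the peak at LVSP
  -> systolic hold at LVSP (gives the waveform its dome and a realistic
     mean pressure)
  -> fall: sin^2 slope ease-in, a short constant-slope span at exactly
     -dP/dt_max, slope ease-out to a fraction beta of -dP/dt_max
  -> monoexponential relaxation tail toward the diastolic floor, whose time
     constant is solved so that the pressure crosses the 66%-drop target
     (LVSP - 0.66*(LVSP - LVEDP)) exactly tau66 after the -dP/dt_max point
  -> raised-cosine refill back to LVEDP at the next onset.

The constant-slope spans make the derivative extrema flat over a few samples,
so a sampled finite-difference analyser can attain them exactly; the earliest
time each extremum is attained is the fiducial the ground truth reports.

The fall geometry has two free shape parameters (ease-in duration ``a_f`` and
tail slope fraction ``beta``); they are solved per parameter set so that the
66%-crossing time equals the configured tau66. Some index combinations are
geometrically impossible (the crossing cannot be made fast or slow enough, or
the segments do not fit in one RR interval); those raise
:class:`InfeasibleBeatError`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import exp, log, pi, sin

import numpy as np
from scipy.optimize import brentq

from .errors import InfeasibleBeatError, InvalidGeometryError

__all__ = ["BeatParams", "BeatGeometry", "solve_tau_exp", "geometry_for"]

# fixed shape constants (seconds)
HOLD_S = 0.012          # diastolic hold before the upstroke
SYST_HOLD_S = 0.040     # systolic hold at LVSP
RISE_PLATEAU_S = 0.006  # span at exactly +dP/dt_max
FALL_PLATEAU_S = 0.006  # span at exactly -dP/dt_max
EASE_OUT_S = 0.008      # fall slope ease-out duration (b)
REFILL_S = 0.030        # raised-cosine refill duration
A_FALL_MIN = 0.010      # smallest fall ease-in duration considered
_JOIN_MARGIN = 1.0      # mmHg clearance of the exp-tail start above the floor
_BETA_LO, _BETA_HI = 0.02, 0.98


def solve_tau_exp(tau66_ms: float, start_pressure_mmHg: float, lvsp_mmHg: float,
                  diastolic_mmHg: float, floor_mmHg: float) -> float:
    """Exponential time constant (ms) whose decay realises a given tau66.

    For a decay ``P(t) = floor + (start - floor) * exp(-t / tau_exp)`` the
    time to reach the 66%-drop target
    ``P_tgt = lvsp - 0.66 * (lvsp - diastolic)`` equals ``tau66`` when

        tau_exp = tau66 / ln((start - floor) / (P_tgt - floor))

    Raises :class:`InvalidGeometryError` unless floor < P_tgt < start.
    """
    if tau66_ms <= 0:
        raise InvalidGeometryError("tau66 must be positive")
    p_tgt = lvsp_mmHg - 0.66 * (lvsp_mmHg - diastolic_mmHg)
    if not (floor_mmHg < p_tgt < start_pressure_mmHg):
        raise InvalidGeometryError(
            f"need floor < target < start, got floor={floor_mmHg}, "
            f"target={p_tgt:.3f}, start={start_pressure_mmHg}")
    return tau66_ms / log((start_pressure_mmHg - floor_mmHg) / (p_tgt - floor_mmHg))


@dataclass(frozen=True)
class BeatParams:
    """Per-beat physiological parameters (pressures mmHg, slopes mmHg/s, tau s)."""

    lvsp: float
    lvedp: float
    floor: float
    dpdt_max: float
    neg_dpdt_max: float
    tau66_s: float

    def __post_init__(self):
        if not (self.floor <= self.lvedp < self.lvsp):
            raise InvalidGeometryError(
                "need floor <= lvedp < lvsp, got "
                f"{self.floor}, {self.lvedp}, {self.lvsp}")
        if min(self.dpdt_max, self.neg_dpdt_max, self.tau66_s) <= 0:
            raise InvalidGeometryError("slopes and tau66 must be positive")


def _sin2_rise_area(n: float, a: float) -> float:
    # integral over [0, a] of n * (u/2 - (a/2pi) sin(pi u / a)), relative to 0
    return n * a * a * (0.25 - 1.0 / (pi * pi))


class BeatGeometry:
    """Solved template geometry for one parameter set.

    Independent of the RR interval except for the exponential-tail duration
    and the refill, which are laid out per beat by :meth:`render`.
    """

    def __init__(self, params: BeatParams, hold_s: float = HOLD_S,
                 syst_s: float = SYST_HOLD_S):
        p = params
        self.params = p
        delta = p.lvsp - p.lvedp
        self.p_tgt = p.lvsp - 0.66 * delta

        # upstroke: ease(a_r) + plateau(l_r) + ease(a_r), total gain delta
        l_r = min(RISE_PLATEAU_S, delta / p.dpdt_max / 3.0)
        a_r = delta / p.dpdt_max - l_r
        if a_r < 0.002:
            raise InfeasibleBeatError("upstroke too steep for the template")
        self.a_r, self.l_r = a_r, l_r

        self.a_f, self.beta = self._solve_fall()
        n_f = p.neg_dpdt_max
        self.p_t0 = p.lvsp - 0.5 * n_f * self.a_f
        self.p1 = self.p_t0 - n_f * FALL_PLATEAU_S
        self.p_join = self.p1 - 0.5 * n_f * EASE_OUT_S * (1.0 + self.beta)
        self.tau_e = (self.p_join - p.floor) / (self.beta * n_f)

        # segment boundaries relative to beat onset
        self.hold_s = hold_s
        self.syst_s = syst_s
        self.t_rise1 = hold_s + a_r            # +dP/dt_max first attained
        self.t_rise2 = self.t_rise1 + l_r
        self.t_peak = self.t_rise2 + a_r       # systolic peak (P = LVSP)
        self.t_syst_end = self.t_peak + syst_s
        self.t_f1 = self.t_syst_end + self.a_f  # -dP/dt_max first attained
        self.t_f2 = self.t_f1 + FALL_PLATEAU_S
        self.t_f3 = self.t_f2 + EASE_OUT_S     # exponential tail start
        # the 66% crossing must complete before the refill starts
        self.t_cross = self.t_f1 + p.tau66_s
        self.min_rr = max(self.t_cross + 0.004, self.t_f3 + 0.002) + 0.008

    # -- fall-shape solver -------------------------------------------------

    def _fall_t66(self, a_f: float, beta: float) -> float:
        """Time from the -dP/dt_max point to the 66%-drop crossing."""
        p = self.params
        n_f = p.neg_dpdt_max
        b = EASE_OUT_S
        p_t0 = p.lvsp - 0.5 * n_f * a_f
        p1 = p_t0 - n_f * FALL_PLATEAU_S
        p_join = p1 - 0.5 * n_f * b * (1.0 + beta)
        if self.p_tgt >= p1:
            return (p_t0 - self.p_tgt) / n_f
        if self.p_tgt >= p_join:
            drop = p1 - self.p_tgt

            def ease_drop(u):
                return n_f * (u - (1.0 - beta)
                              * (0.5 * u - (b / (2 * pi)) * sin(pi * u / b))) - drop

            return FALL_PLATEAU_S + brentq(ease_drop, 0.0, b, xtol=1e-12)
        if p_join <= p.floor:
            return float("inf")  # tail never reaches the target
        tau_e = (p_join - p.floor) / (beta * n_f)
        return (FALL_PLATEAU_S + b
                + tau_e * log((p_join - p.floor) / (self.p_tgt - p.floor)))

    def _a_cap(self, beta: float) -> float:
        p = self.params
        n_f = p.neg_dpdt_max
        budget = p.lvsp - p.floor - _JOIN_MARGIN \
            - n_f * (FALL_PLATEAU_S + 0.5 * EASE_OUT_S * (1.0 + beta))
        return 2.0 * budget / n_f

    def _solve_fall(self) -> tuple[float, float]:
        """Smallest fall ease-in (and its tail fraction) realising tau66.

        Scanning ``a_f`` upward keeps the -dP/dt_max point high, which leaves
        most of the systolic-diastolic span to the exponential tail; the
        tail then crosses the 66% target at a healthy slope instead of
        grazing it, which is both more heart-like and far less sensitive to
        pressure readout error.
        """
        tau66 = self.params.tau66_s
        a_cap = self._a_cap(_BETA_HI)
        if a_cap < A_FALL_MIN:
            raise InfeasibleBeatError(
                "pressure span too small for the fall profile")
        grid = np.append(np.arange(A_FALL_MIN, a_cap, 0.001), a_cap)
        for a_f in grid:
            g_hi = self._fall_t66(a_f, _BETA_HI) - tau66
            if g_hi > 0.0:
                continue  # even the fastest tail is too slow; drop deeper
            g_lo = self._fall_t66(a_f, _BETA_LO) - tau66
            if g_lo < 0.0:
                raise InfeasibleBeatError(
                    f"tau66={tau66 * 1e3:.1f} ms unreachable (too long) for "
                    "this pressure/slope combination")
            beta = brentq(
                lambda b: self._fall_t66(a_f, b) - tau66,
                _BETA_LO, _BETA_HI, xtol=1e-10)
            return float(a_f), float(beta)
        raise InfeasibleBeatError(
            f"tau66={tau66 * 1e3:.1f} ms unreachable (too short) for "
            "this pressure/slope combination")

    # -- evaluation --------------------------------------------------------

    def _layout(self, rr_s: float) -> tuple[float, float]:
        """(tail end, refill duration) for a beat of length ``rr_s``."""
        if rr_s < self.min_rr:
            raise InfeasibleBeatError(
                f"RR={rr_s * 1e3:.0f} ms shorter than the template minimum "
                f"{self.min_rr * 1e3:.0f} ms")
        t_rf = max(rr_s - REFILL_S, self.min_rr - 0.008)
        return t_rf, rr_s - t_rf

    def pressure(self, u, rr_s: float):
        """Template pressure at times ``u`` (seconds since beat onset)."""
        p = self.params
        n_r, n_f = p.dpdt_max, p.neg_dpdt_max
        a_r, a_f, b = self.a_r, self.a_f, EASE_OUT_S
        t_rf, refill = self._layout(rr_s)
        p_re = p.floor + (self.p_join - p.floor) * exp(-(t_rf - self.t_f3) / self.tau_e)

        u = np.asarray(u, dtype=float)
        out = np.empty_like(u)
        bounds = [self.hold_s, self.t_rise1, self.t_rise2, self.t_peak,
                  self.t_syst_end, self.t_f1, self.t_f2, self.t_f3, t_rf]
        seg = np.searchsorted(bounds, u, side="right")

        m = seg == 0
        out[m] = p.lvedp
        m = seg == 1
        if m.any():
            v = u[m] - self.hold_s
            out[m] = p.lvedp + n_r * (0.5 * v - (a_r / (2 * pi)) * np.sin(pi * v / a_r))
        m = seg == 2
        if m.any():
            v = u[m] - self.t_rise1
            out[m] = p.lvedp + 0.5 * n_r * a_r + n_r * v
        m = seg == 3
        if m.any():
            v = u[m] - self.t_rise2
            out[m] = (p.lvsp - 0.5 * n_r * a_r
                      + n_r * (0.5 * v + (a_r / (2 * pi)) * np.sin(pi * v / a_r)))
        out[seg == 4] = p.lvsp
        m = seg == 5
        if m.any():
            v = u[m] - self.t_syst_end
            out[m] = p.lvsp - n_f * (0.5 * v - (a_f / (2 * pi)) * np.sin(pi * v / a_f))
        m = seg == 6
        if m.any():
            v = u[m] - self.t_f1
            out[m] = self.p_t0 - n_f * v
        m = seg == 7
        if m.any():
            v = u[m] - self.t_f2
            out[m] = self.p1 - n_f * (v - (1.0 - self.beta)
                                      * (0.5 * v - (b / (2 * pi)) * np.sin(pi * v / b)))
        m = seg == 8
        if m.any():
            v = u[m] - self.t_f3
            out[m] = p.floor + (self.p_join - p.floor) * np.exp(-v / self.tau_e)
        m = seg == 9
        if m.any():
            v = u[m] - t_rf
            out[m] = p.lvedp + (p_re - p.lvedp) * 0.5 * (1.0 + np.cos(pi * v / refill))
        return out

    def slope(self, u, rr_s: float):
        """Analytic dP/dt at times ``u`` (seconds since beat onset)."""
        p = self.params
        n_r, n_f = p.dpdt_max, p.neg_dpdt_max
        a_r, a_f, b = self.a_r, self.a_f, EASE_OUT_S
        t_rf, refill = self._layout(rr_s)
        p_re = p.floor + (self.p_join - p.floor) * exp(-(t_rf - self.t_f3) / self.tau_e)

        u = np.asarray(u, dtype=float)
        out = np.zeros_like(u)
        bounds = [self.hold_s, self.t_rise1, self.t_rise2, self.t_peak,
                  self.t_syst_end, self.t_f1, self.t_f2, self.t_f3, t_rf]
        seg = np.searchsorted(bounds, u, side="right")

        m = seg == 1
        out[m] = n_r * np.sin(pi * (u[m] - self.hold_s) / (2 * a_r)) ** 2
        m = seg == 2
        out[m] = n_r
        m = seg == 3
        out[m] = n_r * np.cos(pi * (u[m] - self.t_rise2) / (2 * a_r)) ** 2
        m = seg == 5
        out[m] = -n_f * np.sin(pi * (u[m] - self.t_syst_end) / (2 * a_f)) ** 2
        m = seg == 6
        out[m] = -n_f
        m = seg == 7
        out[m] = -n_f * (1.0 - (1.0 - self.beta)
                         * np.sin(pi * (u[m] - self.t_f2) / (2 * b)) ** 2)
        m = seg == 8
        out[m] = -(self.p_join - p.floor) / self.tau_e \
            * np.exp(-(u[m] - self.t_f3) / self.tau_e)
        m = seg == 9
        out[m] = -(p_re - p.lvedp) * (pi / (2 * refill)) \
            * np.sin(pi * (u[m] - t_rf) / refill)
        return out

    # -- analytic truths ---------------------------------------------------

    def mean_pressure(self, rr_s: float) -> float:
        """Closed-form time average of the template over one beat."""
        p = self.params
        n_r, n_f = p.dpdt_max, p.neg_dpdt_max
        a_r, a_f, b = self.a_r, self.a_f, EASE_OUT_S
        l_r, l_f = self.l_r, FALL_PLATEAU_S
        t_rf, refill = self._layout(rr_s)
        tail = t_rf - self.t_f3
        p_re = p.floor + (self.p_join - p.floor) * exp(-tail / self.tau_e)
        p_r1 = p.lvedp + 0.5 * n_r * a_r

        area = p.lvedp * self.hold_s
        area += p.lvedp * a_r + _sin2_rise_area(n_r, a_r)
        area += p_r1 * l_r + 0.5 * n_r * l_r * l_r
        area += (p.lvsp - 0.5 * n_r * a_r) * a_r \
            + n_r * a_r * a_r * (0.25 + 1.0 / (pi * pi))
        area += p.lvsp * self.syst_s
        area += p.lvsp * a_f - _sin2_rise_area(n_f, a_f)
        area += self.p_t0 * l_f - 0.5 * n_f * l_f * l_f
        area += self.p1 * b - n_f * (0.5 * b * b
                                     - (1.0 - self.beta) * b * b * (0.25 - 1.0 / (pi * pi)))
        area += p.floor * tail + (self.p_join - p.floor) * self.tau_e \
            * (1.0 - exp(-tail / self.tau_e))
        area += p.lvedp * refill + 0.5 * (p_re - p.lvedp) * refill
        return area / rr_s

    def vmax(self, grid_hz: float = 100_000.0) -> float:
        """Peak of (dP/dt)/P over the isovolumic upstroke, on a dense grid."""
        p = self.params
        u = np.arange(0.0, self.t_rise1 + 1.0 / grid_hz, 1.0 / grid_hz)
        # the windows below never reach the refill; any valid rr works
        rr = self.min_rr + 1.0
        d = self.slope(u, rr)
        pr = np.maximum(self.pressure(u, rr), 1.0)
        return float(np.max(d / pr))


def geometry_for(params: BeatParams, rr_s: float) -> BeatGeometry:
    """Geometry that fits in ``rr_s``, shrinking the holds if needed."""
    for hold_s, syst_s in ((HOLD_S, SYST_HOLD_S), (0.004, 0.020),
                           (0.004, 0.0)):
        geo = BeatGeometry(params, hold_s=hold_s, syst_s=syst_s)
        if rr_s >= geo.min_rr:
            return geo
    raise InfeasibleBeatError(
        f"beat morphology needs {geo.min_rr * 1e3:.0f} ms but RR is "
        f"{rr_s * 1e3:.0f} ms")
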