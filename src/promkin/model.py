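"""Two-compartment kinetic model of an inducible transcriptional system.

The model tracks the unfolded fluorescent reporter U and the mature
(fluorescent) reporter F in a single cell:

    dU/dt = b + i*S(t) - (f + d)*U
    dF/dt = f*U - d*F
    S(t)  = 1  if  t_start + t_on <= t < t_end + t_off,  else 0

where ``b`` is the basal (leaky) synthesis rate, ``i`` the induced
synthesis-rate increment, ``f`` the first-order fluorophore maturation
rate, ``d`` the combined degradation-and-dilution rate, and ``t_on`` /
``t_off`` the lags between the induction signal switching and the
promoter actually (de)activating.  Promoter activation is a step
function: fluorescence rises purely quadratically at onset (dF/dt = 0 at
t = t_on), which is what distinguishes this second-order model from a
first-order relaxation.

Units: time in minutes, rates in min^-1, amounts in maxGAL1 (1 maxGAL1 =
mean steady-state expression of a single-copy GAL1 promoter reporter).

The module provides the exact piecewise solutions, their second-order
Taylor approximations used for windowed fitting, and an independent
numerical-integration oracle (`integrate_model`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "DegenerateRateError",
    "KineticParams",
    "InductionProtocol",
    "ModelState",
    "model_rhs",
    "closed_form_on",
    "closed_form_off",
    "taylor_on",
    "taylor_off",
    "steady_state",
    "integrate_model",
    "loglog_rise_slope",
]

#: rates closer to zero than this make the closed forms singular
RATE_TOL = 1e-8


class DegenerateRateError(ValueError):
    """Raised when d or f+d is too close to 0 for the closed-form solution.

    Callers should fall back to `integrate_model`.
    """


@dataclass(frozen=True)
class KineticParams:
    """Parameter vector (b, i, f, d, t_on, t_off) of the kinetic model.

    b : basal synthesis rate, maxGAL1/min
    i : induced synthesis-rate increment, maxGAL1/min
    f : fluorophore maturation rate, 1/min (fixed during fitting)
    d : degradation-and-dilution rate, 1/min (may be fit as negative,
        which flags the cell for exclusion downstream)
    t_on, t_off : activation / deactivation lags, min
    """

    b: float
    i: float
    f: float
    d: float
    t_on: float = 0.0
    t_off: float = 0.0

    def __post_init__(self) -> None:
        if self.f <= 0:
            raise ValueError(f"maturation rate f must be > 0, got {self.f}")
        if self.i < 0:
            raise ValueError(f"induced rate i must be >= 0, got {self.i}")
        if self.t_on < 0 or self.t_off < 0:
            raise ValueError("lags t_on and t_off must be >= 0")

    def replace(self, **kw) -> "KineticParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class InductionProtocol:
    """Timing of an induction experiment (canonical design: >=1 h
    pre-induction, 3.5 h induction, 3 h post-induction, 10-min imaging).

    All times in minutes relative to induction onset (t = 0); media_delay_s
    is the transport lag of chemical inducers to the observation chamber,
    in seconds, subtracted from fitted lags downstream.
    """

    t_start: float = 0.0
    t_end: float = 210.0
    observe_from: float = -60.0
    observe_to: float = 390.0
    sampling_interval: float = 10.0
    media_delay_s: float = 170.0

    def __post_init__(self) -> None:
        if not (self.observe_from <= self.t_start < self.t_end <= self.observe_to):
            raise ValueError(
                "protocol must satisfy observe_from <= t_start < t_end <= observe_to"
            )
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be > 0")

    def times(self) -> np.ndarray:
        """The sampling grid observe_from..observe_to (inclusive)."""
        n = int(round((self.observe_to - self.observe_from) / self.sampling_interval))
        return self.observe_from + self.sampling_interval * np.arange(n + 1)

    def signal(self, t, params: KineticParams):
        """Promoter activity S(t): 1 inside [t_start+t_on, t_end+t_off)."""
        t = np.asarray(t, dtype=float)
        on = (t >= self.t_start + params.t_on) & (t < self.t_end + params.t_off)
        return on.astype(float)


@dataclass
class ModelState:
    """Instantaneous model state: unfolded (U) and mature (F) reporter."""

    U: float
    F: float

    def as_array(self) -> np.ndarray:
        return np.array([self.U, self.F], dtype=float)


def model_rhs(
    state: ModelState | np.ndarray,
    t: float,
    params: KineticParams,
    protocol: InductionProtocol,
) -> np.ndarray:
    """Right-hand side (dU/dt, dF/dt) of the model at time t."""
    u, fl = (state.U, state.F) if isinstance(state, ModelState) else state
    s = float(protocol.signal(t, params))
    du = params.b + params.i * s - (params.f + params.d) * u
    df = params.f * u - params.d * fl
    return np.array([du, df])


def _check_rates(params: KineticParams) -> None:
    if abs(params.d) < RATE_TOL or abs(params.f + params.d) < RATE_TOL:
        raise DegenerateRateError(
            "d or f+d within 1e-8 of zero: closed form singular, "
            "use integrate_model instead"
        )


def steady_state(params: KineticParams, induced: bool = False) -> float:
    """Steady-state mature fluorescence.

    basal:   f*b/(d*(f+d))          (promoter off)
    induced: f*(i+b)/(d*(f+d))      (promoter on)
    """
    if params.d <= 0:
        raise ValueError("no steady state for d <= 0")
    rate = params.b + (params.i if induced else 0.0)
    return params.f * rate / (params.d * (params.f + params.d))


def closed_form_on(params: KineticParams, t, t_start: float = 0.0):
    """Exact mature fluorescence during the ON phase (t >= t_start + t_on).

    F_ON(t) = (f/d)(i+b)/(f+d)
              - i/(d(d+f)) e^{-d tau} (f + d(1 - e^{-f tau})),  tau = t - t_start - t_on

    starting from the basal steady state at promoter activation.
    """
    _check_rates(params)
    b, i, f, d = params.b, params.i, params.f, params.d
    t = np.asarray(t, dtype=float)
    tau = t - t_start - params.t_on
    if np.any(tau < -1e-12):
        raise ValueError("closed_form_on requires t >= t_start + t_on")
    tau = np.maximum(tau, 0.0)
    out = f * (i + b) / (d * (f + d)) - i / (d * (d + f)) * np.exp(-d * tau) * (
        f + d * (1.0 - np.exp(-f * tau))
    )
    return out if out.ndim else float(out)


def _on_state_at(params: KineticParams, duration: float) -> tuple[float, float]:
    """(U, F) after `duration` minutes of promoter activity, from basal SS."""
    b, i, f, d = params.b, params.i, params.f, params.d
    u = (b + i) / (f + d) - i / (f + d) * np.exp(-(f + d) * duration)
    fl = closed_form_on(
        params, params.t_on + duration, t_start=0.0
    )
    return float(u), float(fl)


def closed_form_off(
    params: KineticParams, t, t_end: float = 210.0, t_start: float = 0.0
):
    """Exact mature fluorescence after promoter shutoff (t >= t_end + t_off).

    The relaxation toward the basal steady state f*b/(d(f+d)) from whatever
    state the ON dynamics reached at shutoff.  When induction has reached
    steady state this reduces to

        F_OFF(t) = (f/d) b/(f+d) + i/(d(d+f)) e^{-d tau} (f + d(1 - e^{-f tau}))

    with tau = t - t_end - t_off.  (The corresponding printed formula in the
    source model carries a stray factor inside the parenthesis that is
    dimensionally inconsistent; this is the exact re-derived solution,
    validated against `integrate_model`.)
    """
    _check_rates(params)
    b, i, f, d = params.b, params.i, params.f, params.d
    t = np.asarray(t, dtype=float)
    t_off_abs = t_end + params.t_off
    tau = t - t_off_abs
    if np.any(tau < -1e-12):
        raise ValueError("closed_form_off requires t >= t_end + t_off")
    tau = np.maximum(tau, 0.0)
    duration = t_off_abs - (t_start + params.t_on)
    if duration < 0:
        raise ValueError("promoter-on window is empty")
    u0, f0 = _on_state_at(params, duration)
    # relaxation with constant input b: F = A + B e^{-(f+d)tau} + C e^{-d tau}
    a_ss = f * b / (d * (f + d))
    bb = -(u0 - b / (f + d))
    cc = f0 - a_ss - bb
    out = a_ss + bb * np.exp(-(f + d) * tau) + cc * np.exp(-d * tau)
    return out if out.ndim else float(out)


def taylor_on(params: KineticParams, t, t_start: float = 0.0):
    """Second-order Taylor approximation of the ON solution:

    F~_ON(t) = (f/d) b/(d+f) + (i f / 2) (t - t_on)^2
    """
    _check_rates(params)
    b, i, f, d = params.b, params.i, params.f, params.d
    t = np.asarray(t, dtype=float)
    tau = t - t_start - params.t_on
    if np.any(tau < -1e-12):
        raise ValueError("taylor_on requires t >= t_start + t_on")
    out = (f / d) * b / (d + f) + 0.5 * i * f * np.maximum(tau, 0.0) ** 2
    return out if out.ndim else float(out)


def taylor_off(params: KineticParams, t, t_end: float = 210.0):
    """Second-order Taylor approximation of the OFF solution:

    F~_OFF(t) = (f/d)(b+i)/(d+f) - (i f / 2) (t - t_end - t_off)^2
    """
    _check_rates(params)
    b, i, f, d = params.b, params.i, params.f, params.d
    t = np.asarray(t, dtype=float)
    tau = t - t_end - params.t_off
    if np.any(tau < -1e-12):
        raise ValueError("taylor_off requires t >= t_end + t_off")
    out = (f / d) * (b + i) / (d + f) - 0.5 * i * f * np.maximum(tau, 0.0) ** 2
    return out if out.ndim else float(out)


def integrate_model(
    params: KineticParams,
    protocol: InductionProtocol,
    times: np.ndarray,
    rtol: float = 1e-10,
    atol: float = 1e-14,
    return_state: bool = False,
):
    """Numerically integrate the ODEs on an increasing time grid.

    Starts from the pre-induction steady state
    (U, F) = (b/(f+d), f b/(d (f+d))) and splits the integration at the
    promoter switching times t_start+t_on and t_end+t_off so the step
    discontinuity never crosses a solver step.  Serves as the independent
    oracle for the closed forms.

    Returns the mature-fluorescence trace F(times) (and U if
    ``return_state``).
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValueError("times must be a non-empty 1-D array")
    if np.any(np.diff(times) <= 0):
        raise ValueError("time grid must be strictly increasing")
    if params.d <= 0:
        raise ValueError("pre-induction steady state requires d > 0")

    b, i, f, d = params.b, params.i, params.f, params.d
    y = np.array([b / (f + d), f * b / (d * (f + d))])

    switch_on = protocol.t_start + params.t_on
    switch_off = protocol.t_end + params.t_off

    out = np.empty((times.size, 2))
    # basal steady state holds at every sample up to promoter activation
    pre = times <= switch_on + 1e-12
    out[pre] = y
    filled = int(np.count_nonzero(pre))
    if filled == times.size:
        return (out[:, 1], out[:, 0]) if return_state else out[:, 1]

    # integrate from the activation switch onward; only the samples past
    # activation still need filling
    post_times = times[~pre]
    t0 = min(switch_on, post_times[0])
    t1 = times[-1]
    breaks = [t0] + [s for s in sorted((switch_on, switch_off)) if t0 < s < t1] + [t1]
    for seg_a, seg_b in zip(breaks[:-1], breaks[1:]):
        # constant promoter activity inside the segment
        s = float(protocol.signal(0.5 * (seg_a + seg_b), params))
        rate_in = b + i * s

        def rhs(_t, y, rate_in=rate_in):
            return [rate_in - (f + d) * y[0], f * y[0] - d * y[1]]

        last = seg_b == breaks[-1]
        mask = (post_times >= seg_a - 1e-12) & (
            (post_times < seg_b - 1e-12) if not last else (post_times <= seg_b + 1e-12)
        )
        t_eval = post_times[mask]
        # always evaluate at seg_b so the carried state sits exactly on the
        # discontinuity, not on the last sample before it
        if t_eval.size and abs(t_eval[-1] - seg_b) < 1e-12:
            t_solve = t_eval
        else:
            t_solve = np.append(t_eval, seg_b)
        sol = solve_ivp(
            rhs,
            (seg_a, seg_b),
            y,
            method="DOP853",
            t_eval=t_solve,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:  # pragma: no cover - smooth linear system
            raise RuntimeError(f"integration failed: {sol.message}")
        if t_eval.size:
            n_keep = t_eval.size
            out[filled : filled + n_keep] = sol.y.T[:n_keep]
            filled += n_keep
        y = sol.y[:, -1]

    if filled != times.size:  # pragma: no cover
        raise RuntimeError("time grid not fully covered by segments")
    if return_state:
        return out[:, 1], out[:, 0]
    return out[:, 1]


def loglog_rise_slope(
    times: np.ndarray,
    fluorescence: np.ndarray,
    window: tuple[float, float],
    baseline: float,
) -> float:
    """Log-log slope of the initial fluorescence rise above baseline.

    Least-squares slope of log(F - baseline) versus log(t) over the window;
    a purely quadratic rise gives slope 2, a linear one slope 1.  The
    model's step activation predicts a slope near 2 at small times.
    """
    times = np.asarray(times, dtype=float)
    fl = np.asarray(fluorescence, dtype=float)
    sel = (times >= window[0]) & (times <= window[1])
    t_w, f_w = times[sel], fl[sel] - baseline
    if t_w.size < 2:
        raise ValueError("need at least 2 points inside the window")
    if np.any(t_w <= 0):
        raise ValueError("window times must be positive for a log-log fit")
    if np.any(f_w <= 0):
        raise ValueError("fluorescence must exceed baseline throughout the window")
    slope, _ = np.polyfit(np.log(t_w), np.log(f_w), 1)
    return float(slope)
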