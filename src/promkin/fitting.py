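"""Staged windowed estimation of the kinetic parameters per cell.

The full model is never fit in one shot.  Each parameter comes from the
data window where it dominates the signal, mirroring how the time
courses actually constrain the model:

1. basal plateau  — mean fluorescence before induction (the composite
   term (f/d)·b/(d+f));
2. decay          — exponential fit starting ~4 maturation half-times
   after shutoff (where the maturation term is negligible) gives d;
3. rise           — one-sided fit around induction onset gives i and
   t_on;
4. fall           — mirrored fit after inducer removal gives t_off;
5. b              — back-computed from the basal plateau and d.

The maturation rate f is fixed throughout (measured independently);
i, t_on and t_off are bound below by zero.  For chemically induced
systems the media transport delay (~170 s) is subtracted from both
fitted lags.

All rise/fall stages are linear in the amplitude i once the lag is
fixed, so they are solved by variable projection: a closed-form
nonnegative amplitude inside a bounded one-dimensional search over the
lag (coarse grid then Brent refinement).  This minimizes the identical
least-squares objective a simplex search would, but deterministically
and fast enough for bootstrap resampling at scale.

Two rise/fall bases are available.  ``basis="taylor"`` fits the
second-order Taylor forms, the classic simplification; its truncation
bias grows like (2d+f)*tau/3 and is substantial by 30-40 min after
onset, so the fitted i underestimates the true initial slope whenever
the window extends well past the lag.  ``basis="exact"`` (the
`fit_cell` default) fits the exact piecewise solution instead, using
the degradation-and-dilution rate from the decay stage (fitted first);
it is unbiased on model-generated data and equally cheap because the
exact solution is also linear in i.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

from .model import KineticParams

__all__ = [
    "CellTrace",
    "FitWindows",
    "FitConfig",
    "StageFit",
    "FitResult",
    "estimate_basal",
    "fit_rise",
    "fit_fall",
    "fit_decay",
    "recover_b",
    "fit_cell",
    "exclude_cells",
    "average_trace",
    "fit_population_average",
]


@dataclass
class CellTrace:
    """One cell's sampled fluorescence time course."""

    cell_id: str
    times: np.ndarray
    fluorescence: np.ndarray
    system: str = ""
    background_subtracted: bool = True

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.times.shape != self.fluorescence.shape:
            raise ValueError("times and fluorescence must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def value_at(self, t: float) -> float:
        """Fluorescence at the sampled timepoint nearest to t."""
        return float(self.fluorescence[np.argmin(np.abs(self.times - t))])


@dataclass(frozen=True)
class FitWindows:
    """Fit windows in minutes.  Defaults: the canonical chemical-induction
    design (basal −60..0, rise −50..50, fall 210..270, decay 270..390);
    optogenetic systems take basal at the single t=0 point and shift the
    rise window to 0..50 or 0..60."""

    basal: tuple[float, float] = (-60.0, 0.0)
    rise: tuple[float, float] = (-50.0, 50.0)
    fall: tuple[float, float] = (210.0, 270.0)
    decay: tuple[float, float] = (270.0, 390.0)


@dataclass
class FitConfig:
    """Settings of the staged fit."""

    f_fixed: float = 0.035  # min^-1, independently measured maturation rate
    t_end: float = 210.0  # min, end of the induction signal
    windows: FitWindows = field(default_factory=FitWindows)
    chemically_induced: bool = True
    media_delay_s: float = 170.0
    basal_at_t0_only: bool = False  # optogenetic systems: no pre-induction data
    basis: str = "exact"  # "exact" or "taylor" rise/fall model
    lag_grid_step: float = 1.0  # min, coarse grid for the lag search
    flat_rise_tol: float = 1e-12  # amplitude below this => no detectable rise


@dataclass
class StageFit:
    """Outcome of one fitting stage."""

    value: float
    rss: float = 0.0
    converged: bool = True
    flag: str = ""


@dataclass
class FitResult:
    """Full staged-fit output for one trace."""

    cell_id: str
    params: KineticParams | None
    basal_plateau: float
    induced_plateau: float
    residuals: dict = field(default_factory=dict)
    converged: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)
    excluded: bool = False
    exclusion_reason: str = ""

    @property
    def d(self) -> float:
        return self.params.d if self.params is not None else np.nan


def _window_mask(times: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    return (times >= window[0] - 1e-9) & (times <= window[1] + 1e-9)


def estimate_basal(trace: CellTrace, window: tuple[float, float]) -> float:
    """Mean fluorescence over the pre-induction window (the composite
    basal-plateau term (f/d)·b/(d+f)).  A single-timepoint window is
    allowed (optogenetic systems)."""
    sel = _window_mask(trace.times, window)
    if not np.any(sel):
        raise ValueError(f"no timepoints inside basal window {window}")
    return float(trace.fluorescence[sel].mean())


# ---------------------------------------------------------------------------
# basis functions: fluorescence above the basal plateau per unit of i

def _rise_shape_taylor(tau: np.ndarray, f: float, d: float | None) -> np.ndarray:
    return 0.5 * f * tau**2


def _rise_shape_exact(tau: np.ndarray, f: float, d: float) -> np.ndarray:
    """Exact (F(t) - basal)/i for tau = time since promoter activation."""
    return (f - np.exp(-d * tau) * (f + d * (1.0 - np.exp(-f * tau)))) / (d * (d + f))


def _projected_amp_fit(
    y: np.ndarray,
    make_basis: Callable[[float], np.ndarray],
    lag_lo: float,
    lag_hi: float,
    grid_step: float,
):
    """Least squares of y ~ amp * x(lag) with amp >= 0, lag in
    [lag_lo, lag_hi].  For fixed lag the optimal amp is the clamped
    normal-equation solution, so only the lag needs a numerical search
    (vectorized coarse grid, then Brent refinement around the grid
    optimum).  ``make_basis`` maps an array of m lags to an (m, n)
    basis matrix.  Returns (amp, lag, rss)."""

    def sse_for(lag: float) -> tuple[float, float]:
        x = make_basis(np.array([lag]))[0]
        xx = float(x @ x)
        amp = max(0.0, float(x @ y) / xx) if xx > 0 else 0.0
        r = y - amp * x
        return float(r @ r), amp

    if lag_hi <= lag_lo:
        rss, amp = sse_for(lag_lo)
        return amp, lag_lo, rss

    grid = np.arange(lag_lo, lag_hi + grid_step / 2, grid_step)
    xs = make_basis(grid)  # (m, n)
    xx = np.einsum("ij,ij->i", xs, xs)
    with np.errstate(divide="ignore", invalid="ignore"):
        amps = np.where(xx > 0, np.maximum(0.0, (xs @ y) / np.where(xx > 0, xx, 1.0)), 0.0)
    resid = y[None, :] - amps[:, None] * xs
    sse_grid = np.einsum("ij,ij->i", resid, resid)
    k = int(np.argmin(sse_grid))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, grid.size - 1)]
    lag = float(grid[k])
    if hi > lo:
        res = minimize_scalar(
            lambda g: sse_for(g)[0], bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-8},
        )
        if res.fun <= sse_grid[k]:
            lag = float(res.x)
    rss, amp = sse_for(lag)
    return amp, lag, rss


def fit_rise(
    trace: CellTrace,
    f_fixed: float,
    window: tuple[float, float],
    basal_plateau: float,
    t_start: float = 0.0,
    grid_step: float = 1.0,
    flat_tol: float = 1e-12,
    basis: str = "taylor",
    d: float | None = None,
) -> tuple[StageFit, StageFit]:
    """Fit the one-sided rise around induction onset; returns (i, t_on).

    Taylor basis: basal + (i f / 2)(t - t_start - t_on)^2 for
    t > t_start + t_on, constant basal before (the classic windowed
    quadratic).  Exact basis (requires d > 0 from the decay stage): the
    exact ON solution, still linear in i.  Both i and t_on are bound
    below by zero.
    """
    if f_fixed <= 0:
        raise ValueError("f_fixed must be > 0")
    if basis == "exact":
        if d is None or d <= 0:
            raise ValueError("exact basis requires a positive fitted d")
        shape = _rise_shape_exact
    elif basis == "taylor":
        shape = _rise_shape_taylor
    else:
        raise ValueError(f"unknown basis {basis!r}")
    sel = _window_mask(trace.times, window)
    t = trace.times[sel]
    y = trace.fluorescence[sel] - basal_plateau
    if t.size < 3:
        raise ValueError("rise window must contain at least 3 timepoints")
    lag_hi = float(t[-1] - t_start)

    def make_basis(lags: np.ndarray) -> np.ndarray:
        tau = np.maximum(t[None, :] - t_start - np.asarray(lags)[:, None], 0.0)
        return shape(tau, f_fixed, d)

    amp, lag, rss = _projected_amp_fit(y, make_basis, 0.0, lag_hi, grid_step)
    if amp <= flat_tol:
        return (
            StageFit(0.0, rss, True, "flat"),
            StageFit(np.nan, rss, True, "undefined"),
        )
    flag = "at_bound" if lag >= lag_hi - 1e-6 else ""
    return StageFit(amp, rss, True), StageFit(lag, rss, True, flag)


def fit_fall(
    trace: CellTrace,
    f_fixed: float,
    window: tuple[float, float],
    induced_plateau: float,
    t_end: float = 210.0,
    grid_step: float = 1.0,
    flat_tol: float = 1e-12,
    basis: str = "taylor",
    d: float | None = None,
    t_on: float | None = None,
    basal_plateau: float | None = None,
    t_start: float = 0.0,
) -> StageFit:
    """Fit the post-removal fall; returns t_off (amplitude is a nuisance).

    Taylor basis: induced_plateau - (i f / 2)(t - t_end - t_off)^2 for
    t > t_end + t_off.  Exact basis (requires d and the fitted t_on):
    the exact solution through the shutoff — still on the ON branch
    before t_end + t_off, relaxing toward basal after.

    A trace still flat through the window pins t_off at the window edge
    and is flagged ``at_bound``.
    """
    if f_fixed <= 0:
        raise ValueError("f_fixed must be > 0")
    sel = _window_mask(trace.times, window)
    t = trace.times[sel]
    if t.size < 3:
        raise ValueError("fall window must contain at least 3 timepoints")
    lag_hi = float(t[-1] - t_end)
    f, dd = f_fixed, d

    if basis == "taylor":
        y = induced_plateau - trace.fluorescence[sel]  # drop below plateau

        def make_basis(lags: np.ndarray) -> np.ndarray:
            tau = np.maximum(t[None, :] - t_end - np.asarray(lags)[:, None], 0.0)
            return 0.5 * f * tau**2

    elif basis == "exact":
        if dd is None or dd <= 0:
            raise ValueError("exact basis requires a positive fitted d")
        if t_on is None or basal_plateau is None:
            raise ValueError("exact basis requires fitted t_on and basal_plateau")
        y = trace.fluorescence[sel] - basal_plateau

        def make_basis(lags: np.ndarray) -> np.ndarray:
            lag_col = np.asarray(lags)[:, None]
            t_shut = t_end + lag_col
            dur = t_shut - (t_start + t_on)
            safe_dur = np.maximum(dur, 0.0)
            on_part = _rise_shape_exact(
                np.maximum(t[None, :] - t_start - t_on, 0.0), f, dd
            )
            bcoef = (1.0 - np.exp(-(f + dd) * safe_dur)) / (f + dd)
            ccoef = _rise_shape_exact(safe_dur, f, dd) + bcoef
            tau = np.maximum(t[None, :] - t_shut, 0.0)
            off_part = -bcoef * np.exp(-(f + dd) * tau) + ccoef * np.exp(-dd * tau)
            out = np.where(t[None, :] <= t_shut, on_part, off_part)
            return np.where(dur > 0, out, 0.0)

    else:
        raise ValueError(f"unknown basis {basis!r}")

    amp, lag, rss = _projected_amp_fit(y, make_basis, 0.0, lag_hi, grid_step)
    if amp <= flat_tol:
        return StageFit(lag_hi, rss, True, "at_bound")
    flag = "at_bound" if lag >= lag_hi - 1e-6 else ""
    return StageFit(lag, rss, True, flag)


def fit_decay(
    trace: CellTrace,
    window: tuple[float, float],
    floor: float = 0.0,
) -> StageFit:
    """Exponential-decay fit F(t) = F0 e^{-d (t - t0)} + floor over the
    post-shutoff window (>= 4 maturation half-times after turn-off,
    where the maturation transient is negligible).

    d is deliberately unconstrained: a rising trace yields d < 0, which
    is the downstream exclusion signal.
    """
    sel = _window_mask(trace.times, window)
    t = trace.times[sel]
    y = trace.fluorescence[sel]
    if t.size < 3:
        raise ValueError("decay window must contain at least 3 timepoints")
    t0 = t[0]
    a0 = y[0] - floor
    span = t[-1] - t0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (y[-1] - floor) / a0 if a0 != 0 else np.nan
    d0 = -np.log(ratio) / span if np.isfinite(ratio) and ratio > 0 else 0.01
    if a0 == 0:
        a0 = max(float(np.max(np.abs(y - floor))), 1e-12)

    def resid(theta):
        amp, d = theta
        return amp * np.exp(-d * (t - t0)) + floor - y

    sol = least_squares(resid, x0=[a0, d0], method="lm", xtol=1e-12, ftol=1e-12)
    rss = float(sol.fun @ sol.fun)
    return StageFit(float(sol.x[1]), rss, bool(sol.success))


def recover_b(basal_plateau: float, d: float, f: float) -> float:
    """Invert the basal plateau (f/d)·b/(d+f) for b given fitted d.

    Only meaningful for d > 0; for d near or below zero (systems that do
    not turn off) the plateau no longer determines b.
    """
    if f <= 0:
        raise ValueError("f must be > 0")
    if d <= 0:
        raise ValueError("cannot recover b for d <= 0 (no basal steady state)")
    return basal_plateau * d * (d + f) / f


def fit_cell(trace: CellTrace, config: FitConfig) -> FitResult:
    """Run the full staged fit (basal -> decay -> rise -> fall -> b) on
    one trace.  Stage failures become flags, never exceptions, so
    batches always complete.

    With ``config.basis == "exact"`` and a non-positive fitted d (a
    pathological cell that will be excluded anyway) the rise/fall stages
    fall back to the Taylor basis, flagged."""
    flags: list[str] = []
    residuals: dict = {}
    converged: dict = {}
    w = config.windows

    if config.basal_at_t0_only:
        basal = trace.value_at(0.0)
    else:
        basal = estimate_basal(trace, w.basal)

    d_fit = fit_decay(trace, w.decay, floor=basal)
    residuals["decay"] = d_fit.rss
    converged["decay"] = d_fit.converged
    if not d_fit.converged:
        flags.append("decay:nonconverged")

    basis = config.basis
    if basis == "exact" and d_fit.value <= 0:
        basis = "taylor"
        flags.append("rise:taylor_fallback_d_nonpositive")

    i_fit, t_on_fit = fit_rise(
        trace, config.f_fixed, w.rise, basal,
        grid_step=config.lag_grid_step, flat_tol=config.flat_rise_tol,
        basis=basis, d=d_fit.value if basis == "exact" else None,
    )
    residuals["rise"] = i_fit.rss
    converged["rise"] = i_fit.converged
    for sf, name in ((i_fit, "rise"), (t_on_fit, "t_on")):
        if sf.flag:
            flags.append(f"{name}:{sf.flag}")

    induced_plateau = trace.value_at(config.t_end)
    if i_fit.value <= config.flat_rise_tol or not np.isfinite(t_on_fit.value):
        t_off_fit = StageFit(np.nan, 0.0, True, "undefined")
        flags.append("t_off:undefined")
    else:
        t_off_fit = fit_fall(
            trace, config.f_fixed, w.fall, induced_plateau, t_end=config.t_end,
            grid_step=config.lag_grid_step, flat_tol=config.flat_rise_tol,
            basis=basis, d=d_fit.value if basis == "exact" else None,
            t_on=t_on_fit.value, basal_plateau=basal,
        )
        if t_off_fit.flag:
            flags.append(f"t_off:{t_off_fit.flag}")
    residuals["fall"] = t_off_fit.rss
    converged["fall"] = t_off_fit.converged

    if d_fit.value > 0:
        b = recover_b(basal, d_fit.value, config.f_fixed)
    else:
        b = np.nan
        flags.append("b:undefined_d_nonpositive")

    t_on = t_on_fit.value
    t_off = t_off_fit.value
    if config.chemically_induced:
        delay = config.media_delay_s / 60.0
        if np.isfinite(t_on):
            t_on = max(0.0, t_on - delay)
        if np.isfinite(t_off):
            t_off = max(0.0, t_off - delay)

    params = KineticParams(
        b=b if np.isfinite(b) else 0.0,
        i=i_fit.value,
        f=config.f_fixed,
        d=d_fit.value,
        t_on=t_on if np.isfinite(t_on) else 0.0,
        t_off=t_off if np.isfinite(t_off) else 0.0,
    )
    return FitResult(
        cell_id=trace.cell_id,
        params=params,
        basal_plateau=basal,
        induced_plateau=induced_plateau,
        residuals=residuals,
        converged=converged,
        flags=flags,
    )


def exclude_cells(
    results: Sequence[FitResult],
    traces: Sequence[CellTrace],
    t_zero: float = 0.0,
    t_check: float = 270.0,
):
    """Apply the pathological-cell exclusion rules.

    A cell is excluded when its fitted d is negative (fluorescence
    rising after promoter shutoff) or when its fluorescence at induction
    onset strictly exceeds the level one hour after shutoff
    (F(0 h) > F(4.5 h), read at the nearest sampled timepoints).
    Equality keeps the cell.
    """
    if len(results) != len(traces):
        raise ValueError("results and traces must be aligned")
    kept: list[FitResult] = []
    excluded: list[FitResult] = []
    for res, trace in zip(results, traces):
        reasons = []
        if res.params is not None and res.params.d < 0:
            reasons.append("negative_d")
        if trace.value_at(t_zero) > trace.value_at(t_check):
            reasons.append("high_at_start")
        if reasons:
            res.excluded = True
            res.exclusion_reason = "+".join(reasons)
            excluded.append(res)
        else:
            kept.append(res)
    return kept, excluded


def average_trace(
    traces: Sequence[CellTrace], cell_id: str = "population_mean"
) -> CellTrace:
    """Pointwise mean trace over the cells present at each timepoint."""
    if len(traces) < 1:
        raise ValueError("need at least 1 trace")
    import pandas as pd

    frames = {tr.cell_id: pd.Series(tr.fluorescence, index=np.round(tr.times, 9))
              for tr in traces}
    wide = pd.DataFrame(frames)
    mean = wide.mean(axis=1, skipna=True)
    return CellTrace(
        cell_id=cell_id,
        times=mean.index.to_numpy(dtype=float),
        fluorescence=mean.to_numpy(dtype=float),
        system=traces[0].system,
    )


def fit_population_average(traces: Sequence[CellTrace], config: FitConfig) -> FitResult:
    """Fit the staged model to the population-averaged time course.

    Averaging first suppresses single-cell fluctuations that the lag
    estimates are particularly sensitive to.
    """
    if len(traces) < 2:
        raise ValueError("need at least 2 traces for a population average")
    return fit_cell(average_trace(traces), config)
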