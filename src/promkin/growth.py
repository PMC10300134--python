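"""Colony-area growth rates and reporter-turnover decomposition.

Colony areas grow exponentially during balanced growth, so the area
doubling time comes from a log-linear fit over a stated window
(canonically the last hour of induction, 2.5-3.5 h).  Because growth
dilutes cellular contents, the fitted degradation-and-dilution rate d
decomposes as d = growth rate + active degradation; regressing d on
growth rate with the slope fixed at 1 isolates the active-degradation
intercept, whose inverse ln(2)/intercept is the reporter's degradation
half-life.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .simulate import GrowthRecord

__all__ = [
    "GrowthRecord",
    "area_doubling_time",
    "degradation_growth_decomposition",
    "half_life_from_rate",
]


def area_doubling_time(
    record: GrowthRecord,
    window: tuple[float, float] = (150.0, 210.0),
    ci: float = 90.0,
) -> GrowthRecord:
    """Area doubling time ln(2)/r from a log-linear fit over the window.

    r is the least-squares slope of ln(area) versus time; the CI is
    propagated from the slope's standard error (Student t).  A
    non-positive slope flags the colony as non-growing (infinite
    doubling time).  Returns the record with growth_rate, doubling_time
    and ci90 filled in.
    """
    sel = (record.times >= window[0] - 1e-9) & (record.times <= window[1] + 1e-9)
    t = record.times[sel]
    a = record.areas[sel]
    if t.size < 3:
        raise ValueError("need at least 3 timepoints inside the window")
    if np.any(a <= 0):
        raise ValueError("areas must be positive")
    fit = sps.linregress(t, np.log(a))
    r = float(fit.slope)
    record.growth_rate = r
    if r <= 0:
        record.doubling_time = np.inf
        record.ci90 = (np.nan, np.nan)
        return record
    record.doubling_time = float(np.log(2) / r)
    alpha = 1 - ci / 100
    tcrit = sps.t.ppf(1 - alpha / 2, t.size - 2)
    stderr = float(fit.stderr) if np.isfinite(fit.stderr) else 0.0
    r_lo, r_hi = r - tcrit * stderr, r + tcrit * stderr
    # doubling time is decreasing in r: upper rate -> lower doubling time
    dt_lo = np.log(2) / r_hi if r_hi > 0 else np.inf
    dt_hi = np.log(2) / r_lo if r_lo > 0 else np.inf
    record.ci90 = (float(dt_lo), float(dt_hi))
    return record


def degradation_growth_decomposition(
    d_values: Mapping[str, float],
    growth_rates: Mapping[str, float],
    excluded: Sequence[str] = (),
):
    """Slope-1 decomposition d = growth rate + intercept across systems.

    With the slope fixed at one, the least-squares intercept is simply
    the mean of (d - growth rate) over the included systems; it
    estimates the active-degradation rate of the reporter (degron
    turnover).  Residuals are returned for every system, including the
    excluded ones — systems far below the line turn off more slowly
    than their growth explains.

    Returns ``(intercept, residuals)`` with residuals a dict
    system -> d - growth - intercept.
    """
    systems = [s for s in d_values if s in growth_rates]
    included = [s for s in systems if s not in excluded]
    if len(included) < 2:
        raise ValueError("need at least 2 included systems")
    diffs = {s: d_values[s] - growth_rates[s] for s in systems}
    intercept = float(np.mean([diffs[s] for s in included]))
    residuals = {s: diffs[s] - intercept for s in systems}
    return intercept, residuals


def half_life_from_rate(rate: float) -> float:
    """Half-life ln(2)/rate in minutes for a first-order rate in min^-1."""
    if rate <= 0:
        raise ValueError("rate must be > 0")
    return float(np.log(2) / rate)
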