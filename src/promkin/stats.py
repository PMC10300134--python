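"""Population-level statistics over single-cell traces and fitted parameters.

Covers: normalization of fluorescence to the maxGAL1 unit, cross-batch
calibration through a shared reference construct, bootstrap confidence
intervals for the activation/deactivation lags, expression-noise
scaling (CV versus mean on log-log axes), bimodality-aware violin
summaries with an adaptive kernel bandwidth, event-triggered trace
alignment, and a one-tailed z test.

Conventions: the sample standard deviation (n-1 denominator) is used
everywhere a std enters; the bimodality coefficient uses plain (biased)
sample moments and non-excess kurtosis, which is what makes the
reference values 5/9 (uniform, exponential) and 1/3 (normal) hold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .fitting import CellTrace, FitConfig, average_trace, fit_cell

__all__ = [
    "ViolinSummary",
    "NoisePoint",
    "normalize_to_maxgal1",
    "cross_calibrate",
    "bootstrap_lag_ci",
    "compute_cv",
    "noise_scaling_regression",
    "bimodality_coefficient",
    "violin_summary",
    "otsu_threshold",
    "align_by_event",
    "one_tailed_z_test",
]

#: bimodality threshold: the coefficient of the uniform and exponential
#: distributions; strictly above it a sample is treated as bimodal
BIMODALITY_THRESHOLD = 5.0 / 9.0


@dataclass
class ViolinSummary:
    """Outlier-trimmed distribution summary for one violin."""

    kept: np.ndarray
    outliers: np.ndarray
    bandwidth: float
    bimodality_coefficient: float
    is_bimodal: bool
    split_threshold: float | None = None
    subpop_bandwidths: tuple[float, float] | None = None
    notes: list = field(default_factory=list)


@dataclass
class NoisePoint:
    """One system's expression noise at the last induction timepoint."""

    system: str
    mean_expression: float  # maxGAL1
    cv: float
    mean_ci90: tuple[float, float] | None = None
    cv_ci90: tuple[float, float] | None = None


def normalize_to_maxgal1(
    traces: Sequence[CellTrace], gal1_steady_state: float
) -> list[CellTrace]:
    """Express background-subtracted fluorescence in maxGAL1 units.

    The reference is the mean of the GAL1 promoter reporter's
    stationary-state distribution *including* outliers (that is how the
    unit is defined).
    """
    if gal1_steady_state <= 0:
        raise ValueError("reference steady state must be > 0")
    return [
        CellTrace(
            cell_id=tr.cell_id,
            times=tr.times.copy(),
            fluorescence=tr.fluorescence / gal1_steady_state,
            system=tr.system,
            background_subtracted=tr.background_subtracted,
        )
        for tr in traces
    ]


def cross_calibrate(batch_a_ref: float, batch_b_ref: float) -> float:
    """Multiplicative factor mapping batch-B units onto batch A's scale.

    Both arguments are the two batches' measured levels of the same
    shared reference construct (e.g. the leaky basal expression of a
    common reporter); values from batch B multiplied by the returned
    factor are directly comparable to batch A.
    """
    if batch_a_ref <= 0 or batch_b_ref <= 0:
        raise ValueError("reference levels must be > 0")
    return batch_a_ref / batch_b_ref


def bootstrap_lag_ci(
    traces: Sequence[CellTrace],
    config: FitConfig,
    n_resamples: int = 1000,
    sample_size: int = 100,
    seed: int = 0,
    ci: float = 95.0,
):
    """Percentile bootstrap CIs for the population-average lags.

    Each resample draws ``sample_size`` single-cell timecourses with
    replacement, averages them, runs the staged fit on the average, and
    records t_on and t_off; the CI spans the 2.5th to 97.5th percentile
    (for ci=95).  Resamples whose fit flags the lag as undefined are
    dropped and counted.  Deterministic given ``seed``.

    Returns ``(t_on_ci, t_off_ci, info)`` with info holding the resample
    draws and the number dropped.
    """
    if len(traces) < sample_size:
        raise ValueError("need at least sample_size cells to resample")
    base = traces[0].times
    mat = np.empty((len(traces), base.size))
    for row, tr in enumerate(traces):
        if tr.times.shape != base.shape or np.any(tr.times != base):
            raise ValueError("bootstrap requires traces on a common time grid")
        mat[row] = tr.fluorescence

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(traces), size=(n_resamples, sample_size))
    t_on_draws, t_off_draws = [], []
    dropped = 0
    for r in range(n_resamples):
        mean_tr = CellTrace("resample", base, mat[idx[r]].mean(axis=0))
        res = fit_cell(mean_tr, config)
        ok_on = not any(fl.startswith("t_on:") for fl in res.flags)
        ok_off = not any(fl.startswith("t_off:") for fl in res.flags)
        if not (ok_on and ok_off):
            dropped += 1
        if ok_on:
            t_on_draws.append(res.params.t_on)
        if ok_off:
            t_off_draws.append(res.params.t_off)
    lo, hi = (100 - ci) / 2, 100 - (100 - ci) / 2

    def pct_ci(draws):
        if not draws:
            return (np.nan, np.nan)
        return tuple(np.percentile(draws, [lo, hi]))

    info = {"t_on_draws": np.asarray(t_on_draws),
            "t_off_draws": np.asarray(t_off_draws), "dropped": dropped}
    return pct_ci(t_on_draws), pct_ci(t_off_draws), info


def compute_cv(values: Sequence[float]) -> float:
    """Coefficient of variation: sample SD divided by the mean."""
    values = np.asarray(values, dtype=float)
    mean = values.mean()
    if mean <= 0:
        raise ValueError("CV requires a positive mean")
    if values.size < 2:
        return 0.0
    return float(values.std(ddof=1) / mean)


def noise_scaling_regression(
    points: Sequence[NoisePoint], exclusions: Sequence[str] = ()
):
    """OLS of log10(CV) on log10(mean expression) across systems.

    Returns ``(slope, intercept, r_squared, slope_ci95)``.  Systems in
    ``exclusions`` are dropped before fitting (outliers such as very
    noisy or weakly induced systems).
    """
    used = [p for p in points if p.system not in exclusions]
    if len(used) < 3:
        raise ValueError("need at least 3 points after exclusions")
    x = np.log10([p.mean_expression for p in used])
    y = np.log10([p.cv for p in used])
    fit = sps.linregress(x, y)
    dof = len(used) - 2
    tcrit = sps.t.ppf(0.975, dof)
    ci = (fit.slope - tcrit * fit.stderr, fit.slope + tcrit * fit.stderr)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2), ci


def bimodality_coefficient(values: np.ndarray) -> float:
    """b = (skewness^2 + 1) / kurtosis, with plain sample moments and
    non-excess kurtosis.  5/9 for uniform and exponential distributions,
    1/3 for a normal; strictly above 5/9 reads as bimodal."""
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("need at least 3 values")
    c = values - values.mean()
    m2 = np.mean(c**2)
    if m2 == 0:
        raise ValueError("degenerate (constant) sample")
    s = np.mean(c**3) / m2**1.5
    k = np.mean(c**4) / m2**2
    return float((s**2 + 1.0) / k)


def _eq8_bandwidth(values: np.ndarray) -> float:
    """Kernel bandwidth 0.8 * std / n^(1/5) (sample std)."""
    return float(0.8 * values.std(ddof=1) / values.size ** 0.2)


def violin_summary(values: Sequence[float], n_bins: int = 256) -> ViolinSummary:
    """Outlier-trimmed, bimodality-aware summary of a 1-D sample.

    1. values further than 2 SD from the mean are set aside as outlier
       dots;
    2. the bimodality coefficient of the kept values decides unimodal
       vs bimodal (strictly above 5/9 = bimodal);
    3. unimodal: bandwidth 0.8*std/n^(1/5); bimodal: split at the Otsu
       threshold and use the smaller of the two subpopulations'
       bandwidths (falling back to the unimodal bandwidth, with a note,
       if a side has fewer than 2 points).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 5:
        raise ValueError("need at least 5 values")
    mean, sd = values.mean(), values.std(ddof=1)
    out_mask = np.abs(values - mean) > 2 * sd
    kept, outliers = values[~out_mask], values[out_mask]
    notes: list[str] = []

    bc = bimodality_coefficient(kept)
    unimodal_bw = _eq8_bandwidth(kept)
    is_bimodal = bc > BIMODALITY_THRESHOLD
    split = None
    sub_bws = None
    bw = unimodal_bw
    if is_bimodal:
        split = otsu_threshold(kept, n_bins)
        low, high = kept[kept <= split], kept[kept > split]
        if low.size < 2 or high.size < 2:
            notes.append("split produced a side with <2 points; "
                         "fell back to unimodal bandwidth")
        else:
            sub_bws = (_eq8_bandwidth(low), _eq8_bandwidth(high))
            bw = min(sub_bws)
    return ViolinSummary(
        kept=kept, outliers=outliers, bandwidth=bw,
        bimodality_coefficient=bc, is_bimodal=is_bimodal,
        split_threshold=split, subpop_bandwidths=sub_bws, notes=notes,
    )


def otsu_threshold(values: Sequence[float], n_bins: int = 256) -> float:
    """Histogram threshold maximizing the between-class variance.

    Values are binned into ``n_bins`` equal-width bins; the returned
    threshold is the bin edge with maximal between-class variance, ties
    resolved toward the lower edge.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2 or values.min() == values.max():
        raise ValueError("otsu_threshold requires non-constant input")
    counts, edges = np.histogram(values, bins=n_bins)
    total = counts.sum()
    p = counts / total
    centers = 0.5 * (edges[:-1] + edges[1:])
    w0 = np.cumsum(p)[:-1]  # weight of the lower class at each inner edge
    w1 = 1.0 - w0
    cum_mu = np.cumsum(p * centers)[:-1]
    mu_total = float(np.sum(p * centers))
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = cum_mu / w0
        mu1 = (mu_total - cum_mu) / w1
        between = w0 * w1 * (mu0 - mu1) ** 2
    between = np.where((w0 > 0) & (w1 > 0), between, -np.inf)
    k = int(np.argmax(between))  # argmax takes the first (lowest) maximum
    return float(edges[k + 1])


def align_by_event(
    traces: Sequence[CellTrace], event_times: Sequence[float]
):
    """Shift each trace so its event (e.g. time of budding) sits at t=0.

    Event times are snapped to the nearest sampled timepoint so the
    shifted grids stay commensurate.  Returns ``(aligned_traces, mean_df)``
    where mean_df has columns time/mean/sd/n, restricted to timepoints
    where at least 2 cells overlap.
    """
    if len(event_times) != len(traces):
        raise ValueError("need exactly one event time per trace")
    if any(e is None or not np.isfinite(e) for e in event_times):
        raise ValueError("missing event time")
    import pandas as pd

    aligned = []
    for tr, ev in zip(traces, event_times):
        snap = tr.times[np.argmin(np.abs(tr.times - ev))]
        aligned.append(
            CellTrace(tr.cell_id, tr.times - snap, tr.fluorescence.copy(),
                      tr.system, tr.background_subtracted)
        )
    frames = {tr.cell_id: pd.Series(tr.fluorescence, index=np.round(tr.times, 9))
              for tr in aligned}
    wide = pd.DataFrame(frames)
    n = wide.notna().sum(axis=1)
    mean_df = pd.DataFrame({
        "time": wide.index.to_numpy(dtype=float),
        "mean": wide.mean(axis=1).to_numpy(),
        "sd": wide.std(axis=1, ddof=1).to_numpy(),
        "n": n.to_numpy(),
    })
    mean_df = mean_df[mean_df["n"] >= 2].reset_index(drop=True)
    return aligned, mean_df


def one_tailed_z_test(sample_a: Sequence[float], sample_b: Sequence[float]) -> float:
    """One-tailed z test of mean(a) > mean(b) using sample SDs.

    Returns P(Z >= z_obs); identical samples give p = 0.5.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need n >= 2")
    se = np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
    if se == 0:
        return 0.5 if a.mean() == b.mean() else (0.0 if a.mean() > b.mean() else 1.0)
    z = (a.mean() - b.mean()) / se
    return float(sps.norm.sf(z))
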