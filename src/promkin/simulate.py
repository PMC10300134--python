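"""Seeded synthetic induction experiments.

Emulates the benchmark's experimental design — at least 1 h of
pre-induction imaging, 3.5 h of induction, 3 h post-induction, 10-min
sampling — so that every downstream stage (fitting, exclusion,
population statistics, growth analysis) is testable offline with known
ground truth.

Cell-to-cell variability is lognormal on the rate parameters (keeps
rates positive, reproduces right-skewed parameter distributions) and
zero-truncated normal on the lags.  Measurement noise is additive
Gaussian per timepoint on top of a cell-constant autofluorescence
offset, matching an analysis pipeline that background-subtracts mean
wild-type autofluorescence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .model import InductionProtocol, KineticParams, integrate_model, steady_state

__all__ = [
    "PopulationConfig",
    "SystemPreset",
    "SYSTEM_PRESETS",
    "generate_population",
    "inject_outlier_cells",
    "generate_growth_series",
    "generate_bimodal_sample",
    "generate_noise_points",
    "GrowthRecord",
]

#: central parameters of a GAL1pr-like reporter used as simulation default:
#: maturation half-time ~20 min, turnover ~40 min timescale, 10-min
#: activation lag, 5-min deactivation lag.
DEFAULT_CENTRAL = KineticParams(b=1e-4, i=1e-3, f=0.035, d=0.017, t_on=10.0, t_off=5.0)

#: default per-parameter coefficients of variation across cells
DEFAULT_CV = {"b": 0.2, "i": 0.2, "f": 0.0, "d": 0.1, "t_on": 0.2, "t_off": 0.2}


@dataclass
class PopulationConfig:
    """Configuration of one synthetic single-cell induction experiment.

    noise_sd defaults to 5% of the central induced steady state;
    autofluorescence is the residual cell-constant offset left after
    background subtraction (mean 0 by construction).
    """

    n_cells: int = 200
    central_params: KineticParams = DEFAULT_CENTRAL
    cv_params: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_CV))
    noise_sd: float | None = None
    autofluorescence_mean: float = 0.0
    autofluorescence_sd: float = 0.0
    protocol: InductionProtocol = field(default_factory=InductionProtocol)
    outlier_fraction: float = 0.0
    seed: int = 0
    system: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.outlier_fraction < 0 or self.outlier_fraction >= 1:
            raise ValueError("outlier_fraction must be in [0, 1)")
        if self.noise_sd is None:
            self.noise_sd = 0.05 * steady_state(self.central_params, induced=True)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class SystemPreset:
    """Approximate characteristics of a benchmarked inducible system.

    Only values printed in running text are stored (figure-read numbers
    are excluded); all are flagged approximate.
    """

    name: str
    steady_state_level: float | None = None  # maxGAL1
    leakiness: float | None = None  # maxGAL1
    relative_max_intensity: float | None = None  # fold vs reference system
    t_off_shift_min: float | None = None  # minutes vs reference system
    maturation_time_min: float | None = None
    provenance: str = "approximate, from running text"


SYSTEM_PRESETS: tuple[SystemPreset, ...] = (
    SystemPreset("GAL1pr", steady_state_level=1.0,
                 provenance="approximate, from text: unit definition, 1 maxGAL1"),
    SystemPreset("GALL", steady_state_level=0.02,
                 provenance="approximate, from text: ~0.02 maxGAL1 steady state"),
    SystemPreset("tetOpr", leakiness=0.01,
                 provenance="approximate, from text: basal expression ~1% maxGAL1"),
    SystemPreset("strongLOV", relative_max_intensity=5.7, t_off_shift_min=22.0,
                 leakiness=None,
                 provenance="approximate, from text: 5.7x El222 max intensity, "
                            "t_off 22 min longer, leakiness 3.2x El222"),
    SystemPreset("AQTrip", relative_max_intensity=3.4,
                 provenance="approximate, from text: 3.4x El222 max intensity"),
    SystemPreset("ymScarletI-reporter", maturation_time_min=11.8,
                 provenance="approximate, from text: maturation time "
                            "(11.8 +/- 0.11) min (median +/- s.e.m.)"),
)


@dataclass
class GrowthRecord:
    """One colony's area time series with (optionally) fitted growth."""

    colony_id: str
    times: np.ndarray
    areas: np.ndarray
    growth_rate: float | None = None  # 1/min
    doubling_time: float | None = None  # min
    ci90: tuple[float, float] | None = None  # min

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.areas <= 0):
            raise ValueError("areas must be positive")


def _draw_lognormal(rng: np.random.Generator, mean: float, cv: float, n: int):
    """Lognormal draws with the requested mean and coefficient of variation."""
    if mean == 0 or cv == 0:
        return np.full(n, mean)
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return np.exp(rng.normal(mu, np.sqrt(sigma2), n))


def _draw_truncnorm(rng: np.random.Generator, mean: float, cv: float, n: int):
    """Zero-truncated normal draws (for lags, which must stay >= 0)."""
    if mean == 0 or cv == 0:
        return np.full(n, mean)
    sd = cv * mean
    a = (0.0 - mean) / sd
    u = rng.random(n)
    return truncnorm.ppf(u, a, np.inf, loc=mean, scale=sd)


def generate_population(config: PopulationConfig):
    """Simulate a population of single-cell fluorescence time courses.

    Per cell: draw the kinetic parameters around the central values,
    integrate the model on the protocol grid, add a cell-constant
    autofluorescence offset and i.i.d. Gaussian measurement noise.

    Returns ``(traces, truth)`` where traces is a list of
    :class:`promkin.fitting.CellTrace` and truth is a DataFrame of the
    per-cell ground-truth parameters (for recovery tests).  Fully
    deterministic given ``config.seed``.
    """
    from .fitting import CellTrace  # local import avoids a cycle

    rng = np.random.default_rng(config.seed)
    c = config.central_params
    cv = dict(DEFAULT_CV)
    cv.update(config.cv_params)
    n = config.n_cells

    draws = {
        "b": _draw_lognormal(rng, c.b, cv["b"], n),
        "i": _draw_lognormal(rng, c.i, cv["i"], n),
        "f": _draw_lognormal(rng, c.f, cv["f"], n),
        "d": _draw_lognormal(rng, c.d, cv["d"], n),
        "t_on": _draw_truncnorm(rng, c.t_on, cv["t_on"], n),
        "t_off": _draw_truncnorm(rng, c.t_off, cv["t_off"], n),
    }
    if np.any(draws["d"] <= 0):
        raise ValueError("drew a non-positive degradation-and-dilution rate d")
    autofl = rng.normal(config.autofluorescence_mean, config.autofluorescence_sd, n) \
        if config.autofluorescence_sd > 0 else np.full(n, config.autofluorescence_mean)

    times = config.protocol.times()
    traces: list[CellTrace] = []
    rows = []
    for k in range(n):
        params = KineticParams(
            b=draws["b"][k], i=draws["i"][k], f=draws["f"][k], d=draws["d"][k],
            t_on=draws["t_on"][k], t_off=draws["t_off"][k],
        )
        trace_f = integrate_model(params, config.protocol, times, rtol=1e-9)
        noisy = trace_f + autofl[k]
        if config.noise_sd > 0:
            noisy = noisy + rng.normal(0.0, config.noise_sd, times.size)
        cell_id = f"cell_{k:04d}"
        traces.append(
            CellTrace(cell_id=cell_id, times=times.copy(), fluorescence=noisy,
                      system=config.system)
        )
        rows.append({"cell_id": cell_id, **{p: getattr(params, p) for p in
                     ("b", "i", "f", "d", "t_on", "t_off")},
                     "autofluorescence": autofl[k], "is_outlier": False,
                     "outlier_type": ""})
    truth = pd.DataFrame(rows)

    if config.outlier_fraction > 0:
        traces, tags = inject_outlier_cells(
            traces, config.outlier_fraction, seed=rng.integers(2**31),
            protocol=config.protocol, noise_sd=config.noise_sd,
        )
        truth = truth.set_index("cell_id")
        truth.loc[tags["cell_id"], "is_outlier"] = True
        truth.loc[tags["cell_id"], "outlier_type"] = tags["outlier_type"].values
        truth = truth.reset_index()
    return traces, truth


def inject_outlier_cells(
    traces: Sequence,
    fraction: float,
    seed: int,
    protocol: InductionProtocol | None = None,
    noise_sd: float = 0.0,
):
    """Replace a random fraction of cells with pathological traces.

    Two kinds, alternating:

    * ``rising_after_shutoff`` — fluorescence keeps increasing after the
      inducer is removed (yields a negative fitted d);
    * ``high_at_start`` — fluorescence at induction onset exceeds the
      level one hour after shutoff (F(0 h) > F(4.5 h)).

    Returns ``(traces, tags)`` with tags a DataFrame (cell_id,
    outlier_type) so exclusion logic can be scored.
    """
    if not (0 <= fraction < 1):
        raise ValueError("fraction must be in [0, 1)")
    traces = list(traces)
    n_out = int(round(fraction * len(traces)))
    rng = np.random.default_rng(seed)
    if n_out == 0:
        return traces, pd.DataFrame(columns=["cell_id", "outlier_type"])
    protocol = protocol or InductionProtocol()
    idx = rng.choice(len(traces), size=n_out, replace=False)
    rows = []
    for j, cell_idx in enumerate(sorted(idx)):
        old = traces[cell_idx]
        times = old.times
        if j % 2 == 0:
            # promoter never shuts off: fluorescence still rising at the end
            kind = "rising_after_shutoff"
            params = KineticParams(b=1e-4, i=1e-3, f=0.035, d=0.017,
                                   t_on=10.0, t_off=5.0)
            never_off = InductionProtocol(
                t_start=protocol.t_start, t_end=protocol.observe_to + 60.0,
                observe_from=protocol.observe_from,
                observe_to=protocol.observe_to + 120.0,
                sampling_interval=protocol.sampling_interval,
            )
            fl = integrate_model(params, never_off, times, rtol=1e-9)
        else:
            # starts bright and decays: F(0 h) > F(4.5 h)
            kind = "high_at_start"
            level = 0.05
            fl = level * np.exp(-0.01 * (times - times[0]))
        if noise_sd > 0:
            fl = fl + rng.normal(0.0, noise_sd, times.size)
        traces[cell_idx] = type(old)(
            cell_id=old.cell_id, times=times.copy(), fluorescence=fl,
            system=old.system,
        )
        rows.append({"cell_id": old.cell_id, "outlier_type": kind})
    return traces, pd.DataFrame(rows)


def generate_growth_series(
    rate: float,
    t_range: tuple[float, float] = (150.0, 210.0),
    noise_cv: float = 0.0,
    seed: int = 0,
    area0: float = 100.0,
    sampling_interval: float = 10.0,
    colony_id: str = "colony_0",
) -> GrowthRecord:
    """Exponential colony-area growth with multiplicative lognormal noise.

    A(t) = area0 * exp(rate * (t - t0)), sampled every ``sampling_interval``
    minutes over ``t_range``.
    """
    if rate <= 0:
        raise ValueError("growth rate must be > 0")
    rng = np.random.default_rng(seed)
    n = int(round((t_range[1] - t_range[0]) / sampling_interval))
    times = t_range[0] + sampling_interval * np.arange(n + 1)
    areas = area0 * np.exp(rate * (times - times[0]))
    if noise_cv > 0:
        sigma2 = np.log1p(noise_cv**2)
        areas = areas * np.exp(rng.normal(-sigma2 / 2, np.sqrt(sigma2), times.size))
    return GrowthRecord(colony_id=colony_id, times=times, areas=areas)


def generate_noise_points(
    n_systems: int = 12,
    slope: float = -0.32,
    intercept: float = -0.5,
    scatter_sd: float = 0.05,
    mean_range: tuple[float, float] = (1e-2, 1.0),
    seed: int = 0,
):
    """Synthetic per-system noise points with a known CV-vs-mean power law.

    log10(CV) = intercept + slope * log10(mean) + N(0, scatter_sd), with
    mean expressions log-spaced over ``mean_range`` — the structure of a
    cross-system noise-scaling panel.
    """
    from .stats import NoisePoint

    rng = np.random.default_rng(seed)
    means = np.logspace(np.log10(mean_range[0]), np.log10(mean_range[1]), n_systems)
    log_cv = intercept + slope * np.log10(means) + rng.normal(0, scatter_sd, n_systems)
    return [
        NoisePoint(system=f"system_{k:02d}", mean_expression=float(means[k]),
                   cv=float(10.0 ** log_cv[k]))
        for k in range(n_systems)
    ]


def generate_bimodal_sample(
    n: int,
    weights: Sequence[float],
    means: Sequence[float],
    sds: Sequence[float],
    seed: int = 0,
) -> np.ndarray:
    """Draw from a Gaussian mixture (fixture for bimodality/Otsu logic)."""
    weights = np.asarray(weights, dtype=float)
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("weights must sum to 1")
    if not (len(weights) == len(means) == len(sds)):
        raise ValueError("weights, means, sds must have equal length")
    rng = np.random.default_rng(seed)
    comp = rng.choice(len(weights), size=n, p=weights)
    return rng.normal(np.asarray(means, float)[comp], np.asarray(sds, float)[comp])
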