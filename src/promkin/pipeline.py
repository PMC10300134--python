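"""End-to-end orchestration: simulate (or load) -> fit -> exclude -> summarize.

`run_pipeline` chains the full benchmark analysis on one population and
writes versioned tabular outputs plus a run log carrying the seed and a
hash of the configuration, so a rerun with the same config and seed is
byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import growth as growth_mod
from . import io as pio
from . import stats as pstats
from .fitting import CellTrace, exclude_cells, fit_cell, fit_population_average
from .io import RunConfig
from .model import KineticParams
from .simulate import PopulationConfig, generate_growth_series, generate_population

__all__ = [
    "run_pipeline",
    "fit_batch",
    "results_table",
    "lag_ci_coverage",
    "noise_slope_ci_coverage",
]

PARAM_FIELDS = ("b", "i", "f", "d", "t_on", "t_off")


def fit_batch(traces: Sequence[CellTrace], config) -> list:
    """Staged fit of every trace; stage failures become flags."""
    return [fit_cell(tr, config) for tr in traces]


def results_table(results) -> pd.DataFrame:
    """Flatten fit results into a per-cell parameter table."""
    rows = []
    for res in results:
        row = {"cell_id": res.cell_id}
        for fld in PARAM_FIELDS:
            row[fld] = getattr(res.params, fld) if res.params else np.nan
        row.update({
            "basal_plateau": res.basal_plateau,
            "induced_plateau": res.induced_plateau,
            "rss_rise": res.residuals.get("rise", np.nan),
            "rss_fall": res.residuals.get("fall", np.nan),
            "rss_decay": res.residuals.get("decay", np.nan),
            "flags": ";".join(res.flags),
            "excluded": res.excluded,
            "exclusion_reason": res.exclusion_reason,
        })
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig, outdir: str | Path, traces=None) -> dict:
    """Run the benchmark chain and write its report bundle under outdir.

    If ``traces`` is None, a synthetic population is generated from the
    config.  Outputs: traces.csv, ground_truth.csv (synthetic runs),
    per_cell_fits.csv, population_fit.json, lag_bootstrap.json,
    violin_summaries.json, noise_point.json, growth.csv, growth_summary.json,
    run_log.json.  Returns the bundle as a dict of paths and objects.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    log: dict = {"seed": config.seed, "config_hash": config.config_hash(),
                 "config": asdict(config), "stages": []}

    truth = None
    if traces is None:
        pop_cfg = PopulationConfig(
            n_cells=config.n_cells,
            central_params=KineticParams(**config.central_params),
            cv_params=dict(config.cv_params),
            noise_sd=config.noise_sd,
            protocol=config.induction_protocol(),
            outlier_fraction=config.outlier_fraction,
            seed=int(rng.integers(2**31)),
        )
        traces, truth = generate_population(pop_cfg)
        pio.write_traces(traces, outdir / "traces.csv")
        truth.to_csv(outdir / "ground_truth.csv", index=False)
        log["stages"].append("simulate")

    if config.normalization_reference:
        traces = pstats.normalize_to_maxgal1(traces, config.normalization_reference)
        log["stages"].append("normalize")

    fit_cfg = config.fit_config()
    results = fit_batch(traces, fit_cfg)
    kept, excluded = exclude_cells(results, traces)
    table = results_table(results)
    table.to_csv(outdir / "per_cell_fits.csv", index=False)
    log["stages"].append("fit_per_cell")
    log["n_cells"] = len(traces)
    log["n_excluded"] = len(excluded)

    kept_ids = {r.cell_id for r in kept}
    kept_traces = [tr for tr in traces if tr.cell_id in kept_ids]
    pop_res = fit_population_average(kept_traces, fit_cfg)
    pop_payload = {f: getattr(pop_res.params, f) for f in PARAM_FIELDS}
    pop_payload["flags"] = pop_res.flags
    (outdir / "population_fit.json").write_text(json.dumps(pop_payload, indent=2))
    log["stages"].append("fit_population")

    boot = {}
    if len(kept_traces) >= config.bootstrap_sample_size:
        (t_on_ci, t_off_ci), = [(pstats.bootstrap_lag_ci(
            kept_traces, fit_cfg, n_resamples=config.n_resamples,
            sample_size=config.bootstrap_sample_size,
            seed=int(rng.integers(2**31)))[:2])]
        boot = {"t_on_ci95": list(t_on_ci), "t_off_ci95": list(t_off_ci),
                "n_resamples": config.n_resamples,
                "sample_size": config.bootstrap_sample_size}
        (outdir / "lag_bootstrap.json").write_text(json.dumps(boot, indent=2))
        log["stages"].append("bootstrap_lags")

    kept_table = table[~table["excluded"]]
    violins = {}
    for fld in ("i", "d", "b"):
        vals = kept_table[fld].dropna().to_numpy()
        if vals.size >= 5:
            vs = pstats.violin_summary(vals, n_bins=config.otsu_bins)
            violins[fld] = {
                "bandwidth": vs.bandwidth,
                "bimodality_coefficient": vs.bimodality_coefficient,
                "is_bimodal": vs.is_bimodal,
                "split_threshold": vs.split_threshold,
                "n_outliers": int(vs.outliers.size),
            }
    (outdir / "violin_summaries.json").write_text(json.dumps(violins, indent=2))
    log["stages"].append("violin_summaries")

    t_last = config.protocol["t_end"]
    last_vals = np.array([tr.value_at(t_last) for tr in kept_traces])
    noise = {"system": "synthetic",
             "mean_expression": float(last_vals.mean()),
             "cv": pstats.compute_cv(last_vals)}
    (outdir / "noise_point.json").write_text(json.dumps(noise, indent=2))
    log["stages"].append("noise_point")

    colonies = [
        generate_growth_series(
            config.growth_rate, t_range=tuple(config.growth_window),
            noise_cv=config.growth_noise_cv, seed=int(rng.integers(2**31)),
            colony_id=f"colony_{k:03d}",
        )
        for k in range(config.n_colonies)
    ]
    pio.write_growth(colonies, outdir / "growth.csv")
    fitted = [growth_mod.area_doubling_time(c, window=tuple(config.growth_window))
              for c in colonies]
    growth_summary = {
        "doubling_times_min": [c.doubling_time for c in fitted],
        "mean_doubling_time_min": float(np.mean([c.doubling_time for c in fitted])),
    }
    (outdir / "growth_summary.json").write_text(json.dumps(growth_summary, indent=2))
    log["stages"].append("growth")

    (outdir / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    return {
        "traces": traces, "truth": truth, "results": results,
        "kept": kept, "excluded": excluded, "table": table,
        "population_fit": pop_res, "bootstrap": boot, "violins": violins,
        "noise_point": noise, "growth": fitted, "log": log, "outdir": outdir,
    }


def lag_ci_coverage(
    n_replicates: int = 100,
    n_resamples: int = 1000,
    sample_size: int = 100,
    n_cells: int = 120,
    seed: int = 0,
    pop_config: PopulationConfig | None = None,
    fit_config=None,
) -> dict:
    """Coverage diagnostic of the bootstrap lag CI on synthetic data.

    Runs ``n_replicates`` independent synthetic experiments and counts
    how often the nominal 95% bootstrap CI for t_on (and t_off) covers
    the central ground-truth lag.  Returns counts and the coverage
    fractions.
    """
    from .fitting import FitConfig
    from . import stats as pstats

    rng = np.random.default_rng(seed)
    fit_config = fit_config or FitConfig(chemically_induced=False)
    template = pop_config or PopulationConfig(n_cells=n_cells)
    hits_on = hits_off = valid_off = 0
    for _ in range(n_replicates):
        cfg = PopulationConfig(
            n_cells=template.n_cells,
            central_params=template.central_params,
            cv_params=dict(template.cv_params),
            noise_sd=template.noise_sd,
            protocol=template.protocol,
            seed=int(rng.integers(2**31)),
        )
        traces, _ = generate_population(cfg)
        ci_on, ci_off, _ = pstats.bootstrap_lag_ci(
            traces, fit_config, n_resamples=n_resamples,
            sample_size=sample_size, seed=int(rng.integers(2**31)),
        )
        c = cfg.central_params
        if ci_on[0] <= c.t_on <= ci_on[1]:
            hits_on += 1
        if np.isfinite(ci_off[0]):
            valid_off += 1
            if ci_off[0] <= c.t_off <= ci_off[1]:
                hits_off += 1
    return {
        "n_replicates": n_replicates,
        "t_on_covered": hits_on,
        "t_on_coverage": hits_on / n_replicates,
        "t_off_covered": hits_off,
        "t_off_valid": valid_off,
    }


def noise_slope_ci_coverage(
    n_seeds: int = 200,
    slope: float = -0.32,
    scatter_sd: float = 0.05,
    seed: int = 0,
) -> dict:
    """How often the noise-scaling regression's 95% slope CI covers the
    true power-law slope on synthetic cross-system noise panels."""
    from . import stats as pstats
    from .simulate import generate_noise_points

    rng = np.random.default_rng(seed)
    hits = 0
    slopes = []
    for _ in range(n_seeds):
        pts = generate_noise_points(
            slope=slope, scatter_sd=scatter_sd, seed=int(rng.integers(2**31))
        )
        est, _, _, ci = pstats.noise_scaling_regression(pts)
        slopes.append(est)
        if ci[0] <= slope <= ci[1]:
            hits += 1
    return {
        "n_seeds": n_seeds,
        "covered": hits,
        "coverage": hits / n_seeds,
        "mean_slope": float(np.mean(slopes)),
    }
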