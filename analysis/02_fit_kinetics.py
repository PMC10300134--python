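#!/usr/bin/env python
"""Fit the kinetic model to every cell and to the population average.

Reads the traces written by 01_simulate_population.py, runs the staged
fit (basal plateau, degradation-and-dilution rate, induction speed and
lags), applies the pathological-cell exclusion rules, and writes the
per-cell parameter table and the population-average fit.  Prints the
recovered parameters next to the generator's central truth.
"""

import json
from pathlib import Path

import pandas as pd

from promkin.fitting import FitConfig, exclude_cells, fit_population_average
from promkin.io import read_traces
from promkin.pipeline import fit_batch, results_table

OUT = Path("results/analysis")
TRUTH = {"b": 1e-4, "i": 1e-3, "d": 0.017, "t_on": 10.0, "t_off": 5.0}


def main() -> None:
    traces_path = OUT / "traces.csv"
    if not traces_path.exists():
        raise SystemExit("run analysis/01_simulate_population.py first")
    traces = read_traces(traces_path)
    cfg = FitConfig(chemically_induced=False)

    results = fit_batch(traces, cfg)
    kept, excluded = exclude_cells(results, traces)
    table = results_table(results)
    table.to_csv(OUT / "per_cell_fits.csv", index=False)

    kept_ids = {r.cell_id for r in kept}
    pop = fit_population_average(
        [tr for tr in traces if tr.cell_id in kept_ids], cfg)
    payload = {k: getattr(pop.params, k) for k in ("b", "i", "f", "d", "t_on", "t_off")}
    (OUT / "population_fit.json").write_text(json.dumps(payload, indent=2))

    print(f"fitted {len(results)} cells, excluded {len(excluded)}")
    print("population-average fit vs. generator truth:")
    for k, true in TRUTH.items():
        est = payload[k]
        print(f"  {k:>6}: fitted {est:.5g}   true {true:.5g}")
    med = table.loc[~table["excluded"], ["i", "d", "b"]].median()
    print("per-cell medians: "
          + ", ".join(f"{k}={med[k]:.4g}" for k in ("i", "d", "b")))
    print(f"wrote {OUT/'per_cell_fits.csv'} and {OUT/'population_fit.json'}")


if __name__ == "__main__":
    main()
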