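#!/usr/bin/env python
"""Simulate the canonical induction experiment.

Generates a 200-cell synthetic population of a GAL1pr-like inducible
reporter on the standard protocol (1 h pre-induction, 3.5 h induction,
3 h post-induction, 10-min imaging), with cell-to-cell parameter
variability and 5% measurement noise, and writes the long-format trace
table plus the per-cell ground truth under results/analysis/.
"""

import sys
from pathlib import Path

import numpy as np

from promkin.io import write_traces
from promkin.model import KineticParams
from promkin.simulate import PopulationConfig, generate_population

OUT = Path("results/analysis")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    central = KineticParams(b=1e-4, i=1e-3, f=0.035, d=0.017, t_on=10.0, t_off=5.0)
    cfg = PopulationConfig(n_cells=200, central_params=central, seed=SEED)
    traces, truth = generate_population(cfg)
    write_traces(traces, OUT / "traces.csv")
    truth.to_csv(OUT / "ground_truth.csv", index=False)

    last = np.array([tr.value_at(210.0) for tr in traces])
    print(f"simulated {len(traces)} cells, seed={SEED}")
    print(f"  grid: {traces[0].times[0]:.0f}..{traces[0].times[-1]:.0f} min, "
          f"step {traces[0].times[1] - traces[0].times[0]:.0f} min")
    print(f"  fluorescence at end of induction: "
          f"mean {last.mean():.4f}, CV {last.std(ddof=1)/last.mean():.3f}")
    print(f"  wrote {OUT/'traces.csv'} and {OUT/'ground_truth.csv'}")


if __name__ == "__main__":
    main()
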