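"""Tabular I/O and run configuration.

Trace tables are long-format CSV with columns cell_id, time_min,
fluorescence, system (optional: channel, background_subtracted).  Times
are minutes with induction onset at t=0.  Validation is strict and
reports offending line numbers (1-based, counting the header as line 1).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .fitting import CellTrace, FitConfig, FitWindows
from .model import InductionProtocol

__all__ = [
    "read_traces",
    "write_traces",
    "read_growth",
    "write_growth",
    "RunConfig",
]

REQUIRED_COLUMNS = ("cell_id", "time_min", "fluorescence")


def read_traces(path: str | Path) -> list[CellTrace]:
    """Read a long-format trace CSV into per-cell traces.

    Raises ValueError with line numbers on schema violations or
    duplicate (cell_id, time_min) rows.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required column(s) {missing}")
    for col in ("time_min", "fluorescence"):
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
        if len(bad):
            lines = [int(i) + 2 for i in bad[:5]]
            raise ValueError(f"{path.name}: non-numeric {col} at line(s) {lines}")
        if df[col].isna().any():
            lines = [int(i) + 2 for i in df.index[df[col].isna()][:5]]
            raise ValueError(f"{path.name}: missing {col} at line(s) {lines}")
    dup = df.duplicated(subset=["cell_id", "time_min"], keep=False)
    if dup.any():
        lines = [int(i) + 2 for i in df.index[dup][:5]]
        raise ValueError(
            f"{path.name}: duplicate (cell_id, time_min) at line(s) {lines}"
        )
    traces = []
    for cell_id, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("time_min")
        traces.append(
            CellTrace(
                cell_id=str(cell_id),
                times=grp["time_min"].to_numpy(dtype=float),
                fluorescence=grp["fluorescence"].to_numpy(dtype=float),
                system=str(grp["system"].iloc[0]) if "system" in grp else "",
                background_subtracted=bool(grp["background_subtracted"].iloc[0])
                if "background_subtracted" in grp else True,
            )
        )
    return traces


def write_traces(traces: Sequence[CellTrace], path: str | Path) -> Path:
    """Write traces as long-format CSV (round-trips through read_traces)."""
    path = Path(path)
    rows = []
    for tr in traces:
        for t, fl in zip(tr.times, tr.fluorescence):
            rows.append({
                "cell_id": tr.cell_id, "time_min": t, "fluorescence": fl,
                "system": tr.system,
                "background_subtracted": tr.background_subtracted,
            })
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_growth(path: str | Path):
    """Read a colony-area CSV (colony_id, time_min, area) into records."""
    from .simulate import GrowthRecord

    df = pd.read_csv(path)
    missing = [c for c in ("colony_id", "time_min", "area") if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s) {missing}")
    records = []
    for colony_id, grp in df.groupby("colony_id", sort=True):
        grp = grp.sort_values("time_min")
        records.append(GrowthRecord(
            colony_id=str(colony_id),
            times=grp["time_min"].to_numpy(dtype=float),
            areas=grp["area"].to_numpy(dtype=float),
        ))
    return records


def write_growth(records, path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {"colony_id": rec.colony_id, "time_min": t, "area": a}
        for rec in records for t, a in zip(rec.times, rec.areas)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


@dataclass
class RunConfig:
    """Declarative configuration of a full pipeline run.

    All defaults are explicit here; everything random derives from the
    single root seed.
    """

    seed: int = 0
    n_cells: int = 200
    protocol: dict = field(default_factory=lambda: asdict(InductionProtocol()))
    # simulation
    central_params: dict = field(default_factory=lambda: {
        "b": 1e-4, "i": 1e-3, "f": 0.035, "d": 0.017, "t_on": 10.0, "t_off": 5.0})
    cv_params: dict = field(default_factory=lambda: {
        "b": 0.2, "i": 0.2, "f": 0.0, "d": 0.1, "t_on": 0.2, "t_off": 0.2})
    noise_sd: float | None = None
    outlier_fraction: float = 0.0
    # fitting
    f_fixed: float = 0.035
    windows: dict = field(default_factory=lambda: asdict(FitWindows()))
    chemically_induced: bool = False  # synthetic inductions carry no media delay
    media_delay_s: float = 170.0
    basis: str = "exact"
    # statistics
    n_resamples: int = 1000
    bootstrap_sample_size: int = 100
    otsu_bins: int = 256
    normalization_reference: float | None = None
    noise_exclusions: list = field(default_factory=list)
    # growth
    growth_rate: float = 0.0069  # ~100-min doubling
    growth_noise_cv: float = 0.02
    n_colonies: int = 20
    growth_window: tuple = (150.0, 210.0)

    def fit_config(self) -> FitConfig:
        w = FitWindows(**{k: tuple(v) for k, v in self.windows.items()})
        return FitConfig(
            f_fixed=self.f_fixed,
            t_end=self.protocol["t_end"],
            windows=w,
            chemically_induced=self.chemically_induced,
            media_delay_s=self.media_delay_s,
            basis=self.basis,
        )

    def induction_protocol(self) -> InductionProtocol:
        return InductionProtocol(**self.protocol)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**data)
        if isinstance(cfg.growth_window, list):
            cfg.growth_window = tuple(cfg.growth_window)
        return cfg

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
        return path
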