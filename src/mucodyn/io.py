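"""Table, config and report I/O.

CSV dialects: abundance tables have sample IDs in the first column and
taxon names as the header; growth tables are ``taxon,r_max,mu,sigma``;
trajectories are tidy ``time_days,taxon,abundance,relative_abundance_pct``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from mucodyn.model_core import GrowthParams, Trajectory
from mucodyn.network_inference import AbundanceTable
from mucodyn.scenario_engine import SolverConfig

__all__ = [
    "read_abundance_table",
    "write_abundance_table",
    "read_growth_table",
    "write_growth_table",
    "write_trajectory",
    "load_config",
    "write_json_report",
]


def _sep_for(path: str | Path, dialect: str | None) -> str:
    if dialect == "tsv":
        return "\t"
    if dialect == "csv":
        return ","
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_abundance_table(path: str | Path, dialect: str | None = None) -> AbundanceTable:
    """Load a sample-by-taxon percentage table from CSV/TSV.

    First column holds sample IDs; header row holds taxon names.
    Negative values and duplicate IDs are rejected with the offending
    row/column named.
    """
    df = pd.read_csv(
        path, sep=_sep_for(path, dialect), index_col=0, float_precision="round_trip"
    )
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"{path}: duplicate sample IDs {dups}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].tolist()
        raise ValueError(f"{path}: duplicate taxon names {dups}")
    values = df.to_numpy(dtype=float)
    if np.any(values < 0):
        r, c = np.argwhere(values < 0)[0]
        raise ValueError(
            f"{path}: negative abundance at sample {df.index[r]!r}, "
            f"taxon {df.columns[c]!r}"
        )
    return AbundanceTable.from_frame(df)


def write_abundance_table(
    table: AbundanceTable, path: str | Path, dialect: str | None = None
) -> None:
    table.to_frame().rename_axis("sample").to_csv(path, sep=_sep_for(path, dialect))


def read_growth_table(path: str | Path) -> list[GrowthParams]:
    """Load ``taxon,r_max,mu,sigma`` rows; r_max is per day."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"taxon", "r_max", "mu", "sigma"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: growth table needs columns {sorted(required)}")
    return [
        GrowthParams(
            taxon_id=str(row.taxon),
            r_max=float(row.r_max),
            mu=float(row.mu),
            sigma=float(row.sigma),
        )
        for row in df.itertuples()
    ]


def write_growth_table(params: Sequence[GrowthParams], path: str | Path) -> None:
    # shortest round-trip float repr so read_growth_table is an exact inverse
    lines = ["taxon,r_max,mu,sigma"]
    lines += [f"{p.taxon_id},{p.r_max!r},{p.mu!r},{p.sigma!r}" for p in params]
    Path(path).write_text("\n".join(lines) + "\n")


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Tidy CSV with per-time relative abundances alongside raw values."""
    taxa = traj.taxon_ids or [f"taxon_{i:02d}" for i in range(traj.states.shape[1])]
    totals = traj.states.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(totals[:, None] > 0, 100.0 * traj.states / totals[:, None], np.nan)
    rows = []
    for ti, t in enumerate(traj.times):
        for xi, taxon in enumerate(taxa):
            rows.append(
                {
                    "time_days": t,
                    "taxon": taxon,
                    "abundance": traj.states[ti, xi],
                    "relative_abundance_pct": rel[ti, xi],
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def load_config(path: str | Path | None) -> SolverConfig:
    """YAML config -> SolverConfig; missing keys fall back to defaults."""
    if path is None:
        return SolverConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in SolverConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return SolverConfig(**raw)


def write_json_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
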