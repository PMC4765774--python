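"""CSV time-course format and YAML configuration.

Canonical table layout (one row per sample):

    condition, replicate, time_h, od600, activity[, activity_units,
    dilution_factor, blank]

Column names are matched case-insensitively; ``dilution_factor`` defaults
to 1 and ``blank`` (an activity blank to subtract) to 0. Each
(condition, replicate) pair becomes one :class:`~protdeg.estimation.GrowthTimeCourse`,
sorted by time.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .estimation import GrowthTimeCourse
from .model import DegradationModelParams
from .synthetic import Condition, ExperimentDesign
from .units import CalibrationConstants

__all__ = [
    "REQUIRED_COLUMNS",
    "read_timecourses",
    "write_timecourses",
    "load_config",
    "params_from_config",
    "calibration_from_config",
    "design_from_config",
]

REQUIRED_COLUMNS = ("condition", "replicate", "time_h", "od600", "activity")
OPTIONAL_COLUMNS = ("activity_units", "dilution_factor", "blank")


def _normalise_columns(df: pd.DataFrame, path) -> pd.DataFrame:
    df = df.rename(columns={c: c.strip().lower() for c in df.columns})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return df


def read_timecourses(path) -> list[GrowthTimeCourse]:
    """Parse a time-course CSV into one GrowthTimeCourse per replicate.

    Rows are sorted by time within each (condition, replicate) group, so
    the parse is independent of row order in the file. Errors carry
    row-level context.
    """
    path = Path(path)
    # round_trip parser: re-reading a written table is bit-exact
    df = _normalise_columns(pd.read_csv(path, float_precision="round_trip"), path)
    if "dilution_factor" not in df.columns:
        df["dilution_factor"] = 1.0
    df["dilution_factor"] = df["dilution_factor"].fillna(1.0)
    if "blank" in df.columns:
        df["activity"] = df["activity"] - df["blank"].fillna(0.0)
    if "activity_units" not in df.columns:
        df["activity_units"] = "RFU_per_OD"

    dup = df.duplicated(subset=["condition", "replicate", "time_h"])
    if dup.any():
        rows = (df.index[dup] + 2).tolist()  # +2: header + 0-based index
        raise ValueError(f"{path}: duplicate (condition, replicate, time_h) at row(s) {rows}")
    bad_od = df["od600"] <= 0
    if bad_od.any():
        rows = (df.index[bad_od] + 2).tolist()
        raise ValueError(f"{path}: nonpositive od600 at row(s) {rows}")
    if (df["time_h"] < 0).any():
        rows = (df.index[df["time_h"] < 0] + 2).tolist()
        raise ValueError(f"{path}: negative time_h at row(s) {rows}")

    out = []
    for (cond, rep), g in df.groupby(["condition", "replicate"], sort=True):
        g = g.sort_values("time_h")
        units = str(g["activity_units"].iloc[0])
        out.append(
            GrowthTimeCourse(
                condition=str(cond),
                replicate=str(rep),
                times=g["time_h"].to_numpy(float),
                od=g["od600"].to_numpy(float),
                activity=g["activity"].to_numpy(float),
                dilution_factor=g["dilution_factor"].to_numpy(float),
                units=units,
            )
        )
    return out


def write_timecourses(tcs: Sequence[GrowthTimeCourse], path) -> None:
    """Write time courses to the canonical CSV layout (lossless round-trip)."""
    rows = []
    for tc in tcs:
        for j in range(tc.times.size):
            rows.append(
                {
                    "condition": tc.condition,
                    "replicate": tc.replicate,
                    "time_h": tc.times[j],
                    "od600": tc.od[j],
                    "activity": tc.activity[j],
                    "activity_units": tc.units,
                    "dilution_factor": tc.dilution_factor[j],
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def load_config(path) -> dict:
    """Load a YAML run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def params_from_config(section: dict) -> DegradationModelParams:
    return DegradationModelParams(
        alpha=float(section.get("alpha", 0.0)),
        mu=float(section.get("mu", 0.0)),
        vmax=float(section.get("vmax", 0.0)),
        km=float(section.get("km", 0.0)),
        p0=float(section.get("p0", 0.0)),
    )


def calibration_from_config(section: dict) -> CalibrationConstants:
    rc = section.get("residue_count")
    return CalibrationConstants(
        rfu_per_od_to_proteins=float(section.get("rfu_per_od_to_proteins", 10.0)),
        cell_volume=float(section.get("cell_volume_l", 1e-15)),
        residue_count=int(rc) if rc is not None else None,
    )


def design_from_config(section: dict, seed: int | None = None) -> ExperimentDesign:
    conditions = tuple(
        Condition(
            label=str(c["label"]),
            params=params_from_config(c.get("model", {})),
            is_control=bool(c.get("is_control", False)),
        )
        for c in section.get("conditions", [])
    )
    return ExperimentDesign(
        conditions=conditions,
        replicates=int(section.get("replicates", 6)),
        t_start=float(section.get("t_start", 0.0)),
        t_end=float(section.get("t_end", 4.0)),
        sampling_interval=float(section.get("sampling_interval", 1.0)),
        noise_cv=float(section.get("noise_cv", 0.05)),
        od0=float(section.get("od0", 0.05)),
        dilution_threshold=float(section.get("dilution_threshold", 1.0)),
        seed=int(seed if seed is not None else section.get("seed", 0)),
    )
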