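"""Readers and writers for trajectory/annotation CSVs, YAML configs and reports."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import DT_S, AnalysisWindow, GradientSpec, Trajectory, TrajectorySource, regrid_uniform

TRAJECTORY_COLUMNS = ["worm_id", "t_s", "x_mm", "y_mm"]
ANNOTATION_COLUMNS = ["worm_id", "t_s", "state"]


def read_trajectories(path, dt: float = DT_S) -> list[Trajectory]:
    """Read trajectories from CSV (columns worm_id,t_s,x_mm,y_mm).

    Rows are grouped by worm and sorted by time; non-numeric cells or
    non-monotone time after sorting are rejected with a row-level diagnostic.
    """
    df = pd.read_csv(path, dtype={"worm_id": str})
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    for col in ("t_s", "x_mm", "y_mm"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(f"{path}: non-numeric value in column {col!r} at row {bad[0] + 2}")
        if vals.isna().any():
            raise ValueError(f"{path}: empty cell in column {col!r}")
        df[col] = vals
    out: list[Trajectory] = []
    for worm_id, g in df.groupby("worm_id", sort=True):
        g = g.sort_values("t_s", kind="stable")
        t = g["t_s"].to_numpy()
        if np.any(np.diff(t) <= 0):
            i = int(np.flatnonzero(np.diff(t) <= 0)[0])
            raise ValueError(
                f"{path}: worm {worm_id!r} has non-increasing time at t={t[i + 1]:g}"
            )
        xy = g[["x_mm", "y_mm"]].to_numpy()
        t, xy = regrid_uniform(t, xy, dt=dt)
        out.append(Trajectory(worm_id=str(worm_id), t=t, xy=xy, source=TrajectorySource.IMPORTED))
    return out


def write_trajectories(trajs, path) -> None:
    frames = [
        pd.DataFrame(
            {
                "worm_id": tr.worm_id,
                "t_s": np.round(tr.t, 6),
                "x_mm": np.round(tr.xy[:, 0], 6),
                "y_mm": np.round(tr.xy[:, 1], 6),
            }
        )
        for tr in trajs
    ]
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=TRAJECTORY_COLUMNS)
    df.to_csv(path, index=False)


def write_annotations(anns, path) -> None:
    frames = [
        pd.DataFrame({"worm_id": a.worm_id, "t_s": np.round(a.t, 6), "state": a.state})
        for a in anns
    ]
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=ANNOTATION_COLUMNS)
    df.to_csv(path, index=False)


def read_annotations(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"worm_id": str, "state": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return df


# --- descriptive summaries -------------------------------------------------

def five_number_summary(values) -> dict[str, float]:
    """Median, quartiles (linear interpolation) and Tukey 1.5*IQR whiskers.

    Whiskers sit at the most extreme data points within 1.5*IQR of the
    quartiles; points beyond are outliers (listed, never dropped).
    """
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("cannot summarize an empty sample")
    q1, med, q3 = np.percentile(v, [25, 50, 75])  # linear interpolation
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return {
        "n": int(v.size),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(inside.min()),
        "whisker_high": float(inside.max()),
        "outliers": [float(x) for x in v[(v < lo_fence) | (v > hi_fence)]],
    }


def write_report(indices_df: pd.DataFrame, path_tsv, path_json, group_col: str | None = None) -> None:
    """Write the per-worm index table (TSV) and group summaries (JSON).

    Summaries report median, Q1, Q3 and Tukey whiskers per numeric column,
    per group when ``group_col`` is given; deterministic given the inputs.
    """
    indices_df.to_csv(path_tsv, sep="\t", index=False)
    numeric = [c for c in indices_df.columns if pd.api.types.is_numeric_dtype(indices_df[c])]
    summaries: dict = {}
    groups = indices_df.groupby(group_col) if group_col else [("all", indices_df)]
    for name, g in groups:
        entry = {}
        for col in numeric:
            vals = g[col].dropna().to_numpy()
            if vals.size:
                entry[col] = five_number_summary(vals)
        summaries[str(name)] = entry
    Path(path_json).write_text(json.dumps(summaries, indent=2))


# --- YAML configuration ----------------------------------------------------

def load_gradient(path) -> GradientSpec:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "origin_mm" in raw:
        raw["origin_mm"] = tuple(raw["origin_mm"])
    if "axis" in raw:
        raw["axis"] = tuple(raw["axis"])
    return GradientSpec(**raw)


def load_params(path, cls):
    """Instantiate a params dataclass from a YAML mapping (missing keys -> defaults)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(raw) - names
    if unknown:
        raise ValueError(f"{path}: unknown parameter(s) {sorted(unknown)} for {cls.__name__}")
    return cls(**raw)


def load_window(path) -> AnalysisWindow:
    return load_params(path, AnalysisWindow)
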