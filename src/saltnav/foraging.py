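"""Roaming/dwelling classification on food and local-search summaries off food.

On food, speed and angular speed (a path-curvature proxy) are averaged over
10 s bins and the two foraging states are separated by the line
Speed = AngularSpeed / 450 in (mm/s, deg/s) space: bins strictly above the
line are roaming, bins on or below it are dwelling. Off food, trajectories
are segmented into pause/run/turn/pirouette and summarized as per-animal
state-time fractions plus mean speed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import BehaviorAnnotation, Trajectory, STATES


@dataclass(frozen=True)
class ForagingParams:
    bin_s: float = 10.0
    line_slope: float = 1.0 / 450.0   # (mm/s) per (deg/s)
    min_track_s_on_food: float = 1200.0
    offfood_duration_s: float = 900.0

    def __post_init__(self) -> None:
        if self.bin_s <= 0 or self.line_slope <= 0:
            raise ValueError("bin_s and line_slope must be > 0")


def bin_speed_curvature(traj: Trajectory, fp: ForagingParams) -> pd.DataFrame:
    """Mean speed (mm/s) and mean angular speed (deg/s) per 10 s bin.

    Headings come from successive displacements of the (smoothed) path;
    angular speed is |wrapped heading change| / dt. Static samples have no
    heading and are skipped within their bin (a bin with no defined heading
    gets NaN angular speed). The incomplete trailing bin is dropped.
    """
    if traj.speed is None:
        raise ValueError("speed must be populated")
    dt = traj.dt
    per_bin = int(round(fp.bin_s / dt))
    n = traj.t.size
    n_bins = n // per_bin
    if n_bins < 1:
        raise ValueError("track shorter than one bin")
    disp = np.diff(traj.xy, axis=0)
    norms = np.linalg.norm(disp, axis=1)
    heading = np.arctan2(disp[:, 1], disp[:, 0])          # heading[i]: i -> i+1
    valid_h = norms > 0
    # angular speed sample aligned to sample i (i = 1 .. n-2)
    ang = np.full(n, np.nan)
    dh = heading[1:] - heading[:-1]
    dh = (dh + np.pi) % (2 * np.pi) - np.pi
    ok = valid_h[1:] & valid_h[:-1]
    ang_vals = np.degrees(np.abs(dh)) / dt
    ang[1:-1] = np.where(ok, ang_vals, np.nan)
    rows = []
    for b in range(n_bins):
        sl = slice(b * per_bin, (b + 1) * per_bin)
        a = ang[sl]
        a = a[np.isfinite(a)]
        rows.append(
            (
                float(traj.t[sl.start]),
                float(traj.speed[sl].mean()),
                float(a.mean()) if a.size else np.nan,
            )
        )
    return pd.DataFrame(rows, columns=["t_start_s", "speed_mm_s", "angular_speed_deg_s"])


def classify_roaming_dwelling(bins: pd.DataFrame, fp: ForagingParams) -> np.ndarray:
    """Per-bin label: roaming iff speed strictly above the separating line.

    Bins exactly on the line, and bins with undefined angular speed (a
    static animal), are dwelling.
    """
    speed = bins["speed_mm_s"].to_numpy(dtype=float)
    ang = bins["angular_speed_deg_s"].to_numpy(dtype=float)
    roaming = speed > ang * fp.line_slope  # NaN comparison -> False -> dwelling
    return np.where(roaming, "roaming", "dwelling")


def foraging_summary(labels: np.ndarray, bins: pd.DataFrame) -> dict:
    """Per-animal state-time fractions and per-state mean speeds.

    Fractions of roaming and dwelling sum to 1; the mean speed of an absent
    state is None.
    """
    labels = np.asarray(labels)
    n = labels.size
    if n == 0:
        raise ValueError("no bins to summarize")
    speed = bins["speed_mm_s"].to_numpy(dtype=float)
    out = {}
    for state in ("roaming", "dwelling"):
        m = labels == state
        out[f"fraction_{state}"] = float(m.sum()) / n
        out[f"mean_speed_{state}"] = float(speed[m].mean()) if m.any() else None
    return out


def local_search_summary(ann: BehaviorAnnotation, traj: Trajectory) -> dict:
    """Off-food summary: fractions of pause/run/turn/pirouette plus mean speed.

    Mean speed is over the whole track, pause samples included.
    """
    if traj.speed is None:
        raise ValueError("speed must be populated")
    out = {f"fraction_{s}": f for s, f in ann.state_fractions().items()}
    out["mean_speed"] = float(traj.speed.mean())
    return out
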