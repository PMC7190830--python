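"""Navigation indices on linear gradients and the quadrant-assay index.

Per-animal, over an analysis window (default the first 10 min after
release):

* chemotactic index = <v_g> / <s>, the mean signed velocity component along
  the gradient over the mean crawling speed; +1 is straight up-gradient;
* biased-random-walk (BRW) index = (<len run_up> - <len run_down>) /
  (<len run_up> + <len run_down>) on mean run durations per direction;
* klinotaxis index = (N_up - N_down) / (N_up + N_down) over runs that
  immediately follow a reorientation, classified by the net displacement
  along the gradient over their first 5 s; runs interrupted within 5 s are
  discarded.

Population aggregation is a separate explicit step; these functions are
per-animal. The quadrant index is (n(A) - n(C)) / (n(A) + n(C)) over animal
counts in salt vs control quadrants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import AnalysisWindow, BehaviorAnnotation, GradientSpec, Trajectory
from .segmentation import SegmentationParams


@dataclass
class NavigationIndices:
    worm_id: str
    chemotactic: float | None
    brw: float | None
    klinotaxis: float | None
    mean_pos_mm: float            # mean axis coordinate relative to release
    n_runs_up: int = 0
    n_runs_down: int = 0
    n_reorient_up: int = 0
    n_reorient_down: int = 0


def select_analysis_tracks(trajs: list[Trajectory], w: AnalysisWindow) -> list[Trajectory]:
    """Keep tracks with >= min_active_s presence inside the window, clipped.

    If several surviving tracks share a worm_id (possible for simulated
    ground truth, impossible for one live animal at one time), only the
    longest is kept, mirroring the one-track-per-animal rule.
    """
    kept: dict[str, Trajectory] = {}
    for tr in trajs:
        clip = tr.clipped(w.t_start, w.t_end)
        if clip.t.size < 2 or clip.duration_s < w.min_active_s:
            continue
        prev = kept.get(tr.worm_id)
        if prev is None or clip.duration_s > prev.duration_s:
            kept[tr.worm_id] = clip
    if not kept:
        warnings.warn("no tracks meet the analysis-window activity requirement")
    return list(kept.values())


def _axis_velocity(traj: Trajectory, g: GradientSpec) -> np.ndarray:
    """Signed per-sample velocity along the gradient axis, v[0] duplicated.

    Uses the same displacement convention as the speed so that
    |v_g| <= speed holds sample-wise and the chemotactic index is in [-1, 1].
    """
    s = g.axis_coordinate(traj.xy)
    if s.size < 2:
        return np.zeros(s.size)
    step = np.diff(s) / traj.dt
    return np.concatenate([[step[0]], step])


def chemotactic_index(
    traj: Trajectory, g: GradientSpec, w: AnalysisWindow | None = None
) -> float | None:
    """<v_g> / <s> over the (window-clipped) trajectory; None if <s> = 0."""
    if w is not None:
        traj = traj.clipped(w.t_start, w.t_end)
    if traj.t.size < 2:
        return None
    # v_g and s are means over the same displacement intervals, so
    # |v_g| <= s holds interval-wise and the index stays in [-1, 1]
    disp = np.diff(traj.xy, axis=0)
    vg = np.diff(g.axis_coordinate(traj.xy)) / traj.dt
    sp = np.linalg.norm(disp, axis=1) / traj.dt
    mean_speed = float(sp.mean())
    if mean_speed == 0:
        return None
    return float(vg.mean()) / mean_speed


def _clip_runs(runs, w: AnalysisWindow | None):
    if w is None:
        return list(runs)
    out = []
    for r in runs:
        a, b = max(r.start, w.t_start), min(r.end, w.t_end)
        if b > a:
            out.append(type(r)(a, b, r.kind))
    return out


def brw_index(ann: BehaviorAnnotation, w: AnalysisWindow | None = None) -> float | None:
    """Fractional difference of mean run duration up vs down the gradient.

    Runs clipped at window edges contribute their in-window duration; ties
    (zero net axis displacement) belong to neither direction. A direction
    with no runs contributes mean 0, so a one-sided animal scores +-1.
    Undefined (None) if the animal has no runs, or both means are zero.
    """
    runs = _clip_runs(ann.runs, w)
    if not runs:
        return None
    up = [r.duration for r in runs if r.kind == "up"]
    down = [r.duration for r in runs if r.kind == "down"]
    mean_up = float(np.mean(up)) if up else 0.0
    mean_down = float(np.mean(down)) if down else 0.0
    if mean_up + mean_down == 0:
        return None
    return (mean_up - mean_down) / (mean_up + mean_down)


def _qualifying_post_reorientation_runs(
    ann: BehaviorAnnotation,
    traj: Trajectory,
    g: GradientSpec,
    stretch_s: float,
    w: AnalysisWindow | None,
) -> tuple[int, int]:
    """Count post-reorientation runs by up/down over their first ``stretch_s``."""
    t = traj.t
    dt = traj.dt
    axis_coord = g.axis_coordinate(traj.xy)
    run_starts = {r.start: r for r in ann.runs}
    n_up = n_down = 0
    for ev in ann.reorientations:
        if w is not None and not (w.t_start <= ev.end <= w.t_end):
            continue
        run = run_starts.get(round(ev.end + dt, 9))
        if run is None:
            # tolerate float jitter in interval arithmetic
            cand = [r for r in ann.runs if abs(r.start - (ev.end + dt)) < dt / 4]
            run = cand[0] if cand else None
        if run is None or run.duration < stretch_s:
            continue  # another behavior started within the 5 s stretch
        i0 = int(np.searchsorted(t, run.start))
        i1 = int(np.searchsorted(t, run.start + stretch_s))
        if i1 >= t.size:
            continue
        net = axis_coord[i1] - axis_coord[i0]
        if net > 0:
            n_up += 1
        elif net < 0:
            n_down += 1
    return n_up, n_down


def klinotaxis_index(
    ann: BehaviorAnnotation,
    g: GradientSpec,
    traj: Trajectory,
    w: AnalysisWindow | None = None,
    sp: SegmentationParams | None = None,
) -> float | None:
    """Fractional difference of post-reorientation runs starting up vs down.

    Only runs immediately following a reorientation and lasting at least the
    5 s qualification stretch are counted, classified by the sign of net
    axis displacement over that stretch. None if no run qualifies.
    """
    stretch = (sp or SegmentationParams()).klino_stretch_s
    n_up, n_down = _qualifying_post_reorientation_runs(ann, traj, g, stretch, w)
    if n_up + n_down == 0:
        return None
    return (n_up - n_down) / (n_up + n_down)


def mean_position_trace(
    trajs: list[Trajectory], g: GradientSpec, grid: np.ndarray
) -> pd.DataFrame:
    """Population mean axis position (relative to release) +- S.E.M. on a time grid.

    A track is active at a grid time if the time lies within its span; its
    position is linearly interpolated. Grid points with no active track are
    gaps (NaN); S.E.M. with a single track is undefined (NaN).
    """
    grid = np.asarray(grid, dtype=float)
    cols = []
    for tr in trajs:
        s = g.axis_coordinate(tr.xy) - g.release_mm
        active = (grid >= tr.t[0]) & (grid <= tr.t[-1])
        col = np.full(grid.shape, np.nan)
        col[active] = np.interp(grid[active], tr.t, s)
        cols.append(col)
    mat = np.array(cols) if cols else np.empty((0, grid.size))
    n = np.sum(np.isfinite(mat), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(mat, axis=0) if cols else np.full(grid.shape, np.nan)
        sd = np.nanstd(mat, axis=0, ddof=1) if cols else np.full(grid.shape, np.nan)
    sem = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), np.nan)
    return pd.DataFrame({"t_s": grid, "mean_mm": mean, "sem_mm": sem, "n": n})


def quadrant_index(n_A: int, n_C: int) -> float:
    """(n(A) - n(C)) / (n(A) + n(C)) over quadrant animal counts."""
    if n_A < 0 or n_C < 0:
        raise ValueError("counts must be non-negative")
    if n_A + n_C == 0:
        raise ValueError("quadrant index undefined for zero total count")
    return (n_A - n_C) / (n_A + n_C)


def compute_navigation_indices(
    traj: Trajectory,
    ann: BehaviorAnnotation,
    g: GradientSpec,
    w: AnalysisWindow | None = None,
    sp: SegmentationParams | None = None,
) -> NavigationIndices:
    """All per-animal indices for one (already window-clipped or raw) track."""
    clip = traj if w is None else traj.clipped(w.t_start, w.t_end)
    runs = _clip_runs(ann.runs, w)
    n_up, n_down = _qualifying_post_reorientation_runs(
        ann, traj, g, (sp or SegmentationParams()).klino_stretch_s, w
    )
    mean_pos = float(np.mean(g.axis_coordinate(clip.xy) - g.release_mm)) if clip.t.size else float("nan")
    return NavigationIndices(
        worm_id=traj.worm_id,
        chemotactic=chemotactic_index(traj, g, w),
        brw=brw_index(ann, w),
        klinotaxis=klinotaxis_index(ann, g, traj, w, sp),
        mean_pos_mm=mean_pos,
        n_runs_up=sum(1 for r in runs if r.kind == "up"),
        n_runs_down=sum(1 for r in runs if r.kind == "down"),
        n_reorient_up=n_up,
        n_reorient_down=n_down,
    )


def indices_table(records: list[NavigationIndices]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "worm_id": r.worm_id,
                "chemotactic": np.nan if r.chemotactic is None else r.chemotactic,
                "brw": np.nan if r.brw is None else r.brw,
                "klinotaxis": np.nan if r.klinotaxis is None else r.klinotaxis,
                "mean_pos_mm": r.mean_pos_mm,
                "n_runs_up": r.n_runs_up,
                "n_runs_down": r.n_runs_down,
                "n_reorient_up": r.n_reorient_up,
                "n_reorient_down": r.n_reorient_down,
            }
            for r in records
        ]
    )
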