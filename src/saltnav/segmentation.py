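"""Rule-based behavioral-state segmentation of worm trajectories.

Each sample of a (smoothed, speed-annotated) trajectory is labeled pause,
turn, pirouette or run:

* pause — in the 10 s sliding window centered on the sample, strictly more
  than half of the samples have speed below 0.01 mm/s;
* turn core — the vertex angle at the sample, between the points 0.3 mm
  behind and ahead along the path, is strictly below 80 degrees (a straight
  path gives ~180 deg); samples after a core with speed still below
  0.1 mm/s extend the turn forward;
* pirouette — successive turns separated by gaps shorter than 3.8 s are
  bundled into one reorientation event (gap samples included);
* run — everything else. Overlaps resolve with precedence
  turn/pirouette > pause > run: a stationary post-turn sample meets both
  the pause and the post-turn criterion and belongs to the turn.

Runs carry a direction (up/down/tie) given by the sign of their net
displacement along the gradient axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import BehaviorAnnotation, GradientSpec, Interval, Trajectory, intervals_from_mask


@dataclass(frozen=True)
class SegmentationParams:
    pause_speed: float = 0.01       # mm/s
    pause_window_s: float = 10.0
    turn_arc_mm: float = 0.3
    turn_angle_deg: float = 80.0
    postturn_speed: float = 0.1     # mm/s
    pirouette_gap_s: float = 3.8
    klino_stretch_s: float = 5.0
    angle_convention: str = "vertex"  # or "complement"

    def __post_init__(self) -> None:
        vals = (self.pause_speed, self.pause_window_s, self.turn_arc_mm,
                self.turn_angle_deg, self.postturn_speed, self.pirouette_gap_s,
                self.klino_stretch_s)
        if any(v <= 0 for v in vals):
            raise ValueError("all segmentation parameters must be strictly positive")
        if self.turn_angle_deg >= 180:
            raise ValueError("turn_angle_deg must be < 180")
        if self.pause_speed >= self.postturn_speed:
            raise ValueError("pause_speed must be < postturn_speed")
        if self.angle_convention not in ("vertex", "complement"):
            raise ValueError("angle_convention must be 'vertex' or 'complement'")


def label_pauses(traj: Trajectory, sp: SegmentationParams) -> np.ndarray:
    """Per-sample pause mask: majority of the 10 s centered window below 0.01 mm/s.

    'More than half' is strict; a window with exactly half slow samples is
    not a pause. Windows truncate at the track ends.
    """
    if traj.speed is None:
        raise ValueError("speed must be populated (preprocess the trajectory first)")
    t, speed = traj.t, traj.speed
    half_w = sp.pause_window_s / 2
    slow = (speed < sp.pause_speed).astype(np.int64)
    cslow = np.concatenate([[0], np.cumsum(slow)])
    lo = np.searchsorted(t, t - half_w, side="left")
    hi = np.searchsorted(t, t + half_w, side="right")
    n_slow = cslow[hi] - cslow[lo]
    n_tot = hi - lo
    return n_slow * 2 > n_tot


def _turn_cores(traj: Trajectory, sp: SegmentationParams) -> np.ndarray:
    """Samples whose path-vertex angle over +-0.3 mm arcs marks a sharp turn."""
    xy = traj.xy
    n = xy.shape[0]
    cores = np.zeros(n, dtype=bool)
    if n < 3:
        return cores
    seg = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    # back[i]: last j with cum[i]-cum[j] >= arc; ahead[i]: first k with cum[k]-cum[i] >= arc
    back = np.searchsorted(cum, cum - sp.turn_arc_mm, side="right") - 1
    ahead = np.searchsorted(cum, cum + sp.turn_arc_mm, side="left")
    evaluable = (back >= 0) & (ahead <= n - 1)
    idx = np.flatnonzero(evaluable)
    if idx.size == 0:
        return cores
    a = xy[back[idx]] - xy[idx]
    b = xy[ahead[idx]] - xy[idx]
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    ok = (na > 0) & (nb > 0)  # a zero-length chord (path loops onto itself) is not evaluable
    cosang = np.full(idx.size, np.nan)
    cosang[ok] = np.einsum("ij,ij->i", a[ok], b[ok]) / (na[ok] * nb[ok])
    vertex_deg = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    if sp.angle_convention == "vertex":
        hit = vertex_deg < sp.turn_angle_deg
    else:  # complement: angle between incoming and outgoing displacement vectors
        hit = (180.0 - vertex_deg) < sp.turn_angle_deg
    cores[idx[ok & np.nan_to_num(hit, nan=False).astype(bool)]] = True
    return cores


def label_turns(traj: Trajectory, sp: SegmentationParams) -> tuple[np.ndarray, np.ndarray]:
    """Turn mask (cores plus forward low-speed extension) and the core mask."""
    if traj.speed is None:
        raise ValueError("speed must be populated")
    cores = _turn_cores(traj, sp)
    turn = cores.copy()
    n = turn.size
    slow = traj.speed < sp.postturn_speed
    i = 0
    while i < n:
        if turn[i]:
            j = i + 1
            while j < n and turn[j]:
                j += 1
            # extend forward over contiguous slow samples
            while j < n and slow[j] and not turn[j]:
                turn[j] = True
                j += 1
            i = j
        else:
            i += 1
    return turn, cores


def bundle_pirouettes(
    turn_intervals: list[Interval], sp: SegmentationParams
) -> list[Interval]:
    """Merge chains of turns with successive gaps < 3.8 s into pirouettes.

    Returns reorientation events ordered in time, kind 'turn' for isolated
    turns and 'pirouette' for bundles (which span first start to last end,
    gaps included).
    """
    events: list[Interval] = []
    i = 0
    n = len(turn_intervals)
    while i < n:
        j = i
        while j + 1 < n and turn_intervals[j + 1].start - turn_intervals[j].end < sp.pirouette_gap_s:
            j += 1
        if j == i:
            events.append(Interval(turn_intervals[i].start, turn_intervals[i].end, "turn"))
        else:
            events.append(Interval(turn_intervals[i].start, turn_intervals[j].end, "pirouette"))
        i = j + 1
    return events


def segment_trajectory(
    traj: Trajectory, sp: SegmentationParams, g: GradientSpec
) -> BehaviorAnnotation:
    """Label every sample and derive run and reorientation events."""
    t = traj.t
    turn_mask, _ = label_turns(traj, sp)
    pause_mask = label_pauses(traj, sp)
    turn_intervals = intervals_from_mask(t, turn_mask, "turn")
    events = bundle_pirouettes(turn_intervals, sp)

    state = np.full(t.shape, "run", dtype=object)
    state[pause_mask] = "pause"
    for ev in events:
        state[(t >= ev.start) & (t <= ev.end)] = ev.kind  # precedence over pause

    run_intervals = intervals_from_mask(t, state == "run", "run")
    axis_coord = g.axis_coordinate(traj.xy)
    runs: list[Interval] = []
    for iv in run_intervals:
        i0 = int(np.searchsorted(t, iv.start))
        i1 = int(np.searchsorted(t, iv.end))
        net = axis_coord[i1] - axis_coord[i0]
        direction = "up" if net > 0 else ("down" if net < 0 else "tie")
        runs.append(Interval(iv.start, iv.end, direction))
    return BehaviorAnnotation(
        worm_id=traj.worm_id, t=t, state=state,
        runs=runs, reorientations=events, params_used=sp,
    )
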