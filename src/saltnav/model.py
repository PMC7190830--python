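"""Shared data model for salt-chemotaxis analysis.

Coordinates live in the arena frame, in millimeters, with the NaCl gradient
along +y by default. Time grids are uniform at 2 frames per second
(dt = 0.5 s); all windowed rules downstream assume this uniform grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

#: Default sampling interval in seconds (2 frames per second).
DT_S = 0.5

#: Behavioral state labels used throughout.
STATES = ("run", "pause", "turn", "pirouette")


class TrajectorySource(str, Enum):
    SIMULATED = "simulated"
    TRACKED = "tracked"
    IMPORTED = "imported"


@dataclass(frozen=True)
class GradientSpec:
    """Linear concentration gradient across the arena.

    The axis coordinate of a point ``p`` is ``(p - origin_mm) . axis``;
    concentration is affine in that coordinate and clamped to
    ``[c_min, c_max]`` outside ``[0, length_mm]``. ``release_mm`` is the
    axis coordinate where animals are placed (the gradient midpoint for
    the standard 0-100 mM square-plate assay, corresponding to ~50 mM).
    """

    origin_mm: tuple[float, float] = (0.0, 0.0)
    axis: tuple[float, float] = (0.0, 1.0)
    c_min: float = 0.0
    c_max: float = 100.0
    length_mm: float = 120.0
    release_mm: float = 60.0

    def __post_init__(self) -> None:
        ax = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(ax)
        if not np.isclose(n, 1.0):
            raise ValueError(f"axis must have unit norm, got |axis| = {n:.6g}")
        if self.c_max < self.c_min:
            raise ValueError("c_max must be >= c_min")
        if self.length_mm <= 0:
            raise ValueError("length_mm must be > 0")

    def axis_coordinate(self, p) -> np.ndarray:
        """Signed coordinate(s) of position(s) ``p`` (mm) along the gradient axis."""
        p = np.asarray(p, dtype=float)
        rel = p - np.asarray(self.origin_mm)
        return rel @ np.asarray(self.axis)

    def concentration_at(self, p) -> np.ndarray:
        """NaCl concentration (mM) at arena position(s) ``p`` (mm), clamped."""
        s = self.axis_coordinate(p)
        frac = np.clip(s / self.length_mm, 0.0, 1.0)
        return self.c_min + (self.c_max - self.c_min) * frac

    def reversed(self) -> "GradientSpec":
        """Gradient with the axis direction flipped (down becomes up)."""
        ax = -np.asarray(self.axis)
        return GradientSpec(
            origin_mm=self.origin_mm,
            axis=(float(ax[0]), float(ax[1])),
            c_min=self.c_min,
            c_max=self.c_max,
            length_mm=self.length_mm,
            release_mm=-self.release_mm,
        )


@dataclass
class Trajectory:
    """A single animal's time-stamped centroid path.

    ``t`` is a strictly increasing, uniform time grid in seconds; ``xy``
    holds positions in mm (rows aligned with ``t``). ``speed`` (mm/s) is
    populated by :func:`saltnav.tracking.derive_speed` after smoothing and
    is ``None`` until then.
    """

    worm_id: str
    t: np.ndarray
    xy: np.ndarray
    speed: np.ndarray | None = None
    source: TrajectorySource = TrajectorySource.IMPORTED

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.t.ndim != 1 or self.xy.shape != (self.t.size, 2):
            raise ValueError("t must be 1-D and xy must be (len(t), 2)")
        if self.t.size >= 2:
            dts = np.diff(self.t)
            if np.any(dts <= 0):
                raise ValueError(f"time must be strictly increasing (worm {self.worm_id})")
            if not np.allclose(dts, dts[0], rtol=0, atol=1e-6):
                raise ValueError(f"time grid must be uniform (worm {self.worm_id})")
        if not np.all(np.isfinite(self.xy)):
            raise ValueError(f"xy contains non-finite values (worm {self.worm_id})")
        if self.speed is not None:
            self.speed = np.asarray(self.speed, dtype=float)
            if self.speed.shape != self.t.shape:
                raise ValueError("speed must have the same length as t")
            if np.any(self.speed < 0):
                raise ValueError("speed must be non-negative")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if self.t.size >= 2 else DT_S

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0]) if self.t.size else 0.0

    def clipped(self, t_start: float, t_end: float) -> "Trajectory":
        """Sub-trajectory restricted to samples with t_start <= t <= t_end."""
        m = (self.t >= t_start) & (self.t <= t_end)
        return Trajectory(
            worm_id=self.worm_id,
            t=self.t[m],
            xy=self.xy[m],
            speed=None if self.speed is None else self.speed[m],
            source=self.source,
        )


@dataclass(frozen=True)
class AnalysisWindow:
    """Time interval over which navigation indices are computed.

    Defaults follow the standard gradient assay: the first 10 min after
    release, requiring at least 5 min of track presence inside the window
    (shorter tracks are discarded, which also prevents multiple tracks from
    one animal entering the analysis).
    """

    t_start: float = 0.0
    t_end: float = 600.0
    min_active_s: float = 300.0

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError("t_end must be > t_start")
        if self.min_active_s > self.t_end - self.t_start:
            raise ValueError("min_active_s cannot exceed the window length")


#: Window preset for single-worm stage-tracking assays (5 min, min 2.5 min).
OPTOGENETIC_WINDOW = AnalysisWindow(t_start=0.0, t_end=300.0, min_active_s=150.0)


@dataclass(frozen=True)
class Interval:
    """Closed time interval [start, end] with an associated kind/direction."""

    start: float
    end: float
    kind: str

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class BehaviorAnnotation:
    """Per-sample behavioral state labels plus derived events.

    ``state`` assigns each trajectory sample one of run/pause/turn/pirouette.
    ``runs`` are maximal run intervals with direction up/down/tie along the
    gradient; ``reorientations`` are maximal turn-or-pirouette intervals.
    """

    worm_id: str
    t: np.ndarray
    state: np.ndarray  # dtype=object or <U9, values in STATES
    runs: list[Interval] = field(default_factory=list)
    reorientations: list[Interval] = field(default_factory=list)
    params_used: object | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.state = np.asarray(self.state)
        if self.state.shape != self.t.shape:
            raise ValueError("state must cover exactly the trajectory's samples")
        bad = set(np.unique(self.state)) - set(STATES)
        if bad:
            raise ValueError(f"unknown state labels: {bad}")

    def state_fractions(self) -> dict[str, float]:
        n = self.t.size
        return {s: float(np.sum(self.state == s)) / n for s in STATES}


def intervals_from_mask(t: np.ndarray, mask: np.ndarray, kind: str) -> list[Interval]:
    """Maximal contiguous True stretches of ``mask`` as time intervals."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    return [Interval(float(t[a]), float(t[b]), kind) for a, b in zip(starts, ends)]


def regrid_uniform(t: np.ndarray, xy: np.ndarray, dt: float = DT_S):
    """Snap samples to the nearest node of a uniform dt grid, warning on moves.

    Imported trajectories whose timestamps deviate from the uniform 2 Hz grid
    are regridded by nearest-sample assignment; duplicate assignments keep the
    closest original sample.
    """
    t = np.asarray(t, dtype=float)
    xy = np.asarray(xy, dtype=float)
    t0 = t[0]
    idx = np.round((t - t0) / dt).astype(int)
    snapped = t0 + idx * dt
    if not np.allclose(snapped, t, atol=1e-6):
        warnings.warn("non-uniform time grid: regridding to nearest 0.5 s sample")
    # keep the closest sample when several map to one grid node
    order = np.argsort(np.abs(t - snapped), kind="stable")
    seen: dict[int, int] = {}
    for j in order:
        seen.setdefault(int(idx[j]), int(j))
    kept = sorted(seen.items())
    grid_idx = np.array([k for k, _ in kept])
    src = np.array([j for _, j in kept])
    return t0 + grid_idx * dt, xy[src]
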