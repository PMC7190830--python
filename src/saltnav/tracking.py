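"""Image-stack to trajectory conversion.

Worms are dark blobs on a bright arena: detection is average background
subtraction (per-pixel mean over the stack), Gaussian smoothing of the
foreground, intensity thresholding, connected components with a
single-animal size gate, and intensity-weighted centroids. Linking is
greedy mutual-nearest-neighbor between adjacent frames; tracks terminate on
collision, ambiguity, a missing detection (no gap bridging) or contact with
the arena border. Surviving tracks shorter than 5 min are discarded; the
rest are smoothed with a 1.5 s moving average before computing speed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

from .model import DT_S, Trajectory, TrajectorySource


@dataclass(frozen=True)
class TrackingParams:
    gaussian_sigma_px: float = 1.5
    threshold: float = 20.0           # cut on the background-subtracted image
    area_min_px: int = 4
    area_max_px: int = 400
    link_max_px: float = 10.0
    min_track_s: float = 300.0
    smooth_window_s: float = 1.5
    px_per_mm: float = 4.0
    dark_worms: bool = True           # foreground = background - frame
    border_margin_px: float | None = None  # None -> 2 x blob-radius estimate

    def __post_init__(self) -> None:
        if self.area_min_px >= self.area_max_px:
            raise ValueError("area_min_px must be < area_max_px")
        if self.link_max_px <= 0 or self.px_per_mm <= 0:
            raise ValueError("link_max_px and px_per_mm must be > 0")
        if self.min_track_s < 0 or self.smooth_window_s < 0:
            raise ValueError("min_track_s and smooth_window_s must be >= 0")


@dataclass(frozen=True)
class Detection:
    frame_index: int
    centroid_px: tuple[float, float]  # (x = column, y = row)
    area_px: int


@dataclass
class RawTrack:
    """A linked chain of detections in pixel coordinates."""

    frames: list[int] = field(default_factory=list)
    centroids: list[tuple[float, float]] = field(default_factory=list)
    areas: list[int] = field(default_factory=list)

    def append(self, det: Detection) -> None:
        self.frames.append(det.frame_index)
        self.centroids.append(det.centroid_px)
        self.areas.append(det.area_px)


def detect_blobs(frames: np.ndarray, tp: TrackingParams) -> list[list[Detection]]:
    """Per-frame worm detections from a grayscale stack (n_frames, H, W)."""
    frames = np.asarray(frames)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("need a stack of >= 2 frames (background is the stack mean)")
    background = frames.mean(axis=0, dtype=np.float64)
    if np.ptp(frames) == 0:
        warnings.warn("constant image stack: no detections possible")
        return [[] for _ in range(frames.shape[0])]
    out: list[list[Detection]] = []
    for i in range(frames.shape[0]):
        fg = background - frames[i].astype(np.float64) if tp.dark_worms \
            else frames[i].astype(np.float64) - background
        np.clip(fg, 0, None, out=fg)
        fg = ndimage.gaussian_filter(fg, tp.gaussian_sigma_px)
        labels = measure.label(fg > tp.threshold, connectivity=2)
        dets = []
        for rp in measure.regionprops(labels, intensity_image=fg):
            if not (tp.area_min_px <= rp.area <= tp.area_max_px):
                continue
            cy, cx = rp.centroid_weighted
            dets.append(Detection(frame_index=i, centroid_px=(float(cx), float(cy)), area_px=int(rp.area)))
        out.append(dets)
    return out


def _estimate_border_margin(detections, tp: TrackingParams) -> float:
    if tp.border_margin_px is not None:
        return tp.border_margin_px
    areas = [d.area_px for dets in detections for d in dets]
    if not areas:
        return 0.0
    radius = np.sqrt(np.median(areas) / np.pi)
    return 2.0 * float(radius)


def link_tracks(
    detections: list[list[Detection]],
    tp: TrackingParams,
    frame_shape: tuple[int, int] | None = None,
) -> list[RawTrack]:
    """Greedy mutual-nearest-neighbor linking of detections into tracks.

    A track ends when its detection disappears, when two tracks claim one
    detection (collision), when two detections are equidistant (ambiguity is
    terminated, never guessed), or when the centroid enters the border
    margin. Unmatched detections start new tracks.
    """
    margin = _estimate_border_margin(detections, tp)

    def near_border(c: tuple[float, float]) -> bool:
        if frame_shape is None or margin <= 0:
            return False
        h, w = frame_shape
        x, y = c
        return x < margin or y < margin or x > w - 1 - margin or y > h - 1 - margin

    finished: list[RawTrack] = []
    active: list[RawTrack] = []
    for d in detections[0] if detections else []:
        tr = RawTrack()
        tr.append(d)
        active.append(tr)

    for f in range(1, len(detections)):
        dets = detections[f]
        nxt_active: list[RawTrack] = []
        claims: dict[int, list[int]] = {}
        matches: dict[int, int] = {}
        if active and dets:
            last = np.array([tr.centroids[-1] for tr in active])
            cur = np.array([d.centroid_px for d in dets])
            dist = np.linalg.norm(last[:, None, :] - cur[None, :, :], axis=2)
            for ti in range(len(active)):
                row = dist[ti]
                j = int(np.argmin(row))
                if row[j] > tp.link_max_px:
                    continue
                if np.sum(np.isclose(row, row[j], rtol=0, atol=1e-9)) > 1:
                    continue  # ambiguous: terminate rather than guess
                claims.setdefault(j, []).append(ti)
            for j, tis in claims.items():
                if len(tis) > 1:
                    continue  # collision: every claimant terminates
                ti = tis[0]
                col = dist[:, j]
                if np.sum(np.isclose(col, col.min(), rtol=0, atol=1e-9)) > 1:
                    continue  # detection equidistant to two tracks: terminate
                if int(np.argmin(col)) != ti:
                    continue  # not mutual: the nearer track claimed elsewhere
                matches[ti] = j
        matched_dets = set(matches.values())
        for ti, tr in enumerate(active):
            if ti in matches:
                d = dets[matches[ti]]
                if near_border(d.centroid_px):
                    finished.append(tr)  # terminates at the border
                else:
                    tr.append(d)
                    nxt_active.append(tr)
            else:
                finished.append(tr)
        for j, d in enumerate(dets):
            if j not in matched_dets and not near_border(d.centroid_px):
                tr = RawTrack()
                tr.append(d)
                nxt_active.append(tr)
        active = nxt_active
    finished.extend(active)
    return finished


# --- smoothing and speed -----------------------------------------------------

def moving_average_path(xy: np.ndarray, window_samples: int) -> np.ndarray:
    """Centered moving average with symmetric shrinking at the track ends.

    The half-window shrinks near the ends so the window stays symmetric
    about each sample; an affine (constant-velocity) path is therefore
    reproduced exactly everywhere, including the endpoints.
    """
    xy = np.asarray(xy, dtype=float)
    n = xy.shape[0]
    half = max(0, (int(window_samples) - 1) // 2)
    if half == 0 or n < 2:
        return xy.copy()
    csum = np.vstack([np.zeros((1, 2)), np.cumsum(xy, axis=0)])
    idx = np.arange(n)
    k = np.minimum(np.minimum(idx, n - 1 - idx), half)
    lo, hi = idx - k, idx + k + 1
    return (csum[hi] - csum[lo]) / (hi - lo)[:, None]


def derive_speed(xy: np.ndarray, dt: float) -> np.ndarray:
    """Instantaneous centroid speed |dxy|/dt, with speed[0] duplicated."""
    xy = np.asarray(xy, dtype=float)
    if xy.shape[0] < 2:
        return np.zeros(xy.shape[0])
    step = np.linalg.norm(np.diff(xy, axis=0), axis=1) / dt
    return np.concatenate([[step[0]], step])


def preprocess_trajectory(traj: Trajectory, smooth_window_s: float = 1.5) -> Trajectory:
    """Smooth a trajectory's path and populate its speed (positions in mm)."""
    w = max(1, int(round(smooth_window_s / traj.dt)))
    if w % 2 == 0:
        w += 1
    sm = moving_average_path(traj.xy, w)
    return Trajectory(
        worm_id=traj.worm_id, t=traj.t, xy=sm,
        speed=derive_speed(sm, traj.dt), source=traj.source,
    )


def preprocess_track(raw: RawTrack, tp: TrackingParams, dt: float = DT_S) -> Trajectory | None:
    """Convert a raw pixel track to a smoothed mm Trajectory with speed.

    Returns None for tracks shorter than ``min_track_s`` or shorter than the
    smoothing window.
    """
    n = len(raw.frames)
    duration = (n - 1) * dt if n else 0.0
    w_samples = max(1, int(round(tp.smooth_window_s / dt)))
    if duration < tp.min_track_s or n < w_samples:
        return None
    t = np.asarray(raw.frames, dtype=float) * dt
    xy_mm = np.asarray(raw.centroids, dtype=float) / tp.px_per_mm
    traj = Trajectory(
        worm_id=f"track{raw.frames[0]:05d}_{id(raw) & 0xffff:04x}",
        t=t, xy=xy_mm, source=TrajectorySource.TRACKED,
    )
    return preprocess_trajectory(traj, tp.smooth_window_s)


def track_stack(frames: np.ndarray, tp: TrackingParams) -> list[Trajectory]:
    """Full tracking pipeline: detect, link, filter and preprocess."""
    dets = detect_blobs(frames, tp)
    raw = link_tracks(dets, tp, frame_shape=frames.shape[1:])
    out = []
    for i, r in enumerate(raw):
        tr = preprocess_track(r, tp)
        if tr is not None:
            tr.worm_id = f"track{i:04d}"
            out.append(tr)
    return out
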