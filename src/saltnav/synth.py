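"""Synthetic-data generators: run-and-tumble worms, rendered video, calcium
traces and concentration-response tables.

The locomotion simulator is a continuous-time run/turn/pause state machine
sampled at 2 Hz. Two navigation biases are built in, mirroring the two
strategies worms use on salt gradients:

* biased random walk (``brw_bias``, beta): the per-step probability of
  terminating a run is ``run_rate_hz * dt * (1 - beta * cos(phi))`` where
  ``phi`` is the angle between the heading and the up-gradient axis, so runs
  pointed up the gradient last longer when beta > 0;
* klinotaxis (``klinotaxis_bias``, kappa): after a reorientation the new
  heading falls in the up-gradient half-circle with probability
  ``(1 + kappa) / 2``, uniform within the chosen half.

All generators are pure functions of (params, seed). Per-worm seeds derive
from the master seed by the counter scheme ``SeedSequence((seed, worm_index))``
so populations are reproducible under reordering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

from .model import DT_S, GradientSpec, Trajectory, TrajectorySource
from .physiology import CalciumTrace


# --- locomotion --------------------------------------------------------------

@dataclass(frozen=True)
class LocomotionParams:
    """Tunable parameters of the run-and-tumble worm model.

    Defaults are typical of young-adult crawling off food: ~0.12 mm/s runs
    lasting ~20 s on average, occasional pauses of a few seconds, and
    reorientations that are single turns or multi-turn pirouette bursts.
    """

    speed_mean: float = 0.12          # mm/s, truncated-normal run speed
    speed_sd: float = 0.03            # mm/s
    run_rate_hz: float = 0.05         # baseline run-termination rate lambda0
    brw_bias: float = 0.0             # beta in [-1, 1]
    klinotaxis_bias: float = 0.0      # kappa in [-1, 1]
    pirouette_prob: float = 0.3       # P(reorientation is a 2-4 turn burst)
    pause_rate_hz: float = 0.01       # pause initiation rate during runs
    pause_mean_s: float = 4.0         # exponential pause duration
    turn_dwell_s: float = 2.0         # duration of the low-speed turn core
    turn_speed: float = 0.04          # mm/s crawl during a turn core
    heading_noise_deg: float = 10.0   # per-step wrapped-Gaussian jitter

    def __post_init__(self) -> None:
        if self.speed_mean <= 0 or self.run_rate_hz <= 0 or self.pause_rate_hz <= 0:
            raise ValueError("speed_mean and rates must be > 0")
        if not (abs(self.brw_bias) <= 1 and abs(self.klinotaxis_bias) <= 1):
            raise ValueError("|brw_bias| and |klinotaxis_bias| must be <= 1")
        if not 0 <= self.pirouette_prob <= 1:
            raise ValueError("pirouette_prob must be in [0, 1]")


@dataclass
class SimulatedTrack:
    """A simulated trajectory together with its ground-truth state labels."""

    trajectory: Trajectory
    states: np.ndarray  # per-sample label in {run, pause, turn, pirouette}


def _wrap_angle(a: float) -> float:
    return (a + np.pi) % (2 * np.pi) - np.pi


def _reflect(x: float, lo: float, hi: float) -> float:
    span = hi - lo
    y = (x - lo) % (2 * span)
    return lo + (span - abs(y - span))


def simulate_worm(
    params: LocomotionParams,
    g: GradientSpec,
    duration_s: float,
    rng: np.random.Generator,
    worm_id: str = "sim0",
    arena_width_mm: float | None = None,
    boundary: str = "reflect",
) -> SimulatedTrack:
    """Simulate one worm on the gradient; see the module docstring for the model.

    ``boundary`` is "reflect" (default) or "truncate"; truncation ends the
    track when the worm reaches the arena edge (as a real tracker would).
    """
    dt = DT_S
    if params.run_rate_hz * dt * (1 + abs(params.brw_bias)) > 1:
        warnings.warn("run termination probability clamped: run_rate_hz too high for dt")
    n = int(round(duration_s / dt)) + 1
    ax = np.asarray(g.axis, dtype=float)
    perp = np.array([-ax[1], ax[0]])
    width = arena_width_mm if arena_width_mm is not None else g.length_mm
    origin = np.asarray(g.origin_mm, dtype=float)
    up_angle = float(np.arctan2(ax[1], ax[0]))

    # axis/transverse coordinates; arena is [0, length] x [-w/2, w/2]
    s = float(g.release_mm)
    u = 0.0
    heading = float(rng.uniform(-np.pi, np.pi))

    xy = np.empty((n, 2))
    states = np.empty(n, dtype=object)

    STATE_RUN, STATE_PAUSE, STATE_TURN = 0, 1, 2
    state = STATE_RUN
    timer = 0.0            # remaining time in pause or turn core
    turns_left = 0         # further turn cores in the current pirouette burst
    gap_left = 0.0         # remaining inter-turn gap inside a pirouette
    in_pirouette = False
    noise_sd = np.deg2rad(params.heading_noise_deg)
    half = np.pi / 2

    def new_heading() -> float:
        up = rng.random() < (1 + params.klinotaxis_bias) / 2
        base = up_angle if up else up_angle + np.pi
        return _wrap_angle(base + rng.uniform(-half, half))

    n_samples = n
    for i in range(n):
        xy[i] = origin + s * ax + u * perp
        if state == STATE_PAUSE:
            states[i] = "pause"
        elif state == STATE_TURN or (in_pirouette and gap_left > 0):
            states[i] = "pirouette" if in_pirouette else "turn"
        else:
            states[i] = "run"

        # advance dynamics to the next sample
        if state == STATE_PAUSE:
            timer -= dt
            u += rng.normal(0, 5e-4)
            if timer <= 0:
                state = STATE_RUN
        elif state == STATE_TURN:
            # slow isotropic jiggle during the turn core
            step = params.turn_speed * dt
            ang = rng.uniform(-np.pi, np.pi)
            s += step * np.cos(ang - up_angle)
            u += step * np.sin(ang - up_angle)
            timer -= dt
            if timer <= 0:
                heading = new_heading()
                if turns_left > 0:
                    gap_left = rng.uniform(0.5, 3.5)  # < pirouette bundling gap
                    state = STATE_RUN
                else:
                    in_pirouette = False
                    state = STATE_RUN
        else:  # running (possibly inside a pirouette gap)
            speed = max(0.0, rng.normal(params.speed_mean, params.speed_sd))
            heading = _wrap_angle(heading + rng.normal(0, noise_sd))
            step = speed * dt
            s += step * np.cos(heading - up_angle)
            u += step * np.sin(heading - up_angle)
            if in_pirouette and gap_left > 0:
                gap_left -= dt
                if gap_left <= 0:
                    turns_left -= 1
                    state = STATE_TURN
                    timer = params.turn_dwell_s
            else:
                if rng.random() < params.pause_rate_hz * dt:
                    state = STATE_PAUSE
                    timer = rng.exponential(params.pause_mean_s)
                else:
                    phi = heading - up_angle
                    p_term = np.clip(
                        params.run_rate_hz * dt * (1 - params.brw_bias * np.cos(phi)), 0, 1
                    )
                    if rng.random() < p_term:
                        state = STATE_TURN
                        timer = params.turn_dwell_s
                        if rng.random() < params.pirouette_prob:
                            in_pirouette = True
                            turns_left = int(rng.integers(1, 4))  # 2-4 cores total
                        else:
                            in_pirouette = False
                            turns_left = 0

        # boundaries in gradient coordinates
        if boundary == "reflect":
            s = _reflect(s, 0.0, g.length_mm)
            u = _reflect(u, -width / 2, width / 2)
        else:  # truncate
            if not (0.0 <= s <= g.length_mm and -width / 2 <= u <= width / 2):
                n_samples = i + 1
                break

    t = np.arange(n_samples) * dt
    traj = Trajectory(worm_id=worm_id, t=t, xy=xy[:n_samples], source=TrajectorySource.SIMULATED)
    return SimulatedTrack(trajectory=traj, states=states[:n_samples])


def simulate_population(
    params: LocomotionParams,
    g: GradientSpec,
    n_worms: int,
    duration_s: float,
    seed: int,
    arena_width_mm: float | None = None,
    boundary: str = "reflect",
) -> list[SimulatedTrack]:
    """Simulate ``n_worms`` independent worms released at the gradient's release point."""
    if n_worms < 1:
        raise ValueError("n_worms must be >= 1")
    if duration_s < 60:
        raise ValueError("duration_s must be >= 60")
    out = []
    for i in range(n_worms):
        rng = np.random.default_rng(np.random.SeedSequence((seed, i)))
        out.append(
            simulate_worm(
                params, g, duration_s, rng,
                worm_id=f"sim{i:04d}", arena_width_mm=arena_width_mm, boundary=boundary,
            )
        )
    return out


def grid_population(
    params: LocomotionParams,
    n_worms: int,
    duration_s: float,
    seed: int,
    cell_mm: float = 20.0,
    pad_mm: float = 5.0,
    n_cols: int = 2,
) -> list[Trajectory]:
    """Simulate worms confined to separate grid cells so they never collide.

    Each worm runs in its own reflecting ``cell_mm`` x ``cell_mm`` arena and
    is then translated into a padded grid — a guaranteed-collision-free scene
    for tracker fidelity tests. Returns plain trajectories (arena mm).
    """
    pitch = cell_mm + pad_mm
    gcell = GradientSpec(length_mm=cell_mm, release_mm=cell_mm / 2)
    out = []
    for i in range(n_worms):
        rng = np.random.default_rng(np.random.SeedSequence((seed, i)))
        sim = simulate_worm(params, gcell, duration_s, rng,
                            worm_id=f"grid{i:03d}", arena_width_mm=cell_mm)
        col, row = i % n_cols, i // n_cols
        xy = sim.trajectory.xy.copy()
        xy[:, 0] += pad_mm + col * pitch + cell_mm / 2  # transverse coord is centered
        xy[:, 1] += pad_mm + row * pitch
        out.append(Trajectory(worm_id=sim.trajectory.worm_id, t=sim.trajectory.t,
                              xy=xy, source=TrajectorySource.SIMULATED))
    return out


# --- video rendering ---------------------------------------------------------

@dataclass(frozen=True)
class RenderParams:
    """Rendering of dark worm blobs on a bright, noisy arena image."""

    px_per_mm: float = 4.0
    worm_blob_sigma_px: float = 2.0
    worm_intensity: float = 120.0     # peak darkening below background
    background_level: float = 200.0
    noise_sd: float = 0.0
    frame_size_px: tuple[int, int] = (480, 480)  # (rows, cols)

    def __post_init__(self) -> None:
        if self.px_per_mm <= 0:
            raise ValueError("px_per_mm must be > 0")
        if min(self.frame_size_px) <= 0:
            raise ValueError("frame_size_px must be positive")
        if not (0 <= self.background_level <= 255 and 0 <= self.worm_intensity <= 255):
            raise ValueError("intensities must fit the uint8 range")


def render_frames(
    trajs: list[Trajectory],
    rp: RenderParams,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render trajectories as a uint8 frame stack plus a ground-truth table.

    Pixel convention: column = x_mm * px_per_mm, row = y_mm * px_per_mm.
    Overlapping worms render as merged (summed) darkening — a tracker test
    case, not an error. Returns (frames, truth) where truth has columns
    frame, worm_id, x_px, y_px.
    """
    rng = np.random.default_rng(seed)
    h, w = rp.frame_size_px
    n_frames = max((tr.t.size for tr in trajs), default=0)
    frames = np.empty((n_frames, h, w), dtype=np.uint8)
    sigma = rp.worm_blob_sigma_px
    r = int(np.ceil(4 * sigma))
    rows = []
    for f in range(n_frames):
        img = np.full((h, w), rp.background_level, dtype=np.float64)
        for tr in trajs:
            if f >= tr.t.size:
                continue
            cx = tr.xy[f, 0] * rp.px_per_mm
            cy = tr.xy[f, 1] * rp.px_per_mm
            if not (0 <= cx < w and 0 <= cy < h):
                raise ValueError(f"worm {tr.worm_id} outside the rendered arena at frame {f}")
            rows.append((f, tr.worm_id, cx, cy))
            c0, c1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
            r0, r1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
            yy, xx = np.mgrid[r0:r1, c0:c1]
            img[r0:r1, c0:c1] -= rp.worm_intensity * np.exp(
                -((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2)
            )
        if rp.noise_sd > 0:
            img += rng.normal(0, rp.noise_sd, img.shape)
        frames[f] = np.clip(np.round(img), 0, 255).astype(np.uint8)
    truth = pd.DataFrame(rows, columns=["frame", "worm_id", "x_px", "y_px"])
    return frames, truth


def write_frames(frames: np.ndarray, path) -> None:
    tifffile.imwrite(path, frames)


def read_frames(path) -> np.ndarray:
    return tifffile.imread(path)


# --- calcium traces ----------------------------------------------------------

def _response_kernel(t: np.ndarray, onset: float, offset: float, shape: str,
                     rise_s: float, decay_s: float) -> np.ndarray:
    """Unit-peak stimulus-response kernel starting at the stimulus onset."""
    k = np.zeros_like(t)
    if shape == "step":
        k[(t >= onset) & (t < offset)] = 1.0
    elif shape == "double_exp":
        tt = t - onset
        m = tt >= 0
        k[m] = (1 - np.exp(-tt[m] / rise_s)) * np.exp(-tt[m] / decay_s)
        peak = k.max()
        if peak > 0:
            k /= peak  # unit peak on the sampled grid
    else:
        raise ValueError(f"unknown kernel shape {shape!r}")
    return k


def simulate_calcium(
    amplitude_pct: float,
    stim_interval: tuple[float, float] = (10.0, 40.0),
    baseline: float = 100.0,
    bg_level: float = 10.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    duration_s: float = 70.0,
    dt: float = 0.1,
    kernel: str = "double_exp",
    rise_s: float = 2.0,
    decay_s: float = 12.0,
) -> CalciumTrace:
    """Single-channel fluorescence trace with a step stimulus response.

    F(t) = bg_level + baseline * (1 + amplitude_pct/100 * kernel(t)) + noise,
    so with zero noise the peak of the background-corrected dF/F0 trace is
    exactly ``amplitude_pct``.
    """
    onset, offset = stim_interval
    if not (0 < onset < offset <= duration_s):
        raise ValueError("stim interval must lie inside the trace span")
    if not baseline > bg_level >= 0:
        raise ValueError("need baseline > bg_level >= 0")
    rng = np.random.default_rng(seed)
    t = np.arange(0, duration_s + dt / 2, dt)
    k = _response_kernel(t, onset, offset, kernel, rise_s, decay_s)
    f = bg_level + baseline * (1 + amplitude_pct / 100 * k)
    if noise_sd > 0:
        f = f + rng.normal(0, noise_sd, t.shape)
    return CalciumTrace(
        t=t, channels={"F": f}, background=float(bg_level),
        stim_onset_s=onset, pre_window_s=10.0,
    )


def simulate_calcium_fret(
    yfp_pct: float,
    cfp_pct: float,
    stim_interval: tuple[float, float] = (10.0, 40.0),
    yfp_baseline: float = 150.0,
    cfp_baseline: float = 100.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    duration_s: float = 70.0,
    dt: float = 0.1,
    kernel: str = "step",
    rise_s: float = 2.0,
    decay_s: float = 12.0,
) -> CalciumTrace:
    """Anti-correlated CFP/YFP pair for a ratiometric (FRET) indicator.

    YFP changes by ``yfp_pct`` percent and CFP by ``cfp_pct`` percent at the
    response peak (pass opposite signs for the usual anti-correlated pair);
    the peak ratio change is then (1 + yfp/100)/(1 + cfp/100) - 1.
    """
    onset, offset = stim_interval
    rng = np.random.default_rng(seed)
    t = np.arange(0, duration_s + dt / 2, dt)
    k = _response_kernel(t, onset, offset, kernel, rise_s, decay_s)
    yfp = yfp_baseline * (1 + yfp_pct / 100 * k)
    cfp = cfp_baseline * (1 + cfp_pct / 100 * k)
    if noise_sd > 0:
        yfp = yfp + rng.normal(0, noise_sd, t.shape)
        cfp = cfp + rng.normal(0, noise_sd, t.shape)
    return CalciumTrace(
        t=t, channels={"CFP": cfp, "YFP": yfp}, background=0.0,
        stim_onset_s=onset, pre_window_s=10.0,
    )


# --- concentration-response tables -------------------------------------------

#: Half-log concentration series spanning the screened range, 0.1 nM - 100 uM.
DEFAULT_CONCENTRATIONS_M = tuple(float(c) for c in np.logspace(-10, -4, 13))


def four_param_logistic(log10_c, bottom, top, log_ec50, hill):
    """y = bottom + (top - bottom) / (1 + 10**((log_ec50 - log10_c) * hill))."""
    return bottom + (top - bottom) / (1 + 10 ** ((log_ec50 - log10_c) * hill))


def simulate_dose_response(
    logistic: dict,
    concentrations=DEFAULT_CONCENTRATIONS_M,
    n_replicates: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
    lysis_scale: float = 1e6,
) -> pd.DataFrame:
    """Per-well ligand/lysis luminescence from a four-parameter logistic.

    ``logistic`` supplies bottom, top, log_ec50 (log10 molar) and hill on the
    normalized-response scale (ligand / (ligand + lysis), in (0, 1)). Noise is
    added to the normalized response; the raw luminescence pair is emitted
    consistently so that ligand/(ligand+lysis) reproduces the noisy value.
    """
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be > 0")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        y = four_param_logistic(
            np.log10(conc), logistic["bottom"], logistic["top"],
            logistic["log_ec50"], logistic["hill"],
        )
        if noise_sd > 0:
            y = y + rng.normal(0, noise_sd, y.shape)
        y = np.clip(y, 1e-9, 1 - 1e-9)
        lysis = np.full_like(y, lysis_scale)
        ligand = y / (1 - y) * lysis
        for c, yl, ll, yy in zip(conc, ligand, lysis, y):
            rows.append((c, rep, yl, ll))
    return pd.DataFrame(rows, columns=["concentration_M", "replicate", "ligand_lum", "lysis_lum"])
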