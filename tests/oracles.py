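"""Independent brute-force re-implementations of the segmentation and binning
rules, used only to cross-check the pipeline. Every window, arc and angle is
re-evaluated per sample with plain loops — no cumulative sums, no searchsorted.
"""

from __future__ import annotations

import math

import numpy as np


def oracle_pause_mask(t, speed, pause_speed=0.01, window_s=10.0):
    """Pause iff strictly more than half the samples in [t-5, t+5] are slow."""
    t = np.asarray(t, float)
    speed = np.asarray(speed, float)
    n = t.size
    half = window_s / 2
    out = np.zeros(n, dtype=bool)
    for i in range(n):
        n_tot = n_slow = 0
        for j in range(n):
            if abs(t[j] - t[i]) <= half:
                n_tot += 1
                if speed[j] < pause_speed:
                    n_slow += 1
        out[i] = n_slow * 2 > n_tot
    return out


def oracle_turn_cores(xy, arc_mm=0.3, angle_deg=80.0):
    """Turn core iff the vertex angle over +-arc_mm path arcs is < angle_deg."""
    xy = np.asarray(xy, float)
    n = xy.shape[0]
    out = np.zeros(n, dtype=bool)
    for i in range(n):
        # walk backward until the along-path distance reaches the arc
        dist = 0.0
        j = None
        for b in range(i - 1, -1, -1):
            dist += math.dist(xy[b], xy[b + 1])
            if dist >= arc_mm:
                j = b
                break
        if j is None:
            continue
        dist = 0.0
        k = None
        for f in range(i + 1, n):
            dist += math.dist(xy[f - 1], xy[f])
            if dist >= arc_mm:
                k = f
                break
        if k is None:
            continue
        ax, ay = xy[j, 0] - xy[i, 0], xy[j, 1] - xy[i, 1]
        bx, by = xy[k, 0] - xy[i, 0], xy[k, 1] - xy[i, 1]
        na = math.hypot(ax, ay)
        nb = math.hypot(bx, by)
        if na == 0.0 or nb == 0.0:
            continue  # chord collapses onto the vertex: not evaluable
        c = (ax * bx + ay * by) / (na * nb)
        c = max(-1.0, min(1.0, c))
        if math.degrees(math.acos(c)) < angle_deg:
            out[i] = True
    return out


def oracle_turn_mask(xy, speed, arc_mm=0.3, angle_deg=80.0, postturn_speed=0.1):
    """Cores plus forward extension over contiguous slow samples."""
    cores = oracle_turn_cores(xy, arc_mm, angle_deg)
    out = cores.copy()
    n = out.size
    for i in range(n):
        if cores[i]:
            j = i + 1
            while j < n and (out[j] or speed[j] < postturn_speed):
                out[j] = True
                j += 1
    return out


def oracle_intervals(t, mask):
    """(start_index, end_index) pairs of maximal True stretches."""
    out = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            out.append((i, j))
            i = j + 1
        else:
            i += 1
    return out


def oracle_states(t, xy, speed, params=None):
    """Full per-sample labels by direct rule application.

    Precedence: turn/pirouette > pause > run. Turn intervals with successive
    gaps < 3.8 s merge into pirouettes, gap samples included.
    """
    p = params or {}
    t = np.asarray(t, float)
    turn_mask = oracle_turn_mask(
        xy, speed,
        p.get("turn_arc_mm", 0.3), p.get("turn_angle_deg", 80.0),
        p.get("postturn_speed", 0.1),
    )
    pause_mask = oracle_pause_mask(
        t, speed, p.get("pause_speed", 0.01), p.get("pause_window_s", 10.0)
    )
    gap_s = p.get("pirouette_gap_s", 3.8)
    ivs = oracle_intervals(t, turn_mask)
    # chain turns into pirouettes
    events = []  # (i0, i1, kind)
    idx = 0
    while idx < len(ivs):
        j = idx
        while j + 1 < len(ivs) and t[ivs[j + 1][0]] - t[ivs[j][1]] < gap_s:
            j += 1
        kind = "turn" if j == idx else "pirouette"
        events.append((ivs[idx][0], ivs[j][1], kind))
        idx = j + 1
    state = np.array(["run"] * t.size, dtype=object)
    for i in range(t.size):
        if pause_mask[i]:
            state[i] = "pause"
    for i0, i1, kind in events:
        for i in range(i0, i1 + 1):
            state[i] = kind
    return state


def oracle_bin_means(t, xy, speed, bin_s=10.0):
    """Per-bin mean speed and mean angular speed by direct recomputation."""
    t = np.asarray(t, float)
    xy = np.asarray(xy, float)
    dt = t[1] - t[0]
    per = int(round(bin_s / dt))
    n = t.size
    rows = []
    for b in range(n // per):
        i0, i1 = b * per, (b + 1) * per
        sp = float(np.mean(speed[i0:i1]))
        angs = []
        for i in range(max(i0, 1), min(i1, n - 1)):
            d1 = xy[i] - xy[i - 1]
            d2 = xy[i + 1] - xy[i]
            if np.hypot(*d1) == 0 or np.hypot(*d2) == 0:
                continue
            h1 = math.atan2(d1[1], d1[0])
            h2 = math.atan2(d2[1], d2[0])
            dh = (h2 - h1 + math.pi) % (2 * math.pi) - math.pi
            angs.append(abs(math.degrees(dh)) / dt)
        rows.append((sp, float(np.mean(angs)) if angs else float("nan")))
    return rows
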