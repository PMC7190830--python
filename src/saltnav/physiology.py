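"""Calcium-trace normalization and GPCR concentration-response analysis.

Single-channel traces are reported as dF/F0 (%): fluorescence is background
corrected (median of the background stream when a per-sample background is
supplied), F0 is the mean corrected fluorescence over the 10 s window before
stimulus delivery, and the trace is 100 * (F_corr - F0) / F0. Ratiometric
(FRET) traces use R = YFP / CFP and the analogous dR/R.

Concentration-response tables from the aequorin luminescence assay are
normalized per well to the total calcium response, ligand / (ligand + lysis),
expressed as percent of the series maximum (100% activation), and fitted
with a variable-slope four-parameter logistic on log10 concentration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


@dataclass
class CalciumTrace:
    """A fluorescence time series with stimulus timing.

    ``channels`` maps channel names to intensity arrays: {"F": ...} for a
    single-channel indicator or {"CFP": ..., "YFP": ...} for a ratiometric
    one. ``background`` is a scalar or a per-sample background stream for the
    single channel.
    """

    t: np.ndarray
    channels: dict
    background: float | np.ndarray = 0.0
    stim_onset_s: float = 10.0
    pre_window_s: float = 10.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        for name, ch in self.channels.items():
            if ch.shape != self.t.shape:
                raise ValueError(f"channel {name!r} length mismatch")
            if not np.all(np.isfinite(ch)):
                raise ValueError(f"channel {name!r} contains non-finite values")
        if self.stim_onset_s - self.pre_window_s < self.t[0] - 1e-9:
            raise ValueError("pre-stimulus window extends before the trace start")

    def _pre_mask(self) -> np.ndarray:
        return (self.t >= self.stim_onset_s - self.pre_window_s) & (self.t < self.stim_onset_s)


def delta_f_over_f(trace: CalciumTrace) -> np.ndarray:
    """dF/F0 (%) for a single-channel trace.

    F0 is the mean background-corrected fluorescence over the pre-stimulus
    window; a per-sample background stream is reduced to its median before
    subtraction. Raises if F0 <= 0 after correction.
    """
    if "F" not in trace.channels:
        raise ValueError("delta_f_over_f requires a single 'F' channel")
    f = trace.channels["F"]
    bg = trace.background
    bg_scalar = float(np.median(bg)) if np.ndim(bg) > 0 else float(bg)
    f_corr = f - bg_scalar
    pre = trace._pre_mask()
    if not pre.any():
        raise ValueError("empty pre-stimulus window")
    f0 = float(f_corr[pre].mean())
    if f0 <= 0:
        raise ValueError(
            f"F0 = {f0:.4g} <= 0 after background correction (background {bg_scalar:.4g}); "
            "check the background estimate"
        )
    return 100.0 * (f_corr - f0) / f0


def delta_r_over_r(trace: CalciumTrace, ratio_order: str = "yfp/cfp") -> np.ndarray:
    """dR/R (%) for a two-channel ratiometric trace.

    R = YFP/CFP by default (``ratio_order="cfp/yfp"`` for the reciprocal);
    samples with a non-positive denominator are undefined (NaN).
    """
    if not {"CFP", "YFP"} <= set(trace.channels):
        raise ValueError("delta_r_over_r requires CFP and YFP channels")
    if ratio_order == "yfp/cfp":
        num, den = trace.channels["YFP"], trace.channels["CFP"]
    elif ratio_order == "cfp/yfp":
        num, den = trace.channels["CFP"], trace.channels["YFP"]
    else:
        raise ValueError("ratio_order must be 'yfp/cfp' or 'cfp/yfp'")
    r = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    pre = trace._pre_mask()
    r0 = float(np.nanmean(r[pre]))
    if not np.isfinite(r0) or r0 <= 0:
        raise ValueError("pre-stimulus ratio baseline is undefined or non-positive")
    return 100.0 * (r - r0) / r0


# --- concentration-response --------------------------------------------------

def normalize_responses(table: pd.DataFrame) -> pd.DataFrame:
    """Normalize per-well luminescence to the total calcium response.

    Adds ``normalized`` = ligand / (ligand + lysis) and ``percent_activation``
    = 100 * normalized / max(normalized) over the series. Wells with zero
    total luminescence are excluded with a warning.
    """
    req = {"concentration_M", "ligand_lum", "lysis_lum"}
    if not req <= set(table.columns):
        raise ValueError(f"table must have columns {sorted(req)}")
    df = table.copy()
    total = df["ligand_lum"] + df["lysis_lum"]
    dead = total <= 0
    if dead.any():
        warnings.warn(f"excluding {int(dead.sum())} well(s) with zero total luminescence")
        df = df[~dead].copy()
        total = total[~dead]
    df["normalized"] = df["ligand_lum"] / total
    peak = df["normalized"].max()
    if peak <= 0:
        raise ValueError("series maximum normalized response is zero")
    df["percent_activation"] = 100.0 * df["normalized"] / peak
    return df


def summarize_responses(df: pd.DataFrame, column: str = "percent_activation") -> pd.DataFrame:
    """Replicate mean and S.E.M. per concentration."""
    g = df.groupby("concentration_M")[column]
    out = g.agg(["mean", "sem", "count"]).reset_index()
    return out.rename(columns={"mean": f"{column}_mean", "sem": f"{column}_sem", "count": "n"})


def _four_param_logistic(log10_c, bottom, top, log_ec50, hill):
    return bottom + (top - bottom) / (1 + 10 ** ((log_ec50 - log10_c) * hill))


@dataclass
class DoseResponseFit:
    """Result of a four-parameter logistic concentration-response fit."""

    bottom: float
    top: float
    log_ec50: float
    hill: float
    ec50: float
    se: dict = field(default_factory=dict)
    flagged: bool = False
    message: str = ""
    cov: np.ndarray | None = None

    @property
    def params(self) -> dict:
        return {"bottom": self.bottom, "top": self.top,
                "log_ec50": self.log_ec50, "hill": self.hill}

    def predict(self, concentration_M) -> np.ndarray:
        return _four_param_logistic(
            np.log10(np.asarray(concentration_M, dtype=float)),
            self.bottom, self.top, self.log_ec50, self.hill,
        )


def fit_dose_response(
    table: pd.DataFrame,
    response_col: str = "normalized",
    on_means: bool = False,
) -> DoseResponseFit:
    """Fit y = bottom + (top-bottom)/(1 + 10**((logEC50 - log10 c) * hill)).

    All replicate wells enter the fit as observations (``on_means=True``
    fits the replicate means instead). Initialization: bottom = min(y),
    top = max(y), hill = 1 and logEC50 at the half-range crossing by linear
    interpolation of the concentration-mean curve. Degenerate data (no
    spread across concentrations) or a non-positive fitted slope returns a
    flagged result.
    """
    if response_col not in table.columns:
        table = normalize_responses(table)
    df = table[["concentration_M", response_col]].dropna()
    if df["concentration_M"].nunique() < 4:
        raise ValueError("need >= 4 distinct concentrations for a 4-parameter fit")
    if on_means:
        df = df.groupby("concentration_M", as_index=False)[response_col].mean()
    x = np.log10(df["concentration_M"].to_numpy(dtype=float))
    y = df[response_col].to_numpy(dtype=float)

    means = df.groupby("concentration_M")[response_col].mean()
    mx = np.log10(means.index.to_numpy(dtype=float))
    my = means.to_numpy()
    y_lo, y_hi = float(my.min()), float(my.max())
    if np.isclose(y_hi, y_lo, rtol=0, atol=1e-12 * max(1.0, abs(y_hi))):
        return DoseResponseFit(
            bottom=y_lo, top=y_hi, log_ec50=float("nan"), hill=float("nan"),
            ec50=float("nan"), flagged=True, message="no inflection: response constant in concentration",
        )
    half = (y_lo + y_hi) / 2
    # first crossing of the half-range level, linearly interpolated
    log_ec50_0 = float(np.interp(half, my, mx)) if my[0] < my[-1] else float(np.interp(half, my[::-1], mx[::-1]))
    p0 = [y_lo, y_hi, log_ec50_0, 1.0]
    try:
        popt, pcov = curve_fit(
            _four_param_logistic, x, y, p0=p0, maxfev=20000,
            ftol=1e-14, xtol=1e-14, gtol=1e-14,
        )
    except RuntimeError as e:
        return DoseResponseFit(
            bottom=float("nan"), top=float("nan"), log_ec50=float("nan"), hill=float("nan"),
            ec50=float("nan"), flagged=True, message=f"fit did not converge: {e}",
        )
    bottom, top, log_ec50, hill = (float(v) for v in popt)
    perr = np.sqrt(np.clip(np.diag(pcov), 0, None))
    se = dict(zip(("bottom", "top", "log_ec50", "hill"), (float(v) for v in perr)))
    ec50 = 10.0 ** log_ec50
    se["ec50"] = float(np.log(10) * ec50 * se["log_ec50"])  # delta method
    flagged = hill <= 0
    msg = "non-positive Hill slope at optimum" if flagged else ""
    return DoseResponseFit(
        bottom=bottom, top=top, log_ec50=log_ec50, hill=hill, ec50=ec50,
        se=se, flagged=flagged, message=msg, cov=pcov,
    )
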