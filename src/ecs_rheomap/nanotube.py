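"""Local ECS analysis from elongated-probe (SWCNT-style) trajectories.

A single nanotube explores the extracellular space for minutes, so its
trajectory can be cut into short windows and analysed locally: a 10-frame
sliding MSD window with a 3-point linear fit yields a map of local
instantaneous diffusion coefficients, and a 6-point window of positions
yields the local shape of the explored area.  Where the trajectory is
maximally distorted (largest eccentricity of the position-covariance
ellipse) the minor-axis spread reports the local channel width, after
subtracting the localization variance in quadrature.

The width model assumes uniform transverse occupancy of a straight channel
(range = sqrt(12)·SD); a fixed multiplicative calibration factor, determined
once on synthetic channel simulations, compensates the bias introduced by the
6-point sampling and the max-eccentricity window selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ecs_rheomap import rheology

#: default localization precision for SWCNT data, µm (median, ThunderSTORM-style)
DEFAULT_PRECISION_UM = 0.030

#: sliding MSD window (frames) and number of fitted lags for local D_inst
DINST_WINDOW = 10
DINST_FIT_POINTS = 3

#: number of positions in the local-shape (eccentricity) window
ECCENTRICITY_WINDOW = 6

#: number of positions supporting the transverse-variance measurement,
#: centred on the selected max-confinement window (~1 s of data at 33 ms)
WIDTH_SUPPORT = 30

#: fixed calibration of the local-width estimator, determined once on
#: synthetic straight-channel trajectories (widths 60–140 nm, D = 0.04 µm²/s,
#: 33 ms frames, 30 nm localization noise; see scripts/calibrate_width.py).
#: It corrects the residual downward bias of the noise-subtracted transverse
#: variance under max-confinement window selection.
WIDTH_CALIBRATION = 1.1139  # frozen output of scripts/calibrate_width.py (seed 424242)


@dataclass
class ErrorModel:
    """Localization-noise floor on instantaneous diffusion estimates.

    ``delta_D = dx**2 / t_fit`` with ``dx`` the localization precision (µm)
    and ``t_fit`` the duration of the fitted MSD window (s).
    """

    dx: float
    t_fit: float

    @property
    def delta_D(self) -> float:
        return self.dx ** 2 / self.t_fit


def dinst_error(dx: float, n_fit_frames: int = DINST_FIT_POINTS,
                frame_interval: float = 0.030) -> float:
    """Error floor on D_inst from localization precision: Δx²/(n·Δt).

    With the defaults (Δx = 30 nm, 3 fitted frames of 30 ms) the floor is
    0.01 µm²/s.
    """
    if dx < 0:
        raise ValueError("dx must be >= 0")
    t = n_fit_frames * frame_interval
    if t <= 0:
        raise ValueError("fit window duration must be > 0")
    return dx ** 2 / t


# ---------------------------------------------------------------------------
# drift correction
# ---------------------------------------------------------------------------

def correct_drift(trajectories: pd.DataFrame,
                  reference_ids) -> pd.DataFrame:
    """Subtract stage drift measured on non-mobile reference particles.

    The drift at each frame is the mean displacement of the reference
    trajectories from their own first frame; it is subtracted from every
    trajectory (references included).  With no references the table is
    returned unchanged with a warning.
    """
    reference_ids = list(reference_ids)
    refs = trajectories[trajectories["traj_id"].isin(reference_ids)]
    if refs.empty:
        import warnings
        warnings.warn("no reference particles; drift correction skipped", stacklevel=2)
        return trajectories.copy()
    disp = []
    for _, g in refs.groupby("traj_id"):
        g = g.sort_values("frame")
        d = g[["x_um", "y_um"]].to_numpy() - g[["x_um", "y_um"]].to_numpy()[0]
        disp.append(pd.DataFrame({"frame": g["frame"].to_numpy(),
                                  "dx": d[:, 0], "dy": d[:, 1]}))
    drift = pd.concat(disp).groupby("frame")[["dx", "dy"]].mean()
    out = trajectories.copy()
    out = out.merge(drift, left_on="frame", right_index=True, how="left")
    out[["dx", "dy"]] = out[["dx", "dy"]].fillna(0.0)
    out["x_um"] = out["x_um"] - out["dx"]
    out["y_um"] = out["y_um"] - out["dy"]
    return out.drop(columns=["dx", "dy"])


# ---------------------------------------------------------------------------
# sliding-window local diffusion
# ---------------------------------------------------------------------------

def sliding_dinst(
    positions: np.ndarray,
    frame_interval: float,
    window: int = DINST_WINDOW,
    fit_points: int = DINST_FIT_POINTS,
) -> pd.DataFrame:
    """Local D_inst along a trajectory from a sliding MSD window.

    For every start index (step 1 frame) the time-averaged MSD of the
    ``window`` positions is computed and an OLS line with free intercept is
    fitted to the first ``fit_points`` lags; local D = slope/4, floored at 0.
    Returns a table with window index, window-centre coordinates and local
    D; empty for trajectories shorter than the window.
    """
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    rows = []
    for i in range(0, n - window + 1):
        seg = positions[i:i + window]
        msd = rheology.compute_msd(seg, frame_interval)
        d, flags = rheology.fit_dinst(msd, fit_points)
        center = seg.mean(axis=0)
        rows.append({"window_index": i, "x_um": center[0], "y_um": center[1],
                     "local_D": d, "flags": ";".join(flags)})
    return pd.DataFrame(rows, columns=["window_index", "x_um", "y_um",
                                       "local_D", "flags"])


def exclude_immobile(
    trajectories: pd.DataFrame,
    frame_interval: float,
    plateau_factor: float = 2.0,
    d_threshold: float = rheology.IMMOBILE_THRESHOLD,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop trajectories whose global MSD is flat (immobile probes).

    A trajectory is excluded when its global MSD plateau ratio
    ``MSD(late)/MSD(early)`` (mean of the last vs first three computed lags)
    is below ``plateau_factor`` or its global D_inst is below
    ``d_threshold``.  Returns ``(kept, report)`` where the report lists both
    criteria for every trajectory.
    """
    keep_ids, rows = [], []
    for tid, g in trajectories.groupby("traj_id"):
        g = g.sort_values("frame")
        pos = g[["x_um", "y_um"]].to_numpy()
        frames = g["frame"].to_numpy()
        # lags beyond half the span average too few pairs to be reliable
        msd = rheology.compute_msd(pos, frame_interval, frames=frames,
                                   max_lag=max(2, int(frames[-1] - frames[0]) // 2))
        d, _ = rheology.fit_dinst(msd, min(3, len(msd)))
        k = min(3, max(1, len(msd) // 2))
        early = float(msd.msd[:k].mean())
        late = float(msd.msd[-k:].mean())
        ratio = late / early if early > 0 else float("inf")
        excluded = (ratio < plateau_factor) or (math.isnan(d) or d < d_threshold)
        rows.append({"traj_id": tid, "plateau_ratio": ratio, "global_D": d,
                     "excluded": excluded})
        if not excluded:
            keep_ids.append(tid)
    report = pd.DataFrame(rows)
    kept = trajectories[trajectories["traj_id"].isin(keep_ids)].copy()
    return kept, report


# ---------------------------------------------------------------------------
# local-shape (eccentricity) analysis and width estimation
# ---------------------------------------------------------------------------

def _window_covariance_eigen(seg: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Eigenvalues (major, minor) and minor-axis unit vector of a window."""
    cov = np.cov(seg.T, ddof=1)
    vals, vecs = np.linalg.eigh(cov)   # ascending
    return float(vals[1]), float(vals[0]), vecs[:, 0]


def window_eccentricity(
    positions: np.ndarray,
    window: int = ECCENTRICITY_WINDOW,
    precision: float = DEFAULT_PRECISION_UM,
) -> pd.DataFrame:
    """Eccentricity of the position-covariance ellipse per sliding window.

    Eccentricity = sqrt(λ_major / λ_minor) of the window's position
    covariance (an axis-length ratio, >= 1); the minor eigenvalue is floored
    at ``precision²`` for stability with 6-point windows.  Exactly collinear
    windows with zero floor give ``inf`` and are flagged.
    """
    positions = np.asarray(positions, dtype=float)
    if len(positions) < window:
        raise ValueError(f"need at least {window} positions")
    floor = precision ** 2
    rows = []
    for i in range(0, len(positions) - window + 1):
        lam_max, lam_min, _ = _window_covariance_eigen(positions[i:i + window])
        lam_min_f = max(lam_min, floor)
        if lam_min_f == 0.0:
            ecc, flag = float("inf"), "collinear"
        else:
            ecc, flag = math.sqrt(max(lam_max, 0.0) / lam_min_f), ""
        rows.append({"window_index": i, "eccentricity": ecc, "flags": flag})
    return pd.DataFrame(rows)


def select_max_confinement(eccentricities) -> int | None:
    """Index of the maximally confined window (largest finite eccentricity).

    Ties resolve to the earliest window; returns ``None`` when no finite
    eccentricity exists.
    """
    e = np.asarray(eccentricities, dtype=float)
    finite = np.isfinite(e)
    if not finite.any():
        return None
    masked = np.where(finite, e, -np.inf)
    return int(np.argmax(masked))


@dataclass
class WidthEstimate:
    """Local ECS width from one trajectory window."""

    width_nm: float
    window_index: int
    below_resolution: bool = False


def estimate_local_width(
    window_positions: np.ndarray,
    precision: float = DEFAULT_PRECISION_UM,
    calibration: float | None = None,
) -> tuple[float, bool]:
    """Channel width (nm) from the minor-axis spread of a position window.

    The localization variance is subtracted in quadrature from the minor-axis
    sample variance; under uniform transverse occupancy the channel width is
    sqrt(12)·SD, scaled by the fixed simulation calibration factor.  Returns
    ``(width_nm, below_resolution)``; the flag is set (width 0) when the
    measured spread does not exceed the noise floor.

    With a 30 nm precision the transverse spread of a sub-100-nm channel is
    comparable to the noise, so the supporting window should hold well more
    than 6 points for the variance (and its minor-axis direction) to be
    informative; :func:`trajectory_width` therefore measures over
    ``WIDTH_SUPPORT`` positions around the selected confinement window.
    """
    if precision < 0:
        raise ValueError("precision must be >= 0")
    cal = WIDTH_CALIBRATION if calibration is None else calibration
    seg = np.asarray(window_positions, dtype=float)
    _, lam_min, _ = _window_covariance_eigen(seg)
    var_ch = lam_min - precision ** 2
    if var_ch <= 0:
        return 0.0, True
    return math.sqrt(12.0 * var_ch) * 1000.0 * cal, False


def trajectory_width(
    positions: np.ndarray,
    precision: float = DEFAULT_PRECISION_UM,
    window: int = ECCENTRICITY_WINDOW,
    support: int = WIDTH_SUPPORT,
    calibration: float | None = None,
) -> WidthEstimate | None:
    """Local width of one trajectory at its maximum-confinement window.

    The 6-point eccentricity scan locates the most confined stretch; the
    width itself is measured from the transverse variance over ``support``
    positions centred on that window (clipped to the trajectory), which
    keeps the estimate local while giving the variance enough degrees of
    freedom against the localization noise.
    """
    positions = np.asarray(positions, dtype=float)
    ecc = window_eccentricity(positions, window, precision)
    idx = select_max_confinement(ecc["eccentricity"])
    if idx is None:
        return None
    c = idx + window // 2
    lo = max(0, c - support // 2)
    hi = min(len(positions), lo + support)
    lo = max(0, hi - support)
    w, below = estimate_local_width(positions[lo:hi], precision, calibration)
    return WidthEstimate(w, idx, below)


def local_map(
    positions: np.ndarray,
    frame_interval: float,
    precision: float = DEFAULT_PRECISION_UM,
    dinst_window: int = DINST_WINDOW,
    fit_points: int = DINST_FIT_POINTS,
    ecc_window: int = ECCENTRICITY_WINDOW,
    calibration: float | None = None,
) -> pd.DataFrame:
    """Combined local map for one trajectory: D_inst and shape per window.

    Rows follow the sliding D-window; the eccentricity and the selected
    local width (reported once, at the max-confinement window) come from the
    6-point shape window.
    """
    dmap = sliding_dinst(positions, frame_interval, dinst_window, fit_points)
    ecc = window_eccentricity(positions, ecc_window, precision)
    out = dmap.merge(ecc, on="window_index", how="left",
                     suffixes=("", "_ecc"))
    out["width_nm"] = np.nan
    est = trajectory_width(positions, precision, window=ecc_window,
                           calibration=calibration)
    if est is not None and est.window_index in set(out["window_index"]):
        out.loc[out["window_index"] == est.window_index, "width_nm"] = est.width_nm
    return out
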