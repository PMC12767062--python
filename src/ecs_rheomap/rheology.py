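"""MSD-based rheology of single-particle trajectories.

Implements the QD analysis chain: time-averaged mean squared displacement
(MSD) curves, instantaneous diffusion coefficients from a 4-point linear fit,
confinement areas from the 0.6–0.8 s MSD plateau, the 0.005 µm²/s mobility
threshold, per-field-of-view immobile fractions with the amyloid-FOV
inclusion rule, and the paired relative-change statistic between adjacent
plaque compartments.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: probes slower than this are counted immobile (µm²/s)
IMMOBILE_THRESHOLD = 0.005
#: lag-time window of the MSD plateau used as the confinement proxy (s)
CONFINEMENT_WINDOW = (0.6, 0.8)
#: number of leading MSD points in the D_inst fit
DINST_FIT_POINTS = 4


@dataclass
class MSDCurve:
    """Mean squared displacement vs lag time.

    ``lags`` are in seconds (strictly increasing), ``msd`` in µm², and
    ``n_pairs`` counts the displacement pairs averaged at each lag.
    """

    lags: np.ndarray
    msd: np.ndarray
    n_pairs: np.ndarray

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=int)
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if np.any(self.msd < 0):
            raise ValueError("msd values must be non-negative")

    def __len__(self) -> int:
        return len(self.lags)


@dataclass
class RheologyRecord:
    """Per-trajectory rheology summary."""

    traj_id: int
    D_inst: float                      # µm²/s, floored at 0
    confinement_area: float | None     # µm², None when window not covered
    mobile: bool
    roi_label: str = "WT"
    flags: tuple[str, ...] = ()


def compute_msd(
    positions: np.ndarray,
    frame_interval: float,
    frames: np.ndarray | None = None,
    max_lag: int | None = None,
) -> MSDCurve:
    """Time-averaged MSD of one trajectory over all ordered pairs per lag.

    ``positions`` is (n, 2) in µm; ``frames`` gives the (strictly increasing,
    possibly gapped) frame index of each point, defaulting to 0..n-1.  Lags
    are frame differences converted to seconds.  ``max_lag`` (frames) beyond
    the trajectory span is truncated with a warning.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 2 or positions.shape[1] != 2 or len(positions) < 2:
        raise ValueError("positions must be (n>=2, 2)")
    if frames is None:
        frames = np.arange(len(positions))
    frames = np.asarray(frames, dtype=int)
    if np.any(np.diff(frames) <= 0):
        raise ValueError("frames must be strictly increasing")
    span = int(frames[-1] - frames[0])
    if max_lag is None:
        max_lag = span
    elif max_lag >= span + 1:
        warnings.warn("max_lag exceeds trajectory span; truncating", stacklevel=2)
        max_lag = span
    # dense array indexed by frame offset; NaN marks gaps
    dense = np.full((span + 1, 2), np.nan)
    dense[frames - frames[0]] = positions
    lags, msds, npairs = [], [], []
    for k in range(1, max_lag + 1):
        d = dense[k:] - dense[:-k]
        sq = d[:, 0] ** 2 + d[:, 1] ** 2
        valid = ~np.isnan(sq)
        n = int(valid.sum())
        if n == 0:
            continue
        lags.append(k * frame_interval)
        msds.append(float(sq[valid].mean()))
        npairs.append(n)
    return MSDCurve(np.array(lags), np.array(msds), np.array(npairs))


def ensemble_msd(curves: Iterable[MSDCurve]) -> MSDCurve:
    """Average per-trajectory MSD curves with equal trajectory weight.

    At each lag, the ensemble value is the unweighted mean of the MSD of the
    trajectories that report that lag; ``n_pairs`` counts contributing
    trajectories.
    """
    acc: dict[float, list[float]] = {}
    for c in curves:
        for lag, m in zip(c.lags, c.msd):
            acc.setdefault(round(float(lag), 9), []).append(float(m))
    if not acc:
        raise ValueError("no MSD curves supplied")
    lags = np.array(sorted(acc))
    msd = np.array([np.mean(acc[l]) for l in lags])
    n = np.array([len(acc[l]) for l in lags])
    return MSDCurve(lags, msd, n)


def fit_dinst(msd: MSDCurve, n_fit_points: int = DINST_FIT_POINTS) -> tuple[float, tuple[str, ...]]:
    """Instantaneous diffusion coefficient from the first MSD points.

    Ordinary least squares with a free intercept through the first
    ``n_fit_points`` lags; the intercept absorbs the localization-noise
    offset (4·Δx²).  D_inst = slope/4 for 2D motion; a negative fitted slope
    is floored to 0 and flagged.  Returns ``(D_inst, flags)``; insufficient
    lags give ``(nan, ("insufficient_points",))``.
    """
    if n_fit_points < 2:
        raise ValueError("n_fit_points must be >= 2")
    if len(msd) < n_fit_points:
        return float("nan"), ("insufficient_points",)
    t = msd.lags[:n_fit_points]
    y = msd.msd[:n_fit_points]
    slope = np.polyfit(t, y, 1)[0]
    if slope < 0:
        return 0.0, ("negative_slope_floored",)
    return float(slope / 4.0), ()


def confinement_area(
    msd: MSDCurve,
    window: tuple[float, float] = CONFINEMENT_WINDOW,
    min_span: float | None = None,
) -> float | None:
    """Confinement-area proxy: mean MSD over the plateau window (closed).

    At 28 Hz the default [0.6, 0.8] s window covers lags 17–22.  Returns
    ``None`` when no lag falls in the window, or when ``min_span`` (s) is
    given and the trajectory does not span it.
    """
    lo, hi = window
    if not hi > lo:
        raise ValueError("window must be increasing")
    if min_span is not None and (len(msd.lags) == 0 or msd.lags[-1] < min_span):
        return None
    sel = (msd.lags >= lo - 1e-12) & (msd.lags <= hi + 1e-12)
    if not sel.any():
        return None
    return float(msd.msd[sel].mean())


def classify_mobility(D_inst: float, threshold: float = IMMOBILE_THRESHOLD) -> str:
    """'immobile' iff D_inst is strictly lower than the threshold."""
    if D_inst < 0:
        raise ValueError("D_inst must be >= 0")
    return "immobile" if D_inst < threshold else "mobile"


def analyze_trajectory(
    positions: np.ndarray,
    frame_interval: float,
    frames: np.ndarray | None = None,
    traj_id: int = 0,
    roi_label: str = "WT",
    n_fit_points: int = DINST_FIT_POINTS,
    window: tuple[float, float] = CONFINEMENT_WINDOW,
    immobile_threshold: float = IMMOBILE_THRESHOLD,
) -> RheologyRecord:
    """Full per-trajectory record: D_inst, confinement, mobility class.

    The confinement area is reported only when the trajectory spans the upper
    edge of the plateau window.
    """
    msd = compute_msd(positions, frame_interval, frames=frames)
    d, flags = fit_dinst(msd, n_fit_points)
    conf = confinement_area(msd, window, min_span=window[1])
    mobile = (not math.isnan(d)) and classify_mobility(max(d, 0.0), immobile_threshold) == "mobile"
    return RheologyRecord(traj_id, d, conf, mobile, roi_label, flags)


def analyze_table(
    df: pd.DataFrame,
    frame_interval: float,
    roi_column: str | None = None,
    fov_column: str | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Apply :func:`analyze_trajectory` to a trajectory table.

    ``df`` uses the shared format (``traj_id, frame, x_um, y_um`` plus
    optional ROI / FOV columns).  Returns one row per trajectory.
    """
    rows = []
    for tid, g in df.groupby("traj_id", sort=True):
        g = g.sort_values("frame")
        roi = str(g[roi_column].iloc[0]) if roi_column else "WT"
        rec = analyze_trajectory(
            g[["x_um", "y_um"]].to_numpy(), frame_interval,
            frames=g["frame"].to_numpy(), traj_id=int(tid), roi_label=roi, **kwargs)
        row = {
            "traj_id": rec.traj_id, "roi": rec.roi_label, "D_inst": rec.D_inst,
            "confinement_um2": rec.confinement_area, "mobile": rec.mobile,
            "flags": ";".join(rec.flags),
        }
        if fov_column:
            row["fov"] = g[fov_column].iloc[0]
        rows.append(row)
    cols = ["traj_id", "roi", "D_inst", "confinement_um2", "mobile", "flags"]
    if fov_column:
        cols.append("fov")
    return pd.DataFrame(rows, columns=cols)


def immobile_fraction(
    records: pd.DataFrame,
    roi_label: str,
    fov_column: str = "fov",
    amyloid_label: str = "Amyloid",
) -> pd.Series:
    """Per-FOV immobile fraction in one ROI, with the amyloid inclusion rule.

    A field of view enters the analysis only if its Amyloid ROI contains at
    least one immobile particle; excluded FOVs are dropped from every ROI's
    fractions.  FOVs with no particles in the requested ROI yield NaN.

    ``records`` needs columns ``mobile`` (bool), ``roi`` and the FOV column.
    """
    fracs = {}
    for fov, g in records.groupby(fov_column):
        amy = g[g["roi"] == amyloid_label]
        if not (~amy["mobile"]).any():
            continue        # FOV excluded: no immobile particle in Amyloid
        sub = g[g["roi"] == roi_label]
        fracs[fov] = float((~sub["mobile"]).mean()) if len(sub) else float("nan")
    return pd.Series(fracs, name=f"immobile_fraction_{roi_label}", dtype=float)


def relative_change(x: float, y: float) -> float:
    """Paired relative change between adjacent compartments, in percent.

    ``100 * (x - y) / (0.5 * (x + y))`` with x the outermost and y the
    innermost compartment value, i.e. positive when the outer compartment is
    larger.  The opposite sign convention is obtained by swapping the
    arguments (the statistic is antisymmetric).  Undefined (NaN) when
    ``x + y == 0``.
    """
    s = 0.5 * (x + y)
    if s == 0:
        return float("nan")
    return 100.0 * (x - y) / s
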