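"""Plaque geometry, penetrability statistics and circularity phenotyping.

Covers the two geometric analyses used around amyloid plaques:

* shadow-imaging-style morphometry — plaque core and cell-ring surfaces are
  approximated as circles (A = πr²), giving equivalent radii and ring widths,
  and concentric Amyloid/Ring/Out ROIs built with the 1.82 ring-width /
  core-radius scaling;
* ThS-style phenotyping — maximum projection, isodata thresholding, wand
  (connected-component) selection, the 4πA/P² circularity shape descriptor
  and its filamentous/intermediate/compact classification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage import measure

from ecs_rheomap.simkit import DEFAULT_RING_FACTOR

#: circularity class boundaries: filamentous <= 0.14 < intermediate <= 0.28 < compact
FILAMENTOUS_MAX = 0.14
INTERMEDIATE_MAX = 0.28


# ---------------------------------------------------------------------------
# circle-approximation morphometry
# ---------------------------------------------------------------------------

def area_to_radius(area: float) -> float:
    """Equivalent-circle radius (µm) of a measured surface: sqrt(A/π)."""
    if area < 0:
        raise ValueError("area must be >= 0")
    return math.sqrt(area / math.pi)


def ring_width(core_area: float, ring_area: float) -> float:
    """Cell-ring width: total equivalent radius minus core radius (µm)."""
    if core_area < 0 or ring_area < 0:
        raise ValueError("areas must be >= 0")
    return area_to_radius(core_area + ring_area) - area_to_radius(core_area)


def volume_ratio(core_area: float, ring_area: float) -> float:
    """(R_total / r_core)³ — how much volume the whole plaque occupies
    relative to the amyloid core alone, under the spherical approximation."""
    r = area_to_radius(core_area)
    if r == 0:
        raise ValueError("core_area must be > 0")
    return (area_to_radius(core_area + ring_area) / r) ** 3


@dataclass(frozen=True)
class PlaqueROI:
    """Concentric Amyloid / Ring / Out regions around a plaque core.

    Parametric form: the core is a disk of ``core_radius`` at ``center``
    (µm); the ring extends the core radius by ``ring factor × r`` and the
    Out annulus reaches ``out_outer_radius``.
    """

    center: tuple[float, float]
    core_radius: float
    ring_outer_radius: float
    out_outer_radius: float
    clipped: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.core_radius < self.ring_outer_radius < self.out_outer_radius:
            raise ValueError("radii must satisfy 0 < core < ring < out")

    def areas(self) -> dict[str, float]:
        """Analytic region areas (µm²)."""
        a_core = math.pi * self.core_radius ** 2
        a_ring = math.pi * self.ring_outer_radius ** 2 - a_core
        a_out = math.pi * self.out_outer_radius ** 2 - a_core - a_ring
        return {"Amyloid": a_core, "Ring": a_ring, "Out": a_out}

    def label_points(self, points: np.ndarray) -> np.ndarray:
        """Region label per point ('Amyloid'/'Ring'/'Out'/'' outside).

        A point exactly on a shared boundary is assigned to the inner
        region (deterministic tie-break via closed inner intervals).
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        r = np.hypot(pts[:, 0] - self.center[0], pts[:, 1] - self.center[1])
        labels = np.full(len(pts), "", dtype=object)
        labels[r <= self.out_outer_radius] = "Out"
        labels[r <= self.ring_outer_radius] = "Ring"
        labels[r <= self.core_radius] = "Amyloid"
        return labels


def build_concentric_rois(
    core,
    ring_factor: float = DEFAULT_RING_FACTOR,
    out_bound: float | None = None,
    pixel_size: float | None = None,
    field_um: tuple[float, float] | None = None,
) -> PlaqueROI:
    """Concentric ROIs from a plaque core (parametric or mask).

    ``core`` is either ``(center_xy_um, radius_um)`` or a binary mask (with
    ``pixel_size`` in µm/px), whose equivalent-area radius and centroid are
    used.  The ring width is ``ring_factor`` times the core radius; the Out
    region defaults to twice the ring outer radius, clipped to ``field_um``
    when given (clipping is flagged).
    """
    if ring_factor <= 0:
        raise ValueError("ring_factor must be > 0 (a zero-width ring is degenerate)")
    if isinstance(core, np.ndarray):
        if pixel_size is None:
            raise ValueError("mask cores require pixel_size")
        if not core.any():
            raise ValueError("core mask is empty")
        area = float(core.sum()) * pixel_size ** 2
        cy, cx = ndimage.center_of_mass(core)
        center = (cx * pixel_size, cy * pixel_size)
        radius = area_to_radius(area)
    else:
        center, radius = core
        if radius <= 0:
            raise ValueError("core radius must be > 0")
    ring_outer = radius * (1.0 + ring_factor)
    out_outer = 2.0 * ring_outer if out_bound is None else out_bound
    if out_outer <= ring_outer:
        raise ValueError("out_bound must exceed the ring outer radius")
    clipped = False
    if field_um is not None:
        h, w = field_um
        max_r = min(center[0], center[1], w - center[0], h - center[1])
        if out_outer > max_r:
            import warnings
            warnings.warn("Out ROI clipped to the field", stacklevel=2)
            out_outer = max(max_r, ring_outer * 1.0001)
            clipped = True
    return PlaqueROI(tuple(center), radius, ring_outer, out_outer, clipped)


def localization_density(points: np.ndarray, roi: PlaqueROI) -> pd.DataFrame:
    """Localization count and density (points/µm²) per concentric region.

    Counts individual localizations, not trajectories.  Returns a table with
    one row per region (Amyloid, Ring, Out).
    """
    labels = roi.label_points(points) if len(np.atleast_2d(points)) else np.array([])
    areas = roi.areas()
    rows = []
    for region in ("Amyloid", "Ring", "Out"):
        n = int((labels == region).sum()) if labels.size else 0
        a = areas[region]
        rows.append({"region": region, "n_locs": n, "area_um2": a,
                     "density_per_um2": n / a})
    return pd.DataFrame(rows)


def penetrability_ratio(densities: pd.DataFrame, pair: str = "Out/Ring") -> float:
    """Density ratio between adjacent regions (outer / inner).

    ``pair`` is ``"Out/Ring"`` or ``"Ring/Amyloid"``.  A ratio close to 1
    means free exchange across the boundary; values well above 1 mean the
    inner region excludes the probe.  NaN when the inner density is zero.
    """
    outer, inner = pair.split("/")
    d = densities.set_index("region")["density_per_um2"]
    if outer not in d.index or inner not in d.index:
        raise KeyError(f"unknown pair {pair!r}")
    if d[inner] == 0:
        return float("nan")
    return float(d[outer] / d[inner])


# ---------------------------------------------------------------------------
# ThS phenotyping chain
# ---------------------------------------------------------------------------

def max_projection(stack: np.ndarray) -> np.ndarray:
    """Pixel-wise maximum-intensity projection over the slice axis."""
    stack = np.asarray(stack)
    if stack.ndim == 2:
        return stack.copy()
    if stack.shape[0] < 1:
        raise ValueError("stack must contain at least one slice")
    return stack.max(axis=0)


def isodata_threshold(image: np.ndarray) -> float:
    """Ridler–Calvard iterative intermeans threshold.

    Fixed point of T = (mean below T + mean above T) / 2, iterated from the
    global mean.  Raises on constant images (no threshold separates them).
    """
    vals = np.asarray(image, dtype=float).ravel()
    if vals.min() == vals.max():
        raise ValueError("cannot threshold a constant image")
    t = float(vals.mean())
    for _ in range(500):
        below = vals[vals <= t]
        above = vals[vals > t]
        if len(below) == 0 or len(above) == 0:
            break
        t_new = 0.5 * (below.mean() + above.mean())
        if abs(t_new - t) < 1e-9:
            return float(t_new)
        t = t_new
    return float(t)


def wand_select(mask: np.ndarray, seed: tuple[int, int]) -> np.ndarray:
    """8-connected component of a binary mask containing the seed pixel.

    Emulates an ImageJ wand-tool selection on a thresholded image; the seed
    is ``(row, col)`` and must lie on foreground.
    """
    mask = np.asarray(mask, dtype=bool)
    r, c = seed
    if not mask[r, c]:
        raise ValueError("seed point lies on background")
    labels, _ = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    return labels == labels[r, c]


def perimeter_polygon(mask: np.ndarray) -> float:
    """Boundary-polygon perimeter of a binary component (pixels).

    Traces the 0.5 iso-contour through pixel-edge midpoints (marching
    squares) and sums segment lengths over all boundary loops, so diagonal
    steps weigh 1/√2 per half-pixel — the behaviour of ImageJ-style traced
    outlines.  A single isolated pixel is measured by its unit-square
    boundary (P = 4).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask has no perimeter")
    if mask.sum() == 1:
        return 4.0
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    total = 0.0
    for c in contours:
        total += float(np.sum(np.hypot(*np.diff(c, axis=0).T)))
    return total


def circularity(mask: np.ndarray, pixel_size: float = 1.0) -> float:
    """Shape circularity 4π·A/P² of a connected component.

    A is the pixel count times the pixel area and P the traced boundary
    polygon perimeter; the measure is scale-free, so ``pixel_size`` only
    matters for consistency of units.  A perfect circle approaches 1,
    thin filaments approach 0; values slightly above 1 can occur from
    discretization and are not clipped.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("component is empty")
    area = float(mask.sum()) * pixel_size ** 2
    per = perimeter_polygon(mask) * pixel_size
    return 4.0 * math.pi * area / per ** 2


def classify_phenotype(c: float) -> str:
    """Plaque phenotype from circularity.

    filamentous: C <= 0.14; intermediate: 0.14 < C <= 0.28;
    compact: C > 0.28.
    """
    if c < 0:
        raise ValueError("circularity must be >= 0")
    if c <= FILAMENTOUS_MAX:
        return "filamentous"
    if c <= INTERMEDIATE_MAX:
        return "intermediate"
    return "compact"


def phenotype_from_stack(stack: np.ndarray, seed: tuple[int, int],
                         pixel_size: float = 1.0) -> dict:
    """Full ThS chain: max-project, isodata-threshold, wand-select, score.

    Returns the measured circularity, phenotype class, selected area (µm²)
    and the threshold used.
    """
    proj = max_projection(stack)
    t = isodata_threshold(proj)
    comp = wand_select(proj > t, seed)
    c = circularity(comp, pixel_size)
    return {"circularity": c, "phenotype": classify_phenotype(c),
            "area_um2": float(comp.sum()) * pixel_size ** 2, "threshold": t}


# ---------------------------------------------------------------------------
# distribution check
# ---------------------------------------------------------------------------

def lognormality_check(areas, alpha: float = 0.05) -> tuple[bool, float, float]:
    """D'Agostino–Pearson omnibus normality test on log-transformed areas.

    Returns ``(passed, statistic, p_value)`` with ``passed`` true when the
    log-normal hypothesis is not rejected (p > alpha).  Requires n >= 8 and
    strictly positive areas.
    """
    a = np.asarray(areas, dtype=float)
    if len(a) < 8:
        raise ValueError("need at least 8 areas for the omnibus test")
    if np.any(a <= 0):
        raise ValueError("areas must be strictly positive")
    stat, p = stats.normaltest(np.log(a))
    return bool(p > alpha), float(stat), float(p)
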