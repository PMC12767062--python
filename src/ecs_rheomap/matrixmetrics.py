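"""Extracellular-matrix signal quantification.

Percent thresholded area per ROI, topology-preserving skeletonization,
box-counting fractal dimension of the matrix network (a proxy for its
interconnectivity) and plain mean-intensity quantification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import morphology

from ecs_rheomap.plaque import isodata_threshold


@dataclass
class MatrixMask:
    """Binary matrix mask plus the threshold that produced it."""

    mask: np.ndarray
    pixel_size: float = 1.0        # µm/px
    threshold: float | None = None
    method: str = "isodata"


def threshold_matrix(image: np.ndarray, pixel_size: float = 1.0,
                     method: str = "isodata") -> MatrixMask:
    """Binary matrix mask from a fluorescence image (isodata threshold)."""
    if method != "isodata":
        raise ValueError(f"unknown threshold method {method!r}")
    t = isodata_threshold(image)
    return MatrixMask(np.asarray(image) > t, pixel_size, t, method)


def percent_area(mask: np.ndarray, roi: np.ndarray | None = None) -> float:
    """Percentage of ROI pixels covered by the mask foreground."""
    mask = np.asarray(mask, dtype=bool)
    if roi is None:
        roi = np.ones_like(mask, dtype=bool)
    roi = np.asarray(roi, dtype=bool)
    n_roi = int(roi.sum())
    if n_roi == 0:
        raise ValueError("ROI is empty")
    return 100.0 * float((mask & roi).sum()) / n_roi


def skeletonize(mask: np.ndarray) -> np.ndarray:
    """Topology-preserving thinning to a 1-px-wide skeleton."""
    return morphology.skeletonize(np.asarray(mask, dtype=bool))


def box_count_fractal(mask: np.ndarray) -> float:
    """Box-counting fractal dimension of a binary mask.

    Occupied boxes N(s) are counted on a grid anchored at the mask origin for
    dyadic box sizes s in {2, 4, ..., side/4}; the dimension is minus the
    slope of the OLS fit of log N against log s.  An empty mask scores 0 by
    convention (no signal, no structure).
    """
    mask = np.asarray(mask, dtype=bool)
    side = min(mask.shape)
    if side < 64:
        raise ValueError("mask side must be >= 64 px")
    if not mask.any():
        return 0.0
    sizes, counts = [], []
    s = 2
    while s <= side // 4:
        ny = -(-mask.shape[0] // s)
        nx = -(-mask.shape[1] // s)
        padded = np.zeros((ny * s, nx * s), dtype=bool)
        padded[: mask.shape[0], : mask.shape[1]] = mask
        blocks = padded.reshape(ny, s, nx, s).any(axis=(1, 3))
        sizes.append(s)
        counts.append(int(blocks.sum()))
        s *= 2
    if len(sizes) < 2:
        raise ValueError("mask too small for a box-count fit")
    slope = np.polyfit(np.log(sizes), np.log(counts), 1)[0]
    return float(-slope)


def mean_intensity(image: np.ndarray, roi: np.ndarray | None = None) -> float:
    """Mean gray value within an ROI; stacks average per-slice means."""
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        return float(np.mean([mean_intensity(s, roi) for s in img]))
    if roi is None:
        roi = np.ones_like(img, dtype=bool)
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("ROI is empty")
    return float(img[roi].mean())


def analyze_matrix(
    image: np.ndarray,
    roi: np.ndarray | None = None,
    pixel_size: float = 1.0,
    fractal_on_skeleton: bool = True,
) -> dict:
    """Full matrix quantification of one image.

    Thresholds (isodata), then reports percent area in the ROI, the
    box-counting fractal dimension (of the skeletonized mask by default —
    skeletonization precedes the network analysis — or the raw mask), and
    the mean intensity.  The mode used is recorded in the output.
    """
    mm = threshold_matrix(image, pixel_size)
    target = skeletonize(mm.mask) if fractal_on_skeleton else mm.mask
    return {
        "percent_area": percent_area(mm.mask, roi),
        "fractal_dim": box_count_fractal(target),
        "fractal_on_skeleton": fractal_on_skeleton,
        "mean_intensity": mean_intensity(image, roi),
        "threshold": mm.threshold,
        "threshold_method": mm.method,
    }
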