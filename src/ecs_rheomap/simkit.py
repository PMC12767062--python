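"""Synthetic data generation with known ground truth.

Emulates the study's two imaging modalities — quantum-dot (QD) movies sampled
at 28 Hz around amyloid plaques, and carbon-nanotube (SWCNT) trajectories
acquired at 33 ms/frame inside narrow extracellular channels — plus plaque
masks of controlled circularity and extracellular-matrix masks.  All motion is
reflected Brownian dynamics with per-region diffusivity, optional circular
confinement domains, and immobile subpopulations.

Every generator takes an explicit :class:`numpy.random.Generator` (or a seed);
the same seed gives bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special

QD_FRAME_INTERVAL_S = 1.0 / 28.0   # QD movies sampled at 28 Hz
SWCNT_FRAME_INTERVAL_S = 0.033     # SWCNT acquisition, 33 ms exposure
DEFAULT_RING_FACTOR = 1.82         # ring width / core radius, cortical median

RegionLabel = Literal["Out", "Ring", "Amyloid", "WT"]


# ---------------------------------------------------------------------------
# configuration and ground-truth containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    """Acquisition and rendering constants for a simulated experiment.

    Defaults emulate the QD setup: EMCCD sampling at 28 Hz, 160 nm pixels and
    a 130 nm PSF sigma (Nyquist-sampled), 16-bit output.  ``localization_jitter``
    is used only by point-process simulation (no rendering): it is the Gaussian
    observation noise added per frame and per axis, standing in for the
    localization error of the fitting step.
    """

    seed: int = 0
    pixel_size: float = 0.160          # µm / px
    frame_interval: float = QD_FRAME_INTERVAL_S   # s
    n_frames: int = 60
    field_size: tuple[int, int] = (128, 128)      # px (rows, cols)
    psf_sigma: float = 0.130           # µm
    photon_rate: float = 2000.0        # photons / frame / emitter
    background: float = 10.0           # photons / px / frame
    localization_jitter: float = 0.030  # µm

    def __post_init__(self) -> None:
        for name in ("pixel_size", "frame_interval", "psf_sigma"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be a positive integer")
        if self.photon_rate < 0 or self.background < 0 or self.localization_jitter < 0:
            raise ValueError("photon_rate, background and localization_jitter must be >= 0")

    @property
    def field_um(self) -> tuple[float, float]:
        """Field extent in µm, (height, width)."""
        return (self.field_size[0] * self.pixel_size,
                self.field_size[1] * self.pixel_size)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class PlaqueGeometry:
    """Concentric plaque geometry: amyloid core, cell ring, outer shell.

    The ring outer radius follows the cortical scaling in which the cell-ring
    width is ``ring_factor`` (default 1.82) times the core radius.
    """

    center: tuple[float, float]        # µm (x, y)
    core_radius: float                 # µm
    ring_outer_radius: float           # µm
    out_outer_radius: float            # µm

    def __post_init__(self) -> None:
        if not self.core_radius > 0:
            raise ValueError("core_radius must be > 0")
        if not self.ring_outer_radius > self.core_radius:
            raise ValueError("ring_outer_radius must exceed core_radius")
        if not self.out_outer_radius > self.ring_outer_radius:
            raise ValueError("out_outer_radius must exceed ring_outer_radius")

    @classmethod
    def from_core_radius(
        cls,
        core_radius: float,
        center: tuple[float, float] = (0.0, 0.0),
        ring_factor: float = DEFAULT_RING_FACTOR,
        out_factor: float = 2.0,
    ) -> "PlaqueGeometry":
        """Build a geometry from the core radius.

        Ring outer radius = r * (1 + ring_factor); the Out region extends to
        ``out_factor`` times the ring outer radius.
        """
        ring_outer = core_radius * (1.0 + ring_factor)
        return cls(center, core_radius, ring_outer, out_factor * ring_outer)

    def radial_bounds(self, region: str) -> tuple[float, float]:
        """Inner and outer radius (µm) of a region of the plaque."""
        if region == "Amyloid":
            return (0.0, self.core_radius)
        if region == "Ring":
            return (self.core_radius, self.ring_outer_radius)
        if region == "Out":
            return (self.ring_outer_radius, self.out_outer_radius)
        raise KeyError(f"unknown plaque region {region!r}")


@dataclass(frozen=True)
class RegionMotion:
    """Motion parameters for one region.

    ``confinement_radius`` (µm), when finite, confines each particle to a
    reflecting disk of that radius centred on its starting point, in addition
    to the region boundary.  ``immobile_probability`` is the fraction of
    particles born immobile (D = 0).
    """

    D: float                                    # µm²/s
    confinement_radius: float | None = None     # µm, None = unbounded
    immobile_probability: float = 0.0

    def __post_init__(self) -> None:
        if self.D < 0 or not math.isfinite(self.D):
            raise ValueError("D must be finite and >= 0")
        if self.confinement_radius is not None and not self.confinement_radius > 0:
            raise ValueError("confinement_radius must be > 0 when finite")
        if not 0.0 <= self.immobile_probability <= 1.0:
            raise ValueError("immobile_probability must lie in [0, 1]")


@dataclass(frozen=True)
class MotionModel:
    """Per-region motion parameters keyed by region label."""

    regions: Mapping[str, RegionMotion]

    def __getitem__(self, region: str) -> RegionMotion:
        return self.regions[region]

    @classmethod
    def uniform(cls, D: float, **kwargs) -> "MotionModel":
        m = RegionMotion(D=D, **kwargs)
        return cls({r: m for r in ("Out", "Ring", "Amyloid", "WT")})


@dataclass
class GroundTruthTrajectory:
    """One simulated particle: true positions (µm) per frame plus labels."""

    id: int
    region: str
    positions: np.ndarray              # (n_frames, 2) µm
    true_D: float
    mobile: bool

    def observed(self, jitter: float, rng: np.random.Generator) -> np.ndarray:
        """True positions plus isotropic Gaussian observation noise (µm)."""
        if jitter == 0:
            return self.positions.copy()
        return self.positions + rng.normal(0.0, jitter, self.positions.shape)


def trajectories_to_frame(
    trajectories: Sequence[GroundTruthTrajectory],
    frame_interval: float | None = None,
) -> pd.DataFrame:
    """Flatten ground-truth trajectories to the shared CSV table format."""
    rows = []
    for t in trajectories:
        n = len(t.positions)
        rows.append(pd.DataFrame({
            "id": t.id,
            "frame": np.arange(n),
            "x_um": t.positions[:, 0],
            "y_um": t.positions[:, 1],
            "region": t.region,
            "true_D": t.true_D,
            "mobile": t.mobile,
        }))
    out = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["id", "frame", "x_um", "y_um", "region", "true_D", "mobile"])
    if frame_interval is not None:
        out["t_s"] = out["frame"] * frame_interval
    return out


# ---------------------------------------------------------------------------
# plaque geometry sampling
# ---------------------------------------------------------------------------

def sample_core_areas(
    n: int,
    core_area_median: float = 134.2,
    core_area_sigma_log: float = 0.8,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Log-normal amyloid-core surface areas (µm²).

    ``core_area_median`` is the distribution median (the ex vivo cortical
    median by default) and ``core_area_sigma_log`` the SD of log(area).
    """
    if core_area_median <= 0 or core_area_sigma_log < 0:
        raise ValueError("core_area_median must be > 0 and sigma_log >= 0")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    return core_area_median * np.exp(rng.normal(0.0, core_area_sigma_log, n))


def sample_plaque_geometry(
    config: SimConfig,
    core_area_median: float = 134.2,
    core_area_sigma_log: float = 0.8,
    ring_factor: float = DEFAULT_RING_FACTOR,
    out_factor: float = 2.0,
    rng: np.random.Generator | None = None,
) -> PlaqueGeometry:
    """Draw a plaque geometry with a log-normally distributed core area.

    The default median core area (134.2 µm²) matches the ex vivo cortical
    median; ``core_area_sigma_log`` is the SD of log(area).  The core radius
    is the equivalent-circle radius sqrt(A/pi), and the ring follows the
    1.82 width/radius scaling.

    Raises ``ValueError`` if the sampled geometry does not fit in the field.
    """
    rng = config.rng() if rng is None else rng
    area = float(sample_core_areas(1, core_area_median, core_area_sigma_log, rng)[0])
    r = math.sqrt(area / math.pi)
    h, w = config.field_um
    center = (w / 2.0, h / 2.0)
    geom = PlaqueGeometry.from_core_radius(r, center, ring_factor, out_factor)
    half_min = min(h, w) / 2.0
    if geom.out_outer_radius > half_min:
        raise ValueError(
            f"plaque does not fit in field: out_outer_radius "
            f"{geom.out_outer_radius:.2f} µm exceeds half-field {half_min:.2f} µm")
    return geom


# ---------------------------------------------------------------------------
# Brownian dynamics with reflecting boundaries
# ---------------------------------------------------------------------------

def _reflect_radial(pos: np.ndarray, center: np.ndarray,
                    r_in: float, r_out: float) -> np.ndarray:
    """Reflect a point radially into the annulus r_in <= r <= r_out."""
    d = pos - center
    r = math.hypot(d[0], d[1])
    if r_in <= r <= r_out:
        return pos
    for _ in range(64):
        if r > r_out:
            r = 2.0 * r_out - r
        elif r < r_in:
            r = 2.0 * r_in - r
        else:
            break
    # pathological large steps: clamp to the annulus midline
    if not (r_in <= r <= r_out):
        r = 0.5 * (r_in + r_out)
    if r == 0.0:
        return center.copy()
    scale = r / math.hypot(d[0], d[1]) if (d[0] or d[1]) else 0.0
    return center + d * scale


def _auto_substeps(step_sd: float, domain_scale: float, requested: int | None) -> int:
    """Substepping so the sub-step SD stays small against the domain.

    Radial reflection at a curved boundary is only first-order accurate, so
    the per-substep SD is kept below ~8% of the smallest domain dimension
    (capped at 100 substeps/frame); flat-wall or free motion needs none.
    """
    if requested is not None:
        return max(1, int(requested))
    if domain_scale > 0 and step_sd > 0.08 * domain_scale:
        return min(100, math.ceil((step_sd / (0.08 * domain_scale)) ** 2))
    return 1


def _simulate_one(
    start: np.ndarray,
    D: float,
    n_frames: int,
    dt: float,
    rng: np.random.Generator,
    region_center: np.ndarray | None = None,
    region_bounds: tuple[float, float] | None = None,
    confinement_center: np.ndarray | None = None,
    confinement_radius: float | None = None,
    substeps: int | None = None,
) -> np.ndarray:
    """Euler–Maruyama Brownian path with reflecting boundaries.

    Per-axis step SD is sqrt(2 D dt).  Reflection is radial at the region
    annulus and at the per-particle confinement disk.
    """
    if not math.isfinite(D) or D < 0:
        raise ValueError("D must be finite and non-negative")
    pos = np.asarray(start, dtype=float).copy()
    out = np.empty((n_frames, 2))
    out[0] = pos
    if D == 0.0:
        out[:] = pos
        return out
    scales = []
    if region_bounds is not None:
        scales.append(region_bounds[1] - region_bounds[0])
    if confinement_radius is not None:
        scales.append(confinement_radius)
    domain_scale = min(scales) if scales else 0.0
    nsub = _auto_substeps(math.sqrt(2.0 * D * dt), domain_scale, substeps)
    sd = math.sqrt(2.0 * D * dt / nsub)
    steps = rng.normal(0.0, sd, size=((n_frames - 1) * nsub, 2))
    k = 0
    for i in range(1, n_frames):
        for _ in range(nsub):
            pos = pos + steps[k]
            k += 1
            if confinement_radius is not None:
                pos = _reflect_radial(pos, confinement_center, 0.0, confinement_radius)
            if region_bounds is not None:
                pos = _reflect_radial(pos, region_center, *region_bounds)
        out[i] = pos
    return out


def _uniform_in_annulus(rng: np.random.Generator, center: np.ndarray,
                        r_in: float, r_out: float, n: int) -> np.ndarray:
    u = rng.uniform(r_in ** 2, r_out ** 2, n)
    r = np.sqrt(u)
    theta = rng.uniform(0.0, 2.0 * math.pi, n)
    return center + np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def simulate_trajectories(
    geometry: PlaqueGeometry | None,
    motion: MotionModel,
    config: SimConfig,
    n_per_region: int,
    regions: Sequence[str] | None = None,
    rng: np.random.Generator | None = None,
    substeps: int | None = None,
) -> list[GroundTruthTrajectory]:
    """Simulate labelled particles in each plaque region (or free 'WT').

    Particles are born uniformly in their region and never leave it
    (reflecting region boundaries); region labels are fixed at birth so the
    per-ROI ground truth is unambiguous.  'WT' particles have no plaque
    region; they start at the field centre (or diffuse in a confinement disk
    there when the motion model sets one).
    """
    if n_per_region < 0:
        raise ValueError("n_per_region must be >= 0")
    rng = config.rng() if rng is None else rng
    if regions is None:
        regions = [r for r in ("Out", "Ring", "Amyloid", "WT") if r in motion.regions]
    trajs: list[GroundTruthTrajectory] = []
    tid = 0
    h, w = config.field_um
    field_center = np.array([w / 2.0, h / 2.0])
    for region in regions:
        m = motion[region]
        if region == "WT":
            region_center, bounds = None, None
            if m.confinement_radius is not None:
                # equilibrium start: uniform in the confinement disk
                starts = _uniform_in_annulus(rng, field_center, 0.0,
                                             m.confinement_radius, n_per_region)
            else:
                starts = np.tile(field_center, (n_per_region, 1))
        else:
            if geometry is None:
                raise ValueError("plaque regions require a PlaqueGeometry")
            region_center = np.asarray(geometry.center, dtype=float)
            bounds = geometry.radial_bounds(region)
            starts = _uniform_in_annulus(rng, region_center, *bounds, n_per_region)
        for i in range(n_per_region):
            immobile = rng.uniform() < m.immobile_probability
            D = 0.0 if immobile else m.D
            if m.confinement_radius is None:
                conf_center = None
            else:
                conf_center = field_center.copy() if region == "WT" else starts[i].copy()
            pos = _simulate_one(
                starts[i], D, config.n_frames, config.frame_interval, rng,
                region_center=region_center, region_bounds=bounds,
                confinement_center=conf_center,
                confinement_radius=m.confinement_radius,
                substeps=substeps,
            )
            trajs.append(GroundTruthTrajectory(tid, region, pos, D, not immobile))
            tid += 1
    return trajs


def simulate_free_trajectories(
    D: float,
    n_trajectories: int,
    n_frames: int,
    frame_interval: float = QD_FRAME_INTERVAL_S,
    jitter: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> list[GroundTruthTrajectory]:
    """Unconfined 2D Brownian walks (point-process mode, optional jitter).

    When ``jitter`` > 0 the returned positions already include isotropic
    Gaussian observation noise of that SD per axis, emulating localization
    error without rendering a movie.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    trajs = []
    for i in range(n_trajectories):
        pos = _simulate_one(np.zeros(2), D, n_frames, frame_interval, rng)
        if jitter > 0:
            pos = pos + rng.normal(0.0, jitter, pos.shape)
        trajs.append(GroundTruthTrajectory(i, "WT", pos, D, D > 0))
    return trajs


def simulate_channel_trajectories(
    width_nm: float,
    D: float = 0.04,
    n_trajectories: int = 200,
    n_frames: int = 100,
    frame_interval: float = SWCNT_FRAME_INTERVAL_S,
    jitter: float = 0.030,
    rng: np.random.Generator | int | None = None,
    substeps: int = 10,
    angle: float | None = None,
) -> list[GroundTruthTrajectory]:
    """SWCNT-like trajectories in straight channels of a given width.

    The particle diffuses freely along the channel axis and is reflected at
    the channel walls (transverse extent ``width_nm``); the channel is rotated
    by a random angle per trajectory (or a fixed ``angle``, radians).
    ``jitter`` (µm) is observation noise added per axis.  Substepping keeps
    the reflected transverse dynamics accurate when the per-frame step SD is
    comparable to the channel width.
    """
    if width_nm <= 0:
        raise ValueError("width_nm must be > 0")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    half = width_nm / 2000.0            # µm
    sd_sub = math.sqrt(2.0 * D * frame_interval / substeps)
    trajs = []
    for i in range(n_trajectories):
        th = rng.uniform(0.0, 2.0 * math.pi) if angle is None else angle
        # simulate in channel frame: x free, y reflected in [-half, half]
        xy = np.empty((n_frames, 2))
        x = 0.0
        y = rng.uniform(-half, half)
        xy[0] = (x, y)
        steps = rng.normal(0.0, sd_sub, size=((n_frames - 1) * substeps, 2))
        k = 0
        for f in range(1, n_frames):
            for _ in range(substeps):
                x += steps[k, 0]
                y += steps[k, 1]
                k += 1
                # reflect at the walls
                for _ in range(16):
                    if y > half:
                        y = 2.0 * half - y
                    elif y < -half:
                        y = -2.0 * half - y
                    else:
                        break
                y = min(max(y, -half), half)
            xy[f] = (x, y)
        rot = np.array([[math.cos(th), -math.sin(th)],
                        [math.sin(th), math.cos(th)]])
        pos = xy @ rot.T
        if jitter > 0:
            pos = pos + rng.normal(0.0, jitter, pos.shape)
        trajs.append(GroundTruthTrajectory(i, "WT", pos, D, True))
    return trajs


# ---------------------------------------------------------------------------
# movie rendering
# ---------------------------------------------------------------------------

def _pixel_integrated_psf(shape: tuple[int, int], x_px: float, y_px: float,
                          sigma_px: float) -> np.ndarray:
    """2D Gaussian PSF integrated over unit pixels (erf differences)."""
    rows = np.arange(shape[0])
    cols = np.arange(shape[1])
    s = sigma_px * math.sqrt(2.0)
    fx = 0.5 * (special.erf((cols + 0.5 - x_px) / s) - special.erf((cols - 0.5 - x_px) / s))
    fy = 0.5 * (special.erf((rows + 0.5 - y_px) / s) - special.erf((rows - 0.5 - y_px) / s))
    return np.outer(fy, fx)


def render_movie(
    trajectories: Sequence[GroundTruthTrajectory],
    config: SimConfig,
    rng: np.random.Generator | None = None,
    poisson_noise: bool = True,
    bit_depth: int = 16,
) -> tuple[np.ndarray, dict]:
    """Render trajectories into a uint16 image stack with Poisson shot noise.

    Each emitter contributes ``photon_rate`` photons/frame through a pixel-
    integrated Gaussian PSF of ``psf_sigma``; a uniform ``background`` is
    added before Poisson sampling.  Returns ``(stack, metadata)`` where the
    metadata sidecar carries pixel size, frame interval and seed.
    """
    rng = config.rng() if rng is None else rng
    ny, nx = config.field_size
    stack = np.zeros((config.n_frames, ny, nx), dtype=float)
    stack += config.background
    sigma_px = config.psf_sigma / config.pixel_size
    for t in trajectories:
        if len(t.positions) != config.n_frames:
            raise ValueError("trajectory length must equal config.n_frames")
        for f in range(config.n_frames):
            x_um, y_um = t.positions[f]
            x_px = x_um / config.pixel_size
            y_px = y_um / config.pixel_size
            if not (-2 <= x_px <= nx + 1 and -2 <= y_px <= ny + 1):
                raise ValueError(f"trajectory {t.id} leaves the field at frame {f}")
            stack[f] += config.photon_rate * _pixel_integrated_psf((ny, nx), x_px, y_px, sigma_px)
    if poisson_noise:
        stack = rng.poisson(stack).astype(float)
    vmax = 2 ** bit_depth - 1
    if stack.max() > vmax:
        import warnings
        warnings.warn(f"rendered intensities exceed {bit_depth}-bit range; clipping",
                      stacklevel=2)
        stack = np.clip(stack, 0, vmax)
    meta = {
        "pixel_size_um": config.pixel_size,
        "frame_interval_s": config.frame_interval,
        "seed": config.seed,
        "n_frames": config.n_frames,
        "psf_sigma_um": config.psf_sigma,
    }
    return stack.astype(np.uint16), meta


# ---------------------------------------------------------------------------
# plaque masks of controlled circularity
# ---------------------------------------------------------------------------

def _disk_mask(size: int, radius: float, center: tuple[float, float] | None = None) -> np.ndarray:
    c = (size / 2.0, size / 2.0) if center is None else center
    yy, xx = np.mgrid[0:size, 0:size]
    return (xx - c[0]) ** 2 + (yy - c[1]) ** 2 <= radius ** 2


def _blob_mask(size: int, rng: np.random.Generator, roughness: float,
               n_modes: int = 12) -> np.ndarray:
    """Star-shaped blob: disk with Fourier-perturbed radius."""
    base_r = size * 0.22
    yy, xx = np.mgrid[0:size, 0:size]
    c = size / 2.0
    theta = np.arctan2(yy - c, xx - c)
    r = np.hypot(xx - c, yy - c)
    pert = np.zeros_like(theta)
    for k in range(2, 2 + n_modes):
        amp = rng.normal(0.0, roughness / math.sqrt(k))
        phase = rng.uniform(0.0, 2.0 * math.pi)
        pert += amp * np.cos(k * theta + phase)
    boundary = base_r * np.clip(1.0 + pert, 0.15, 2.2)
    return r <= boundary


def _skeleton_mask(size: int, rng: np.random.Generator, n_branches: int = 6,
                   steps: int = 250) -> np.ndarray:
    """Branched random-walk skeleton dilated to ~2 px: filamentous plaque."""
    from scipy import ndimage

    mask = np.zeros((size, size), dtype=bool)
    c = size // 2
    for _ in range(n_branches):
        x, y = float(c), float(c)
        th = rng.uniform(0.0, 2.0 * math.pi)
        for _ in range(steps):
            th += rng.normal(0.0, 0.35)
            x += math.cos(th)
            y += math.sin(th)
            xi, yi = int(round(x)), int(round(y))
            if 1 <= xi < size - 1 and 1 <= yi < size - 1:
                mask[yi, xi] = True
            else:
                break
    return ndimage.binary_dilation(mask, iterations=1)


def generate_plaque_mask(
    target_class: Literal["filamentous", "intermediate", "compact"],
    size: int = 256,
    rng: np.random.Generator | int | None = None,
    max_retries: int = 50,
) -> np.ndarray:
    """Binary plaque mask whose measured circularity falls in the target class.

    Compact plaques are near-circular disks (circularity > 0.28); filamentous
    plaques are dilated branched skeletons (<= 0.14); intermediate plaques are
    rough star-shaped blobs.  The generator draws candidates and re-measures
    circularity with :func:`ecs_rheomap.plaque.circularity` until the class
    matches, erroring after ``max_retries``.
    """
    from ecs_rheomap.plaque import circularity, classify_phenotype, wand_select

    if target_class not in ("filamentous", "intermediate", "compact"):
        raise ValueError(f"unknown phenotype {target_class!r}")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    for attempt in range(max_retries):
        if target_class == "compact":
            mask = _disk_mask(size, size * 0.2 * rng.uniform(0.8, 1.2))
        elif target_class == "filamentous":
            mask = _skeleton_mask(size, rng)
        else:
            mask = _blob_mask(size, rng, roughness=rng.uniform(0.35, 0.65))
        if not mask.any():
            continue
        # keep the component through the centre (or the largest one)
        cy = cx = size // 2
        if not mask[cy, cx]:
            ys, xs = np.nonzero(mask)
            j = np.argmin((ys - cy) ** 2 + (xs - cx) ** 2)
            cy, cx = ys[j], xs[j]
        comp = wand_select(mask, (cy, cx))
        if classify_phenotype(circularity(comp)) == target_class:
            return comp
    raise RuntimeError(
        f"could not generate a {target_class} mask in {max_retries} attempts")


# ---------------------------------------------------------------------------
# extracellular-matrix masks
# ---------------------------------------------------------------------------

def generate_matrix_mask(
    condition: Literal["intact", "degraded", "empty"],
    size: int = 256,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Binary ECM mask: dense reticular net, sparse fragments, or empty.

    'intact' emulates a healthy hyaluronan meshwork — a percolating reticular
    network whose skeleton has box-counting dimension around 1.5–1.7;
    'degraded' keeps only sparse fragments; 'empty' is all background (as in
    the matrix-free amyloid core).
    """
    from scipy import ndimage

    if size < 64:
        raise ValueError("size must be >= 64 px")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if condition == "empty":
        return np.zeros((size, size), dtype=bool)
    noise = rng.normal(size=(size, size))
    smooth = ndimage.gaussian_filter(noise, sigma=3.0)
    if condition == "intact":
        # ridge network: pixels near the zero level-set of the smoothed field
        level = np.quantile(smooth, 0.5)
        band = np.abs(smooth - level) < 0.35 * smooth.std()
        return band
    if condition == "degraded":
        thr = np.quantile(smooth, 0.92)
        frags = smooth > thr
        return ndimage.binary_opening(frags, iterations=1)
    raise ValueError(f"unknown condition {condition!r}")
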