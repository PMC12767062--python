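"""End-to-end orchestration with reproducibility manifests.

One validated configuration drives a full run: ``simulate`` renders a
synthetic QD experiment; ``qd`` runs localize → link → filter → rheology →
per-ROI statistics on a movie; ``swcnt`` runs the elongated-probe local
analysis on a trajectory table; ``morphometry`` and ``matrix`` run the image
branches.  Every run writes a manifest (config snapshot, package version,
seed, input checksums, per-stage record counts, warnings) so deterministic
stages reproduce bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ecs_rheomap import __version__, io, matrixmetrics, nanotube, plaque, rheology, simkit, spt

MODES = ("simulate", "qd", "swcnt", "morphometry", "matrix")


@dataclass
class RunConfig:
    """Typed run configuration; defaults mirror the published analysis."""

    mode: str = "qd"
    seed: int = 0
    input_path: str | None = None
    # acquisition
    pixel_size: float = 0.160              # µm/px
    frame_interval: float = 1.0 / 28.0     # s (28 Hz QD sampling)
    # localization / linking
    threshold_k: float = 3.0
    detection_scale: int = 2
    max_displacement: float = 1.0          # µm
    max_gap: int = 0
    min_points: int = 11                   # "> 10 points" rule
    # rheology
    fit_points: int = 4
    window: tuple[float, float] = (0.6, 0.8)   # s
    immobile_threshold: float = 0.005      # µm²/s
    # plaque ROIs
    ring_factor: float = 1.82
    # SWCNT branch
    swcnt_frame_interval: float = 0.033    # s
    dinst_window: int = 10
    dinst_fit_points: int = 3
    ecc_window: int = 6
    precision_um: float = 0.030            # Δx = 30 nm
    # simulate mode
    n_frames: int = 60
    n_per_region: int = 20

    def validate(self) -> list[str]:
        errors = []
        if self.mode not in MODES:
            errors.append(f"mode must be one of {MODES}, got {self.mode!r}")
        for name in ("pixel_size", "frame_interval", "max_displacement",
                     "swcnt_frame_interval", "ring_factor"):
            if not getattr(self, name) > 0:
                errors.append(f"{name} must be > 0")
        for name in ("immobile_threshold", "precision_um", "threshold_k"):
            if getattr(self, name) < 0:
                errors.append(f"{name} must be >= 0")
        for name in ("min_points", "fit_points", "dinst_window",
                     "dinst_fit_points", "ecc_window", "n_frames"):
            if getattr(self, name) < 2 and name != "n_frames":
                errors.append(f"{name} must be >= 2")
        if not self.window[1] > self.window[0]:
            errors.append(f"window must be increasing, got {self.window}")
        if self.max_gap < 0:
            errors.append("max_gap must be >= 0")
        return errors


def validate_config(text: str) -> RunConfig:
    """Parse YAML config text into a validated RunConfig.

    Unknown keys are rejected; all violations are reported together.  An
    empty document yields all defaults.
    """
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    errors = [f"unknown config key: {k!r}" for k in raw if k not in known]
    kwargs = {k: v for k, v in raw.items() if k in known}
    if "window" in kwargs:
        kwargs["window"] = tuple(float(v) for v in kwargs["window"])
    cfg = RunConfig(**kwargs)
    errors.extend(cfg.validate())
    if errors:
        raise ValueError("invalid config:\n" + "\n".join(f"  - {e}" for e in errors))
    cfg._explicit_keys = set(kwargs)  # type: ignore[attr-defined]
    return cfg


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute one run; write stage outputs and the manifest to ``out_dir``.

    Returns the manifest dict.  Stage failures abort with the stage name in
    the exception message.
    """
    errs = config.validate()
    if errs:
        raise ValueError("invalid config: " + "; ".join(errs))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    explicit = getattr(config, "_explicit_keys", set())
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "mode": config.mode,
        "config": {f.name: getattr(config, f.name) for f in dataclasses.fields(config)},
        "defaulted_keys": sorted(
            f.name for f in dataclasses.fields(config) if f.name not in explicit),
        "input_checksums": {},
        "counts": {},
        "warnings": [],
    }
    manifest["config"]["window"] = list(config.window)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            if config.mode == "simulate":
                _run_simulate(config, out, manifest)
            elif config.mode == "qd":
                _run_qd(config, out, manifest)
            elif config.mode == "swcnt":
                _run_swcnt(config, out, manifest)
            elif config.mode == "morphometry":
                _run_morphometry(config, out, manifest)
            elif config.mode == "matrix":
                _run_matrix(config, out, manifest)
        except Exception as exc:
            raise RuntimeError(f"stage failure in mode {config.mode!r}: {exc}") from exc
        manifest["warnings"] = [str(w.message) for w in caught]
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest


def _require_input(config: RunConfig, manifest: dict) -> Path:
    if not config.input_path:
        raise ValueError("this mode requires input_path")
    p = Path(config.input_path)
    if not p.exists():
        raise FileNotFoundError(p)
    manifest["input_checksums"][str(p)] = _checksum(p)
    return p


def _run_simulate(config: RunConfig, out: Path, manifest: dict) -> None:
    sim = simkit.SimConfig(seed=config.seed, pixel_size=config.pixel_size,
                           frame_interval=config.frame_interval,
                           n_frames=config.n_frames)
    rng = sim.rng()
    # core sized so the Out annulus stays inside the rendered field
    core_r = 0.10 * min(sim.field_um)
    geom = simkit.PlaqueGeometry.from_core_radius(
        core_r, (sim.field_um[1] / 2, sim.field_um[0] / 2), config.ring_factor, 1.6)
    motion = simkit.MotionModel({
        "Out": simkit.RegionMotion(D=0.07),
        "Ring": simkit.RegionMotion(D=0.068),
        "Amyloid": simkit.RegionMotion(D=0.058, immobile_probability=0.3),
    })
    trajs = simkit.simulate_trajectories(geom, motion, sim, config.n_per_region, rng=rng)
    truth = simkit.trajectories_to_frame(trajs, sim.frame_interval)
    io.write_table(out / "ground_truth.csv", truth)
    stack, meta = simkit.render_movie(trajs, sim, rng=rng)
    io.write_movie(out / "movie.tiff", stack, meta)
    with open(out / "roi.json", "w") as fh:
        json.dump({"center_um": list(geom.center),
                   "core_radius_um": geom.core_radius,
                   "ring_factor": config.ring_factor,
                   "out_bound_um": geom.out_outer_radius}, fh, indent=2)
    manifest["counts"] = {"n_trajectories": len(trajs),
                          "n_frames": config.n_frames}


def _run_qd(config: RunConfig, out: Path, manifest: dict) -> None:
    p = _require_input(config, manifest)
    stack, meta = io.read_movie(p)
    pixel_size = float(meta.get("pixel_size_um", config.pixel_size))
    frame_interval = float(meta.get("frame_interval_s", config.frame_interval))
    locs = spt.localize_movie(stack, pixel_size, config.detection_scale,
                              config.threshold_k)
    io.write_table(out / "localizations.csv", locs)
    linked = spt.link_trajectories(locs, config.max_displacement, config.max_gap)
    kept = spt.filter_trajectories(linked, config.min_points)
    io.write_table(out / "trajectories.csv", kept[io.TRAJECTORY_COLUMNS])
    records = rheology.analyze_table(
        kept, frame_interval, n_fit_points=config.fit_points,
        window=config.window, immobile_threshold=config.immobile_threshold)
    # per-ROI labelling when an ROI file sits beside the movie
    roi_path = p.parent / "roi.json"
    if roi_path.exists():
        with open(roi_path) as fh:
            rd = json.load(fh)
        roi = plaque.build_concentric_rois(
            (tuple(rd["center_um"]), rd["core_radius_um"]),
            rd.get("ring_factor", config.ring_factor), rd.get("out_bound_um"))
        firsts = kept.groupby("traj_id")[["x_um", "y_um"]].first()
        labels = roi.label_points(firsts.to_numpy())
        records["roi"] = records["traj_id"].map(
            dict(zip(firsts.index, labels))).replace("", "Out")
        dens = plaque.localization_density(kept[["x_um", "y_um"]].to_numpy(), roi)
        dens["ratio_out_ring"] = plaque.penetrability_ratio(dens, "Out/Ring")
        dens["ratio_ring_amyloid"] = plaque.penetrability_ratio(dens, "Ring/Amyloid")
        io.write_table(out / "density.csv", dens)
    io.write_table(out / "rheology.csv", records)
    summary = records.groupby("roi").agg(
        n=("traj_id", "size"), median_D=("D_inst", "median"),
        median_confinement=("confinement_um2", "median"),
        immobile_fraction=("mobile", lambda m: float((~m).mean()))).reset_index()
    io.write_table(out / "summary.csv", summary)
    manifest["counts"] = {
        "n_localizations": len(locs), "n_trajectories": linked["traj_id"].nunique(),
        "n_retained": kept["traj_id"].nunique(),
        "n_per_roi": records["roi"].value_counts().to_dict(),
    }


def _run_swcnt(config: RunConfig, out: Path, manifest: dict) -> None:
    p = _require_input(config, manifest)
    trajs = io.read_table(p)
    kept, report = nanotube.exclude_immobile(trajs, config.swcnt_frame_interval)
    io.write_table(out / "mobility_report.csv", report)
    maps = []
    for tid, g in kept.groupby("traj_id"):
        pos = g.sort_values("frame")[["x_um", "y_um"]].to_numpy()
        if len(pos) < config.dinst_window:
            continue
        m = nanotube.local_map(pos, config.swcnt_frame_interval,
                               config.precision_um, config.dinst_window,
                               config.dinst_fit_points, config.ecc_window)
        m.insert(0, "traj_id", tid)
        maps.append(m)
    local = pd.concat(maps, ignore_index=True) if maps else pd.DataFrame()
    io.write_table(out / "local_map.csv", local)
    manifest["counts"] = {"n_input": trajs["traj_id"].nunique(),
                          "n_mobile": kept["traj_id"].nunique(),
                          "n_windows": len(local)}


def _run_morphometry(config: RunConfig, out: Path, manifest: dict) -> None:
    p = _require_input(config, manifest)
    stack, meta = io.read_movie(p)
    pixel_size = float(meta.get("pixel_size_um", config.pixel_size))
    proj = plaque.max_projection(stack)
    t = plaque.isodata_threshold(proj)
    mask = proj > t
    ys, xs = np.nonzero(mask)
    if len(ys) == 0:
        raise ValueError("no foreground after thresholding")
    # seed the wand at the brightest foreground pixel
    j = np.argmax(proj[ys, xs])
    comp = plaque.wand_select(mask, (int(ys[j]), int(xs[j])))
    c = plaque.circularity(comp, pixel_size)
    area = float(comp.sum()) * pixel_size ** 2
    r = plaque.area_to_radius(area)
    row = pd.DataFrame([{
        "plaque_id": 0, "A_core_um2": area, "r_um": r,
        "circularity": c, "phenotype": plaque.classify_phenotype(c),
        "threshold": t,
    }])
    io.write_table(out / "morphometry.csv", row)
    manifest["counts"] = {"n_plaques": 1, "component_px": int(comp.sum())}


def _run_matrix(config: RunConfig, out: Path, manifest: dict) -> None:
    p = _require_input(config, manifest)
    stack, meta = io.read_movie(p)
    img = stack if stack.ndim == 2 else stack.max(axis=0)
    res = matrixmetrics.analyze_matrix(
        img, pixel_size=float(meta.get("pixel_size_um", config.pixel_size)))
    io.write_table(out / "matrix_metrics.csv", pd.DataFrame([res]))
    manifest["counts"] = {"n_images": 1}
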