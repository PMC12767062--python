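"""One-time calibration of the local ECS width estimator.

Simulates straight-channel trajectories at known widths spanning the
physiological range (60–140 nm) under the SWCNT acquisition conditions
(33 ms frames, D = 0.04 µm²/s, 30 nm localization noise), runs the
max-confinement width estimator with calibration factor 1, and reports the
multiplicative factor (median of true/raw over the width grid) that is
frozen into ``ecs_rheomap.nanotube.WIDTH_CALIBRATION``.

Run:  python scripts/calibrate_width.py
"""

import numpy as np

from ecs_rheomap import nanotube, simkit

CALIBRATION_SEED = 424242
WIDTHS_NM = (60.0, 78.0, 100.0, 140.0)
N_TRAJECTORIES = 150
N_FRAMES = 100


def main() -> None:
    rng = np.random.default_rng(CALIBRATION_SEED)
    ratios = []
    for w in WIDTHS_NM:
        trajs = simkit.simulate_channel_trajectories(
            w, D=0.04, n_trajectories=N_TRAJECTORIES, n_frames=N_FRAMES,
            jitter=nanotube.DEFAULT_PRECISION_UM, rng=rng)
        est = []
        for t in trajs:
            e = nanotube.trajectory_width(t.positions, calibration=1.0)
            if e is not None:
                est.append(e.width_nm)
        raw = float(np.median(est))
        ratios.append(w / raw)
        print(f"width {w:6.1f} nm: raw median {raw:6.1f} nm  true/raw {w / raw:.4f}")
    factor = float(np.median(ratios))
    print(f"\ncalibration factor (median true/raw): {factor:.4f}")
    print("frozen as ecs_rheomap.nanotube.WIDTH_CALIBRATION")


if __name__ == "__main__":
    main()
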