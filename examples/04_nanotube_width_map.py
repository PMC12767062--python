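"""Local ECS width from elongated-probe (nanotube-style) trajectories.

A probe diffusing inside a narrow extracellular channel explores an
elongated area; the 6-point eccentricity window finds the most confined
stretch and the transverse spread there, noise-subtracted and scaled by
sqrt(12) (uniform occupancy), reads out the local channel width.
"""

import numpy as np

from ecs_rheomap import nanotube, simkit

DT = 0.033   # 33 ms frames

trajs = simkit.simulate_channel_trajectories(
    78.0, D=0.04, n_trajectories=100, n_frames=100, jitter=0.030, rng=4)

widths = [nanotube.trajectory_width(t.positions).width_nm for t in trajs]
print(f"simulated channel width 78 nm -> median estimate {np.median(widths):.1f} nm "
      f"over {len(widths)} trajectories (30 nm localization noise)")

m = nanotube.local_map(trajs[0].positions, DT)
sel = m[m["width_nm"].notna()].iloc[0]
print(f"\none trajectory's local map has {len(m)} windows; max-confinement "
      f"window {int(sel.window_index)} (eccentricity {sel.eccentricity:.2f}) "
      f"reports width {sel.width_nm:.0f} nm")
print(f"median local D_inst along it: {m['local_D'].median():.4f} µm²/s "
      "(10-frame sliding MSD, 3-point fits)")

print(f"\nnoise floor on local D_inst at 30 nm precision: "
      f"{nanotube.dinst_error(0.030):.3f} µm²/s (Δx²/t)")
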