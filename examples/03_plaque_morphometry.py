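"""Plaque morphometry and circularity phenotyping.

Circle-approximation geometry (A = πr²) converts measured core and ring
surfaces into radii and ring widths; concentric Amyloid/Ring/Out ROIs then
quantify probe penetrability, and the 4πA/P² circularity score classifies
plaque phenotypes.
"""

import numpy as np

from ecs_rheomap import plaque, simkit

# --- circle approximation on a typical cortical plaque -------------------
a_core = 81.71                      # µm², equivalent radius 5.1 µm
a_ring = a_core * ((1 + 1.82) ** 2 - 1)   # ring at the 1.82 width/radius scaling
r = plaque.area_to_radius(a_core)
w = plaque.ring_width(a_core, a_ring)
print(f"core area {a_core:.1f} µm² -> radius {r:.2f} µm; "
      f"ring width {w:.2f} µm (w/r = {w/r:.2f})")
print(f"whole plaque occupies {plaque.volume_ratio(a_core, a_ring):.1f}x "
      "the core volume (spherical approximation)")

# --- penetrability of a uniformly accessible field -----------------------
rng = np.random.default_rng(3)
roi = plaque.build_concentric_rois(((0.0, 0.0), r))
L = roi.out_outer_radius
pts = rng.uniform(-L, L, (20_000, 2))
dens = plaque.localization_density(pts, roi)
print("\nuniform points over the ROI field:")
print(dens.to_string(index=False))
print(f"Out/Ring density ratio = "
      f"{plaque.penetrability_ratio(dens, 'Out/Ring'):.3f} "
      "(1 means free exchange; >>1 means the inner region excludes the probe)")

# --- circularity phenotyping ---------------------------------------------
for phenotype in ("compact", "intermediate", "filamentous"):
    mask = simkit.generate_plaque_mask(phenotype, size=192, rng=rng)
    c = plaque.circularity(mask)
    print(f"generated {phenotype:12s} mask: circularity {c:.3f} -> "
          f"classified {plaque.classify_phenotype(c)}")
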