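"""Extracellular-matrix quantification: percent area, skeleton, fractal.

Compares an intact reticular matrix mask with a degraded and an empty one,
the three regimes seen across healthy tissue, peri-plaque tissue and the
matrix-free amyloid core.
"""

import numpy as np

from ecs_rheomap import matrixmetrics, simkit

rng = np.random.default_rng(5)
for condition in ("intact", "degraded", "empty"):
    mask = simkit.generate_matrix_mask(condition, size=256, rng=rng)
    pa = matrixmetrics.percent_area(mask)
    sk = matrixmetrics.skeletonize(mask)
    fd = matrixmetrics.box_count_fractal(sk)
    print(f"{condition:9s}: {pa:5.1f}% area, skeleton fractal dimension {fd:.2f}")

print("\nfractal dimension ~1.5-1.7 marks an interconnected meshwork; "
      "0 is the empty-mask convention (no signal, no structure).")

img = np.where(simkit.generate_matrix_mask("intact", 256, rng=rng), 180.0, 30.0)
img += rng.normal(0, 3, img.shape)
res = matrixmetrics.analyze_matrix(img)
print(f"\nfull analysis of a synthetic stained image: "
      f"threshold {res['threshold']:.1f} ({res['threshold_method']}), "
      f"{res['percent_area']:.1f}% area, fractal {res['fractal_dim']:.2f}, "
      f"mean intensity {res['mean_intensity']:.1f}")
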