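# Methods

## Scope and data model

The package analyses 2D single-particle trajectories of extracellular probes
in brain tissue and the geometry of the structures that shape them. All
positions are in µm (pixel centres at integer indices, origin top-left,
x = column); trajectories are tables `(traj_id, frame, x_um, y_um)`; movies
are multi-page TIFFs with a YAML sidecar carrying `pixel_size_um`,
`frame_interval_s` and the generator seed.

## Synthetic data (`simkit`)

The generator emulates the two acquisition modalities the analysis was built
for, with ground truth attached to every particle.

**Motion.** Euler–Maruyama Brownian steps with per-axis SD
`sqrt(2 D Δt)`; reflecting boundaries implement confinement. Region
membership (Amyloid / Ring / Out annuli, or free "WT") is fixed at birth and
enforced by reflection, so per-ROI labels are unambiguous. Immobile
particles have D = 0 exactly; apparent jitter arises only at observation
(rendering noise or explicit Gaussian jitter in point-process mode).

*Substepping.* Radial reflection at a curved wall is only first-order
accurate, so frames are internally subdivided until the per-substep SD is
≤ 8% of the smallest domain dimension (cap 100/frame). A fixed 10×
subdivision leaves a ≈6% deficit in the reflecting-disk MSD plateau; the
adaptive rule brings the plateau within 2% of the analytic value
E|P₁−P₂|² = R². Straight channel walls are flat, so channel simulations use
a fixed 10× subdivision. Confined particles start uniformly in their domain
(the stationary distribution), avoiding an equilibration transient.

**Acquisition defaults.** QD-like movies: 28 Hz, 160 nm pixels, PSF sigma
130 nm (Nyquist-sampled), 16-bit; photon budget 2000 photons/frame/emitter
over 10 photons/px/frame background, Poisson shot noise, pixel-integrated
Gaussian PSF (erf differences). SWCNT-like trajectories: 33 ms frames,
channels 50–150 nm wide, 30 nm observation noise. The probe density and
photon counts are package choices (documented here, not measured values);
they put the localizer in its comfortable SNR regime (precision ≪ pixel).

**Geometry.** Core areas are log-normal (median 134.2 µm², σ_log 0.8 —
median from cortical measurements, spread a package choice in the observed
range); radii derive from A = πr² and the ring from the 1.82 width/radius
scaling. Plaque masks of controlled circularity: disks (compact), dilated
branched random walks (filamentous), Fourier-perturbed blobs (intermediate),
re-measured and re-drawn until the requested class is met. Matrix masks:
the near-zero level set of a smoothed Gaussian random field gives a
percolating reticular network whose skeleton has box-counting dimension
≈ 1.5–1.7; a high-quantile threshold gives sparse fragments ("degraded").

**What the generator does not emulate.** No blinking/bleaching, no axial
(3D) structure, no vessel shadows, no spatially varying background, and
channels are straight. Passing recovery tests on these data shows the
estimators are correct under their stated models — not that real tissue
satisfies those models.

## Localization and linking (`spt`)

Detection: à-trous B3-spline wavelet band at scale 2, thresholded at
k = 3 robust noise SDs (1.4826·MAD), regions < 4 px rejected, brightest
pixel per region kept. Refinement: least-squares symmetric 2D Gaussian
(amplitude, centre, sigma, offset) in a 7×7 window; fits rejected when
sigma ∉ [0.5, 5] px or window R² < 0.5; border windows are truncated and
flagged. On rendered movies at SNR ≥ 10 this yields ≥ 95% recall and RMSE
well under ¼ pixel.

Linking minimises total squared displacement per frame pair (Hungarian
algorithm) with a hard displacement gate and optional gap closing
(default max_gap = 0); unmatched localizations start new tracks, each
localization is used once, ties resolve by (frame, id) order. Per-frame-pair
optimal assignment equals the global optimum when no births/deaths compete
across frames; it is verified against exhaustive enumeration on all small
instances. Only tracks with > 10 points (≥ 11) are analysed — the filter
threshold is a config knob.

Localization precision is the coordinate SD of an immobile emitter over
~50 frames. Immobility is accepted when the median windowed D (10-frame
windows, 3-point fits, floored at 0) is below 0.005 µm²/s **or** the global
MSD is flat (late/early < 2 on lags ≤ span/2). The second clause matters at
large noise: a 60 nm jitter alone pushes short-lag fit noise past the
0.005 µm²/s threshold even though the emitter is stationary.

## MSD rheology (`rheology`)

* Time-averaged MSD over **all** ordered pairs per lag (maximal use of
  ≥ 11-point tracks); gaps handled by frame-difference lags. Ensemble curves
  average per-trajectory MSDs with equal weight.
* D_inst: OLS with free intercept on the first 4 lags, D = slope/4.
  Negative slopes floor to 0 and are flagged (and counted immobile).
* Confinement area: unweighted mean of MSD values with lag in the **closed**
  window [0.6, 0.8] s — at 28 Hz, frame lags 17–22 (0.607–0.786 s).
  Reported per trajectory only when the track spans 0.8 s.
* Mobility: immobile iff D_inst < 0.005 µm²/s, strictly ("lower than").
* Immobile fractions are per field of view; a FOV enters the analysis only
  if its Amyloid ROI holds ≥ 1 immobile particle, and exclusion applies to
  all ROIs of that FOV.
* Relative change: 100·(x−y)/(0.5·(x+y)), x = outermost compartment.
  The statistic is antisymmetric, so the opposite convention is the swapped
  call; published compartment comparisons are ambiguous about the sign
  convention actually used (stated outer-minus-inner, yet negative medians
  reported where inner values are smaller), so both orderings are exposed
  rather than guessing.

## Plaque geometry (`plaque`)

Concentric ROIs from a core (parametric or mask; mask cores use the
equivalent-area radius and centroid): ring outer radius = r(1 + 1.82), Out
bound = 2× ring outer radius by default (the outer bound is not a measured
quantity; the default is logged and clipped to the field with a flag).
Boundary points are assigned to the inner region (closed inner intervals) —
a deterministic tie-break. Densities count localizations, not trajectories.

Circularity uses the traced boundary polygon (marching-squares 0.5-contour
through pixel-edge midpoints, diagonal segments weighing 1/√2 per
half-pixel) — the ImageJ-style outline. The estimator converges to ≈ 0.9 on
rasterized disks (contour polygons overestimate smooth perimeters by a few
percent); exact parity with any particular shape-descriptor implementation
is not claimed, and the classification thresholds (0.14 / 0.28, left-closed)
sit far from that discretization effect. A single isolated pixel is scored
by its unit-square boundary (C = 4π/16) and flagged. The isodata threshold
is the Ridler–Calvard intermeans fixed point computed on raw values (exact
on two-level images). Log-normality of area distributions uses the
D'Agostino–Pearson omnibus test on log areas (n ≥ 8).

The sphere-volume helper reports the exact cube ratio (R_tot/r)³; printed
round-number volume factors in the literature differ from the exact cube of
their own medians, so no specific value is targeted.

## Local ECS width (`nanotube`)

Local D_inst: 10-frame sliding MSD windows, OLS on the first 3 lags,
D = slope/4, step 1 frame. Immobile nanotubes are excluded on the plateau
shape of their global MSD (late/early < 2 on lags ≤ span/2, or global
D < 0.005 µm²/s); both criteria are reported per trajectory.

Shape analysis: per 6-point window, eccentricity = sqrt(λ_major/λ_minor) of
the position covariance, with λ_minor floored at Δx² (numerical stability
with 6 points; exactly collinear windows with zero floor flag as infinite).
The maximum-confinement window (largest finite eccentricity, earliest on
ties) locates the most constrained stretch of the trajectory.

**Width estimator.** Under uniform transverse occupancy of a channel,
width = sqrt(12)·σ_ch with σ_ch² = σ_⊥² − Δx² (quadrature noise
subtraction). The transverse variance is measured over a 30-frame (~1 s)
neighbourhood centred on the selected window, not over the 6 points
themselves: at Δx = 30 nm the transverse spread of a sub-100-nm channel
(σ ≤ 30 nm) is at or below the noise, and a 5-dof sample minor eigenvalue
under max-eccentricity selection saturates near the noise floor regardless
of the true width — no single scale factor can linearize it. The 30-frame
support keeps the estimate local while giving the variance enough degrees
of freedom; its residual bias is corrected by a single multiplicative
calibration factor (1.1139) determined once on straight-channel simulations
at widths 60–140 nm (seed 424242, `scripts/calibrate_width.py`) and frozen.
Estimates whose spread does not exceed the noise floor are flagged "below
resolution". With the frozen factor, median recovery at an independent seed
is within 10% across 60–140 nm. Exact parity with published width maps is
not claimed: the original estimator is described elsewhere and this one is
a declared substitute.

Error model: ΔD_inst = Δx²/t (t = fitted window duration); 30 nm and
3 × 30 ms give 0.01 µm²/s.

Drift correction subtracts the per-frame mean displacement of designated
non-mobile reference particles from all trajectories; with no references the
data pass through unchanged with a warning.

## Matrix metrics (`matrixmetrics`)

Isodata threshold (recorded in the output), percent foreground per ROI,
topology-preserving skeletonization, and box-counting dimension over dyadic
box sizes {2, 4, …, side/4} (grid anchored at the origin; offset averaging
available but off by default), −slope of the OLS fit of log N(s) vs log s.
Empty masks score 0 by convention. The fractal dimension is computed on the
skeletonized mask by default (skeletonization precedes the network
analysis), with a raw-mask flag; the mode used is recorded. Validation
targets are analytic: a straight line (1), a filled plane (2), and a
depth-4 Sierpinski carpet (log 8/log 3 ≈ 1.893) rasterized at 3 px per
finest cell so the smallest boxes resolve the finest holes — at 1 px per
cell the 2-px boxes saturate and bias the slope low.

## Pipeline and reproducibility

A single validated config (YAML; unknown keys rejected, all violations
reported together) drives each mode; every run writes a manifest with the
config snapshot, defaulted keys, package version, seed, input SHA-256
checksums, per-stage record counts and captured warnings. Fixed seeds
reproduce trajectory and summary CSVs byte-identically. All module defaults
mirror the published analysis constants (28 Hz; 4-point fit; [0.6, 0.8] s;
0.005 µm²/s; ≥ 11 points; ring factor 1.82; 10-frame/3-point sliding fit;
6-point shape window; Δx = 30 nm; 33 ms SWCNT frames) and are asserted by a
defaults test.

## Problem sizes

Recovery checks use 500 free trajectories × 60 frames (diffusion), 300
confined trajectories × 80 frames (confinement), 200 channel trajectories ×
100 frames (width), and 20,000 points (penetrability) — sizes at which the
medians' sampling error is several times smaller than the tolerance being
checked. The full test suite runs in well under a minute; the acceptance
script in a few seconds.

## Known limitations

* The detector is a parameterized wavelet detector, not a clone of any
  specific SPT software; linking is globally optimal assignment rather than
  simulated annealing (deterministic and oracle-testable).
* Perimeter, isodata and fractal estimators are principled implementations,
  not bit-exact replicas of Fiji plugins; regime agreement, not parity, is
  the claim.
* Width estimation assumes locally straight channels and uniform transverse
  occupancy; the calibration factor is tied to the stated acquisition
  conditions (33 ms, D ≈ 0.04 µm²/s, Δx ≈ 30 nm) and should be re-derived
  for substantially different ones.
* No 3D localization, no drift correction in the QD branch (applied only in
  the nanotube branch, as in the original analysis), no photophysics.
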