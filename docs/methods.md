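# Methods

This note documents the models, numerical choices and limitations behind
each stage of the pipeline, and what the synthetic generators do and do not
emulate.

## Geometry from sparse contour stacks

A cross-section is a planar simple polygon in 3D (validated: ≥3 vertices,
coplanar within 1e-6 mm of its least-squares plane, non-self-intersecting
via shapely).  Area and centroid come from the planar shoelace formula after
projection onto the best-fit plane; the absolute value makes the result
independent of vertex winding.

**Densification.**  The interpolation scheme between sparse slices is not
uniquely determined by the measurement concept, so a deliberately simple
correspondence is used, adequate for convex, tube-like tendon sections:
each contour is resampled to a common vertex count (default 96) uniformly by
perimeter arc length, oriented counter-clockwise about a normal aligned with
the distal→proximal path, phase-aligned by polar angle about its planar
centroid in a stack-consistent frame, and finally cyclically rolled to
minimise the summed squared vertex distance to its distal neighbour.
Corresponding vertices are then linearly interpolated at stations along the
centroid chord path.  The station spacing is the requested value adjusted to
divide each total chord length evenly (so sparse slices land exactly on
stations); interpolated polygons are re-projected onto their own best-fit
plane, which matters only on curved paths where lerped vertices are very
slightly non-planar.  Defaults: 0.27 mm spacing for MRI-resolution work,
0.063 mm for freehand 3D ultrasound; both overridable.  On strongly
non-convex or twisting cross-sections the polar-angle correspondence can
shear the interpolated surface; tendon sections in practice are near-convex.

**Metrics.**  Length is the cumulative centroid-to-centroid distance, volume
the trapezoid rule over slice areas along that same path — the two
definitions are mutually consistent, so average CSA = V/L holds exactly by
construction.  The regional CSA profile linearly interpolates slice area
against cumulative centroid arc length on a fixed 101-point grid with 0% at
the distal (calcaneal) end.  With 96-vertex polygons the inscribed-polygon
area deficit is ≈0.07%, well inside the 0.5% phantom tolerances used in the
tests.

## Moment arm

The talar-dome cylinder fit minimises Σ(distance-to-axis − r)² with
parameters (two axis angles, two in-plane offsets, radius) by
`scipy.optimize.least_squares`.  Initialisation matters on partial arcs: the
axis candidate is the PCA direction whose orthogonal-distance spread about
the median is smallest (the naive smallest-eigenvalue rule fails on
patches), and the in-plane centre/radius come from an algebraic (Kåsa)
circle fit of the projected points — without this, 60° arcs collapse into a
small-cylinder local minimum.  Each of up to three seeded restarts runs the
optimiser twice (the second call restarts the trust region and polishes to
machine precision); collinear clouds are rejected up front.

The fitted axis is represented as a segment spanning the orthogonal
projections of the dome points onto the axis.  Axis segment and tendon
centroid line are interpolated with natural cubic splines parameterised by
cumulative chord length; the minimum distance is located on a 2000×2000
sample grid and refined by bounded L-BFGS-B in the two arc-length
parameters, with ties broken toward the smallest parameter pair.  The
refined minimum is accepted only if it does not exceed the dense-grid
minimum.  Results are reported in cm.  Only a static, neutral-ankle
geometric moment arm is modelled — no tendon-excursion or load dependence.

## T2* relaxometry

Model: `S(TE) = S₀·exp(−TE/T2*) + b`, magnitude signal, with the additive
`b` absorbing the noise floor.  Stage one is a log-linear least-squares fit
of ln S on TE (no bias term) that flags non-decaying pixels; stage two is a
bounded Levenberg–Marquardt fit (lmfit) started from stage one, with
T2* ∈ (0.01, 200] ms, S₀ > 0, b ≥ 0.  The bias start value is half the
minimum measured signal — starting exactly at the zero bound stalls the
bounded-transform optimiser.  ROI summaries average converged pixels whose
T2* is strictly inside the bounds; excluded pixels are counted so users can
audit the mask.

**Known estimator property.**  With echo trains that reach only ≈1×T2*
(both built-in protocols at tendon-like T2* ≈ 10 ms), the three-parameter
likelihood is ill-conditioned along a T2*–bias trade-off.  At SNR 50 the
per-pixel maximum-likelihood estimate is *median*-unbiased but its *mean*
sits ≈4% low; a wide-range brute-force grid search confirms the optimiser
reaches the global optimum, so this is a property of the estimator, not of
the implementation.  Averaging over an ROI therefore carries this small
systematic skew at low SNR; group *comparisons* are unaffected because both
arms share it.  Only the mono-exponential model is implemented; fast/slow
bi-exponential decomposition is out of scope.

## Mechanics

Per condition: net torque = torque under load − torque at rest; force = net
torque / moment arm; elongation and strain are referenced to the resting
length; "true" stress divides force by the CSA measured under that load.
The linear region is operationalised as exactly the three loaded conditions
(25/50/70% MVC) — the rest point is excluded because including (0,0) would
contaminate the slope with toe-region behaviour.  Stiffness is the OLS slope
of force (N) vs elongation (mm); modulus the OLS slope of stress (MPa) vs
strain (fraction) divided by 1000 (GPa); normalised stiffness is
stiffness·L₀/1000 (kN/strain), exact by construction.  Strain is stored as a
fraction and rendered as % only for display.  Replicate trials at a level
are averaged before fitting by default; a per-trial mode is provided because
either convention is defensible.

## Group statistics

Scalar endpoints use a classical one-way F-test (η² = SS_between/SS_total,
equal to F/(F+df₂) for two groups), replaced by tie-corrected
Kruskal–Wallis (η² = (H−k+1)/(n−k)) when either group fails Shapiro–Wilk at
α = 0.05; the gate is overridable.  η² values are reported at full
precision.  Multiple endpoints are tested without family-wise correction,
matching common practice for descriptive cohort tables.

**1D SPM.**  Profiles are compared pointwise with the two-sample t statistic;
field-wise inference is permutation-based by default: group labels are
permuted (exhaustively when the design admits fewer distinct assignments
than requested, with a warning below 100), the max-|t| distribution sets the
critical threshold at α, and supra-threshold clusters get p-values from the
permutation distribution of maximal cluster mass (integral of |t| above the
threshold).  The observed labelling is always included in the null set, so
p ≥ 1/P.  A parametric alternative estimates the field smoothness (FWHM)
from normalised residual gradients and solves the 1D random-field
expected-Euler-characteristic equation for the threshold; cluster p-values
still come from permutation.  Calibration at n = 16+16 with 200 permutations
gives a field-wise type-I error within ±0.02 of the nominal 0.05 (measured
over 500 simulated null cohorts) and essentially full power to localise a
2 SD difference confined to the distal 30% of length.

## Synthetic generators

The generators emulate the *measurement chain*, not the imaging physics: no
ultrasound speckle, no B0/B1 field effects, no segmentation algorithm.
Passing recovery tests therefore demonstrates that the estimators are
correct and well-calibrated for geometrically and statistically realistic
inputs — not that the pipeline is robust to raw-image artefacts.

- **Tendon phantom**: tapered elliptical tube, linear radius from distal to
  proximal (area π r², ellipticity-independent), straight or circular-arc
  centroid path; truth volume from the closed-form frustum integral, truth
  length the arc length.  Contour noise is a smooth low-order Fourier radial
  perturbation (white per-vertex noise creates self-intersecting polygons,
  which real segmentations do not).
- **Talar dome**: cylindrical patch (default radius 10 mm, 120° arc, 25 mm
  extent) under an arbitrary rigid pose with isotropic point noise.
- **Multi-echo**: voxelwise model signal plus Gaussian (clipped at zero) or
  Rician noise; the Rician option matches the analytic Rician mean in tests.
- **Loading series**: quadratic toe region up to a configurable toe strain
  (default 0.5%) followed by a linear region at the true stiffness; loaded
  CSA shrinks isovolumetrically (CSA·L constant); torque targets of 25/50/70
  ±5% MVC with Gaussian jitter; measurement noise on torque and length.
- **Cohorts** (16 per arm by default): per-subject draws of length, average
  CSA, distal-CSA excess, moment arm, MVC torque, plus a Gaussian copula
  tying T2* to Young's modulus (default r = −0.25).  Group defaults use
  published group means where available (moment arm 5.0±0.3 / 4.9±0.5 cm,
  modulus 0.38±0.11 / 0.39±0.12 GPa, MVC torque 95.1±21.4 / 81.7±19.9 Nm)
  and literature-scale values otherwise (length 45±7 / 57±9 mm, average CSA
  75±11 / 65±10 mm², T2* 12±2 / 8±1.5 ms, runners first).  Per-subject
  stiffness is derived as k = 1000·E·A/L₀ so that stiffness, modulus,
  geometry and the loading generator stay mutually consistent — with these
  defaults the emergent stiffness means (~630/450 N·mm⁻¹) bracket published
  cohort values and reproduce the qualitative pattern: shorter, thicker,
  stiffer tendons with longer T2* in the trained arm and near-equal modulus.
  A stiffness mean/SD can be supplied instead, at the cost of internal
  consistency between modulus and geometry.

Every generator takes an explicit seed; identical spec + seed reproduces
outputs bit-for-bit, and every generator emits a truth record so pipeline
estimates can be scored against construction.

## Problem sizes

Defaults were chosen so a complete run of the test suite and the analysis
scripts stays light: cohorts of 16+16 subjects, 12×12 echo grids with
~45-pixel ROIs, 400-point dome clouds, 2000-sample curve discretisation,
500 simulated cohorts × 200 permutations for SPM calibration, 200–500
replicates for recovery experiments.  All sizes are arguments and scale up
directly.

## Limitations

- The contour-interpolation correspondence is a modelling choice; different
  schemes yield slightly different volumes on non-convex sections.
- The moment arm is purely geometric (static cylinder axis vs centroid
  line); joint-angle dependence and weight-bearing are not modelled.
- The T2* ML mean skew at low SNR described above.
- SPM assumes profiles on a common 101-point grid; no smoothness matching
  or covariate adjustment is performed.
- Cohort draws are independent across endpoints except the T2*–modulus
  copula; real anthropometry correlates more broadly.
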