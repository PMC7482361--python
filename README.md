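# tendonmetrics

Morphometry, moment arm, UTE T2\* relaxometry and mechanical-property
estimation for the **free Achilles tendon** — the segment between the soleus
muscle–tendon junction (proximal) and the calcaneal notch (distal) — with the
group statistics used to compare athletic and control cohorts.  It is aimed
at biomechanics and musculoskeletal-imaging researchers who reconstruct
tendon geometry from sparse transverse segmentations (MRI or freehand 3D
ultrasound), estimate tendon loading from dynamometry, and probe tissue
quality with ultrashort-echo-time MRI.

## What it computes

**Geometry** (`tendonmetrics.geometry`).  A tendon is an ordered stack of
planar cross-section polygons.  Sparse manual segmentations (typically 6–8
slices) are densified by arc-length resampling, polar-angle correspondence
and vertex-wise linear interpolation; then

- length `L = Σᵢ ‖cᵢ₊₁ − cᵢ‖` (cumulative distance between consecutive slice
  centroids),
- volume `V = Σᵢ ½(Aᵢ + Aᵢ₊₁)·‖cᵢ₊₁ − cᵢ‖` (trapezoidal rule along the same
  centroid path),
- average CSA `= V / L`, and a regional CSA profile sampled at 1% increments
  of tendon length (0% = distal end).

**Moment arm** (`tendonmetrics.moment_arm`).  The ankle's rotation axis is
modelled by an orthogonal least-squares cylinder fitted to talar-dome
surface points (cost `Σ(dist-to-axis − r)²`, PCA + algebraic circle
initialisation).  The moment arm is the minimum distance between the
cubic-spline axis curve and the cubic-spline tendon centroid line, found by
dense sampling plus bounded 2-D refinement, reported in cm.  Tendon force is
then `F = τ_net / d` with net joint torque `τ_net` (Nm) and moment arm `d`
(m).

**T2\* relaxometry** (`tendonmetrics.relaxometry`).  Per-pixel two-stage fit
of `S(TE) = S₀·exp(−TE/T2*) + b`: a log-linear plain-exponential fit
initialises a bounded Levenberg–Marquardt fit (via lmfit) of all three
parameters; ROI means average converged, in-bounds pixels and report the
number excluded.  Both 5-echo (0.18–9.46 ms) and 7-echo (0.21–10.09 ms) UTE
protocols are built in.

**Mechanics** (`tendonmetrics.mechanics`).  Staged isometric loading at 25,
50 and 70% of maximal voluntary contraction: stiffness `k` is the OLS slope
of force vs elongation over the three loaded conditions, Young's modulus `E`
the slope of "true" stress (`F/CSA_loaded`) vs strain (GPa), and
length-normalised stiffness `k·L₀` (kN/strain).

**Statistics** (`tendonmetrics.stats`).  Shapiro–Wilk-gated one-way ANOVA /
Kruskal–Wallis with η² (`F/(F+df₂)` for two groups; `(H−k+1)/(n−k)` for
ranks), Pearson correlation, and a 1-D statistical parametric mapping (SPM)
two-sample t-test over CSA profiles with permutation max-|t| field-wise
thresholds and cluster-mass p-values (parametric random-field threshold
available).

**Synthetic data** (`tendonmetrics.synthetic`).  Seeded generators with
closed-form ground truth for every input: tapered/curved tendon phantoms,
posed cylindrical dome patches, multi-echo stacks (Gaussian or Rician
noise), staged loading tables with a quadratic toe region, and full
two-group cohorts with a Gaussian-copula T2\*–modulus correlation.

## Worked example

```python
import numpy as np
from tendonmetrics.synthetic import (TendonPhantomSpec, make_tendon_phantom,
                                     make_dome_points, random_rigid_pose, apply_pose)
from tendonmetrics.geometry import densify_stack, compute_metrics
from tendonmetrics.moment_arm import Curve3D, compute_moment_arm

spec = TendonPhantomSpec(length=45.0, distal_radius=5.0, proximal_radius=4.0,
                         ellipticity=1.3, contour_noise_sd=0.1,
                         n_sparse_slices=7, seed=7)
sparse, truth = make_tendon_phantom(spec)
metrics = compute_metrics(densify_stack(sparse, target_spacing=0.27))
print(f"volume      {metrics.volume:8.1f} mm^3   (truth {truth.volume:.1f})")
print(f"length      {metrics.length:8.2f} mm     (truth {truth.length:.2f})")
print(f"average CSA {metrics.average_csa:8.2f} mm^2   (truth {truth.average_csa:.2f})")

pose = random_rigid_pose(7)
dome = apply_pose(make_dome_points(radius=10.0, noise_sd=0.1, n=400, seed=7), pose)
z = np.linspace(-22, 22, 25)
line = apply_pose(np.column_stack([np.zeros(25), np.full(25, 50.0), z]), pose)
print(f"moment arm  {compute_moment_arm(dome, Curve3D(line)).moment_arm:8.3f} cm")
```

prints

```
volume        2868.6 mm^3   (truth 2874.6)
length         45.00 mm     (truth 45.00)
average CSA    63.74 mm^2   (truth 63.88)
moment arm       5.000 cm
```

i.e. a 7-slice sparse segmentation with 0.1 mm contour noise recovers volume
and average CSA within ~0.2% of the phantom's closed-form truth, and a noisy
talar-dome patch posed arbitrarily in space returns the constructed 5.0 cm
moment arm to three decimals.

## Command line

```sh
tendonmetrics simulate --out-dir cohort --seed 1        # synthetic cohort tree
tendonmetrics run --input-dir cohort --output-dir out   # full pipeline
tendonmetrics geometry contours.csv --spacing 0.27      # single stages ...
tendonmetrics momentarm dome.csv tendon_line.csv
tendonmetrics t2star echo.nii echo.json mask.nii --out-dir maps
tendonmetrics mechanics loading.csv --moment-arm 5.0
tendonmetrics compare cohort.csv
```

Exit codes: 0 success, 2 validation error, 3 stage failure.

The `analysis/` scripts run the same chain as a narrative study:
`01_simulate_cohort.py` → `02_measure_subjects.py` → `03_compare_groups.py`
→ `04_method_validation.py`, writing tables under `results/`.

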