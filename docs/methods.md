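# Methods

## Model

Lesion growth between two visits is represented as a monotonically expanding
front. With φ the level-set function of the advancing margin (negative
inside atrophy, initialized as the signed distance to the sub-pixel visit-1
margin), the evolution is

    ∂φ/∂t = −F |∇φ|,   F(x) = max(0, 1 − β κ(x)) · 1[x ∈ Ω₂],

with κ = div(∇φ/|∇φ|) the curvature of the current front (positive where the
lesion boundary is convex). The two ingredients of F encode the model's
assumptions: atrophy advances perpendicular to its margin, and indented
(concave) margin segments close faster than bulging (convex) ones — the
empirically motivated smoothing behaviour of GA margins. The indicator
confines the front to the follow-up region Ω₂, so the evolution terminates
exactly on the observed visit-2 margin rather than on a free boundary. The
clamp at zero prevents margin retreat at very sharp convexities. Because
local rates are defined from trajectory arclengths, not from T, the absolute
front speed (and hence the time normalization) is immaterial; only the
family of intermediate fronts matters, and β is the single shape parameter
controlling it.

Margin correspondence is taken from streamlines of the arrival-time field:
T(x) is the first time the front covers x, and the trajectory of a margin
point is the integral curve of ∇T from that point to the visit-2 margin.
Streamlines are orthogonal to every intermediate front, which makes them the
natural continuous analogue of "where did this piece of margin go". Where
fronts collide (two foci merging, or one focus closing around a pocket), T
develops ridges; correspondence is ill-posed beyond them, and margin points
whose trajectories stall at a ridge or wander into cells first claimed by a
different visit-1 component are flagged and excluded from all statistics
(while still counted, preserving modeled = analyzed + excluded).

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `spacing_um` | 6 | µm | arclength spacing of margin points |
| `beta_um` | 24 | µm | curvature weight of the front speed |
| `grid_pitch_um` | 6 | µm | working grid (native masks supersampled ×2) |
| `epsilon_um` | 1 | µm | surrogate growth-vector length at zero growth |
| `delta_um` | = grid pitch | µm | margin-hit tolerance of the tracer |
| `cfl` | 0.4 | — | explicit time-step bound |
| `reinit_interval` / `reinit_sweeps` | 20 / 5 | steps | signed-distance reinitialization |
| σ (eccentricity, fundus map) | 125 | µm | kernel-regression bandwidth |
| σ (margin / growth angles) | 10 | deg | kernel-regression bandwidth |
| fundus-map support | 250 pts / 250 µm | — | display threshold (map only) |
| histogram bin width | 0.005 | mm/yr | ≈ plausible tracing accuracy |

β has no measured value; 24 µm (two native pixels) makes the curvature term
act at the scale of tracing roughness while leaving lesion-scale geometry
essentially advective. Sensitivity to β is part of the test surface (the
β = 0 limit is checked against an independent geodesic-distance oracle).

## Numerics

* Native binary masks (12 µm pitch in the standard 6 mm field) are contoured
  on the 0.5-level of a one-pixel Gaussian regularization of the mask. The
  raw bilinear 0.5-level of a binary raster is a staircase whose perimeter
  is biased upward by several percent; the regularized level sits within
  half a pixel of the binary boundary and restores perimeters to ~0.5%.
  The same field defines the supersampled regions, so contours and regions
  coincide.
* Level-set update: first-order Godunov upwind gradient, central-difference
  curvature clipped to ±1/h, explicit Euler at CFL 0.4, full-grid vectorized
  updates on the padded bounding box of Ω₂ (simpler than a narrow band and
  fast enough at these grid sizes), Sussman reinitialization every 20 steps.
  Arrival times are sub-step interpolated at the zero crossing of φ.
* Inside Ω₁ the gradient field uses the (negative) initial signed distance,
  so streamlines start smoothly across the margin; interpolation of T and
  ∇T is validity-weighted so unreached cells never contaminate estimates.
* Tracing: lock-step RK2 with step = h/2; a trace succeeds within δ of the
  visit-2 margin and its endpoint is snapped onto the margin (removing the
  δ truncation bias); it stalls on a vanishing gradient or on no net motion
  over a 16-step window (ridge oscillation). Zero-growth points (within δ
  of the visit-2 margin at the start) get single-vertex trajectories, rate
  0, and the ε growth-vector convention.
* Interfoci labels are propagated over Ω₂ by per-component geodesic
  distance (brush-fire over the cell graph) and compared along each
  trajectory.
* Kernel regression uses Gaussian kernels truncated at 5σ (discarded mass
  < 1e-6; exact equality with an untruncated double loop holds whenever all
  data lie within 5σ). Margin angles are treated circularly on 360°; growth
  angles linearly on [0°, 180°] with the estimator's intrinsic edge
  renormalization. Quartiles use linear interpolation of order statistics
  (type 7). The weighted eye count credits each eye with its best-placed
  point (maximum peak-normalized kernel weight), which bounds it by both the
  number of eyes and the weighted point count.

## Accuracy, in grid units

On rasterized concentric disks (0.8 → 0.95 mm over one year, 6 µm working
grid) the median local rate is within a fraction of a grid pitch of the true
0.15 mm/yr, every individual rate within two pitches, and the mean bias
within half a pitch at 24, 12, and 6 µm grids. Growth-vector *directions*
inherit the boundary quantization of binary input masks: margins traced on a
12 µm raster carry ~¼-pixel radial noise, which over a 150 µm trajectory
perturbs the growth angle by ~1.5° (bounded by arctan(2h / growth length)).
This is a property of rasterized input, not of the solver — the tests bound
ψ accordingly rather than at an idealized sub-degree level.

## Synthetic data

The generators produce the full study geometry with known ground truth:

* analytic/rasterized disk scenes, including the two-circle grid-artefact
  scene (foveal lesion swept over R_α ∈ [0.8, 2.1] mm; perifoveal lesion of
  radius 0.1 mm placed at 2.5 mm eccentricity, the zone-3 midline, so it
  stays strictly inside the [2, 3] mm zone throughout; both growing
  0.15 mm/yr) with closed-form circle/annulus intersection areas;
* guaranteed-merging two-foci scenes (disjoint at visit 1, overlapping at
  visit 2, mirror-symmetric);
* synthetic cohorts of star-convex lesions whose margins grow radially at
  m(r)·g(ψ) + noise, clipped at zero. Defaults: 12 eyes, base radius 0.9 mm
  with ±30% eye-to-eye spread and fovea offsets up to 0.8 mm (≈10⁴ margin
  points, the desk-scale analogue of a pilot cohort); tracing noise
  0.03 mm/yr (a ~30 µm/yr margin-delineation jitter); hill profile
  m(r) = 0.05 + 0.10·exp(−(r−1.05)²/(2·0.55²)) mm/yr, peaking across the
  0.5–1.6 mm eccentricity band with slower growth on either side.

What the cohorts deliberately do not emulate: OCT speckle and acquisition
artefacts, grader disagreement beyond isotropic jitter, spatially correlated
growth noise along the margin, multifocal interactions, or eye-level random
effects. Passing parameter-recovery tests therefore demonstrates estimator
correctness under the stated model, not robustness to real tracing
pathology.

## Design choices made where the design was open

* Registration warps visit-2 data into the visit-1 frame (covariates are
  defined on the visit-1 margin); mask warping uses an inverse polynomial
  fitted on the swapped control pairs with nearest-neighbour resampling.
* The effective-radius rate is related to the √area rate by √π (forced by
  r_eff = √(A/π)); both are reported.
* Whole margin points are excluded on merging, not post-merge trajectory
  segments — clipping trajectories at the collision would systematically
  underestimate fast-growing merging segments.
* New visit-2 foci with no visit-1 counterpart generate no trajectories
  (there is no visit-1 margin to correspond from); they still enter global
  area rates. Unreachable visit-2 pockets are handled by the stall rule.
* Eligibility (cohort runs): total baseline area ≥ 2.54 mm² (one disc
  area), largest focus > 1.25 mm² for multifocal lesions, and no foreground
  pixel on the raster border at either visit (field-of-view containment).
* Pooled statistics weight all margin points equally across eyes, so larger
  lesions contribute more points; the per-grid-value eye counts make that
  support visible. No confidence intervals are reported: neighbouring
  margin points are strongly correlated, and naive kernel-regression bands
  (or cross-validated bandwidths) would be misleadingly tight.

## Known limitations

* Fidelity of the curvature-modulated front to true GA biology is untested
  here; the model is a correspondence device whose rates are exact in the
  isotropic limit and self-consistent under its own dynamics.
* First-order upwind arrival times carry O(h) error; directional artefacts
  are below the raster quantization noise of the input masks but not zero.
* Merge exclusion removes points preferentially where growth converges
  (small eccentricities, fovea-directed growth); the merge-bias report
  stratifies the excluded fraction by eccentricity and growth-angle band so
  this selection is visible in every run.
* The distance-based and zone-based comparators are faithful
  re-implementations of the strategies they represent and are intended for
  head-to-head artefact demonstrations, not for production measurement.
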