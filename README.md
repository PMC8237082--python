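# gakinetics

Spatially resolved growth kinetics of geographic atrophy (GA) lesions from
pairs of co-registered en-face OCT lesion masks.

GA, the atrophic late stage of age-related macular degeneration, expands at
rates that vary along the lesion margin and across the fundus. Whole-lesion
metrics (area growth rate, √area rate, effective-radius rate) average this
structure away, and grid- or distance-based attempts to localize them
produce artefacts tied to the grid geometry or to nonphysical straight-line
correspondences. `gakinetics` instead models the growth explicitly: the
baseline lesion margin is evolved to the follow-up margin as an expanding
front, and every margin point gets its own growth trajectory, growth rate,
and fovea-centred covariates.

## The model

Let Ω₁ ⊆ Ω₂ be the lesion regions at the two visits. The visit-1 margin
∂Ω₁ is propagated as a level set φ under

    ∂φ/∂t = −F |∇φ|,    F(x) = max(0, 1 − β κ(x)) · 1[x ∈ Ω₂],

where κ is the front curvature (positive on a convex lesion boundary), so
the margin expands perpendicular to itself, concave margin segments expand
faster than convex ones (curvature weight β, default 24 µm), and the front
conforms to and stops at the visit-2 margin. The first-crossing time of
each point in the growth region Ω₂ \ Ω₁ defines the arrival-time field T.

For each margin point p (sampled every 6 µm of arclength):

* **growth trajectory** ℓ⃗(p): the streamline of ∇T from p to the visit-2
  margin — the path the margin locally travels, possibly curved;
* **growth vector** L⃗(p): the straight segment from the trajectory's start
  to its end (an ε-length outward normal at zero-growth points — only its
  direction is ever used);
* **local growth rate** v(p): trajectory arclength / intervisit time
  (mm/yr) — for a circular lesion growing isotropically this equals the
  effective-radius growth rate;
* **covariates**: margin eccentricity r(p) = |p − fovea|, margin angle θ(p)
  (0°/90°/180°/270° = nasal/superior/temporal/inferior; left eyes mirrored
  about the vertical axis), and growth angle ψ(p) = ∠(L⃗, s⃗) ∈ [0°, 180°]
  (0° = growth directly away from the fovea).

Margin points whose trajectories collide with fronts from other margin
segments or foci (lesion merging) are excluded from statistics, because the
margin correspondence is ill-posed there; they are still counted.

Conditional mean growth rates ("growth atlases") are estimated by
Nadaraya–Watson kernel regression (Gaussian kernels; σ = 125 µm for
eccentricity and fundus position, σ = 10° for angles), with kernel-weighted
margin-point and eye support counts, a fundus-map display threshold (250
points within 250 µm), and descriptive statistics (density-normalized
histograms, exponential fit, Q–Q quantiles, 1.5·IQR boxplot rules).

## Worked example

```python
import gakinetics as gk

# concentric disks growing 0.8 -> 0.95 mm in one year, fovea at the centre
mask1, mask2 = gk.make_disk_pair((3.0, 3.0), 0.8, 0.15, pixel_pitch_um=12.0)
results = gk.GrowthModel(mask1, mask2, fovea_mm=(3.0, 3.0), dt_years=1.0).fit()
print(results.summary())
```

prints

```
Growth model results
========================================================
eye_id                : disk (OD)
intervisit time       : 1.000 yr
margin points modeled : 842
  analyzed / excluded : 842 / 0 (0.0% excluded)
area growth rate      : +0.8208 mm^2/yr
sqrt-area growth rate : +0.2647 mm/yr
eff. radius rate      : +0.1493 mm/yr
local rate v (mm/yr)  : mean 0.1495, median 0.1499, max 0.1566
eccentricity r (mm)   : 0.796 .. 0.805
```

The 842 margin points are the 5.03 mm baseline circumference sampled every
6 µm; every local rate sits within two working-grid pitches of the true
0.15 mm/yr, and the global rates satisfy √area rate = √π × effective-radius
rate exactly. `results.records` is a DataFrame with one row per margin
point (v, r, θ, ψ, merge flags); `results.plot_trajectories()` overlays the
trajectories on the two margins.

Cohort runs (eligibility screening, per-eye fits, pooled kernel-regression
atlases, merge-bias report) go through `gakinetics.run_study` or the CLI:

```bash
gakinetics run manifest.yaml --out study_out
gakinetics gridsweep        # grid-artefact comparator sweep
gakinetics simulate         # synthetic cohort with known ground truth
```

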