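# Methods

## The g-ratio index model

The aggregate g-ratio index treats each voxel as containing a single fiber
population characterized by one myelin volume fraction and one axon volume
fraction. The myelin water volume fraction VF_M (from multicomponent
relaxometry) stands in for the myelin compartment; the NODDI intracellular
fraction ν_IC, restricted to the non-myelin (1 − VF_M) and non-CSF
(1 − ν_ISO) portion of the voxel, stands in for the axon compartment:

    VF_A = (1 − VF_M)(1 − ν_ISO) ν_IC
    VF_F = VF_M + VF_A
    g    = √(1 − VF_M / VF_F)

Assumptions worth keeping in mind: a single g-ratio per voxel (no
within-voxel fiber-population distribution); VF_M is used as the myelin
volume fraction without a proportionality coefficient (the scalar is
exposed as `vfm_scale`, default 1.0, for sensitivity analyses only); gray
matter is not masked out of the maps, so interpretation there is left to
the user. For in-range inputs the algebra guarantees VF_M ≤ VF_F and hence
g ∈ [0, 1]; g depends only on the ratio VF_M/VF_F, so a common rescaling
of the myelin and axon compartments cancels.

Numerical policy: voxels with VF_F ≤ ε (ε = 1e−6) are flagged undefined
(NaN in the g map, excluded from the defined mask and from all regional
statistics) rather than propagated. Input fractions slightly outside
[0, 1] — routine in real parameter fits — are clipped under the default
`clamp` policy with a logged count; `strict` raises instead.

## Trajectory model

Regional development is modeled as g(age) = α·ln(age_days) + β fit to the
per-subject regional means (not voxel-level data) by ordinary least
squares; the model is linear in its parameters after the ln transform, so
the closed-form solution is exact and no iterative optimizer is involved.
Age is in days with the natural log — fixed, not configurable, because the
shipped coefficient table evaluated at ln(10,000) reproduces the shipped
asymptote table only under that convention.

Hemispheric asymmetry is tested per region with the extra-sum-of-squares
F-test: the dual-curve model fits left and right independently
(4 parameters), the single-curve model fits the pooled points
(2 parameters), and

    F = ((RSS_single − RSS_dual)/2) / (RSS_dual/(n_total − 4))

is referred to F(2, n_total − 4). Nesting guarantees
RSS_single ≥ RSS_left + RSS_right; a perfectly fitting dual model
(RSS_dual at round-off level, tolerance 1e−14 scaled by the response's sum
of squares) is flagged and reported as F = +∞, p = 0. Under the null of
identical hemispheric curves with iid Gaussian noise the statistic is
exactly F-distributed, which the test suite confirms by simulation
(2000 replicates, Kolmogorov–Smirnov check and ~5% rejection at p < 0.05).

The "asymptote" is the fitted curve evaluated at 10,000 days (~27 years) —
an extrapolated plateau estimate, not a model parameter — reported rounded
half-up to 2 decimals to match the reference table's precision. Rounding
matters: the cross-region average of the 20 reference values is exactly
0.775, which half-up rounding reports as 0.78.

## Partial correlations

Associations between regional g and each of VF_M, VF_F, ν_IC, ν_ISO are
Pearson partial correlations controlling for age: both variables are
residualized on (1, age) by least squares and the residuals correlated.
With one covariate, t = r√(n−3)/√(1−r²) with df = n − 3 (n = 18 subjects
gives df = 15, so |t| ≈ 2.13 marks p < 0.05 two-sided). No
multiple-comparison correction is applied. The statistic is invariant to
affine transforms of the covariate, so age units (days vs years) cannot
matter — asserted as a property test. A variable collinear with age has no
residual variance and raises a degenerate-case error; in the batch table
such regions yield flagged NaN rows instead of aborting the run. The
closed form r_xy·c = (r_xy − r_xc·r_yc)/√((1−r_xc²)(1−r_yc²)) is kept in
the package purely as an independent oracle; tests require agreement to
1e−12 and also cross-check against pingouin.

## Synthetic cohort

The generator emulates the study conditions, not raw MR physics. Subjects
default to the 18 study ages (102–2713 days, gestation-corrected,
13 M / 5 F); a uniform-in-log-age sampler is available for larger cohorts.
Each of 23 block-shaped atlas regions (left/right pairs of frontal,
occipital, parietal, temporal and cerebellar white matter, cingulum,
corona radiata, internal capsule, optic radiation and superior
longitudinal fasciculus, plus midline genu/body/splenium of the corpus
callosum) on a 32³ grid (1.8 mm isotropic) follows its own growth law:

- **VF_M**: 4-parameter logistic in age. No published sigmoid parameters
  exist, so each region's logistic is calibrated by inverting the target
  g trajectory — given g and the ν_IC/ν_ISO laws,
  vfm = qA/(1 − q + qA) with q = 1 − g² and A = (1−ν_ISO)ν_IC — at the
  published hemispheric coefficients (clamped to g ≤ 0.995, since the
  published left-cerebellar curve exceeds 1 below ~110 days) and
  least-squares fitting the logistic over 100–3000 days. The induced mean
  g trajectories therefore track the published curves approximately (to
  within ~0.03, the logistic/log shape mismatch), not exactly.
- **ν_IC**: 0.055·ln(age) + 0.25 (≈0.50 at 3 months, ≈0.69 at 7.5 years),
  one global default — regional differentiation is carried by VF_M.
- **ν_ISO**: constant 0.05.
- **Noise**: additive zero-mean Gaussian per voxel, clamped to [0, 1];
  default SDs 0.008 (vfm), 0.02 (nu_ic), 0.01 (nu_iso). The vfm SD is the
  binding choice: the youngest subjects' expected VF_M is ~0.02, and
  0.008 keeps the cohort-wide clamp rate well under 1% (measured ~0.02%)
  so the clamping cannot meaningfully bias regional means.
- Midline callosal regions have no published coefficients; their target
  curves are invented within the range of the lateral regions and are
  never compared against reference values.

What the simulation does **not** contain — and hence what passing tests do
not show about real data: scanner noise physics, motion, registration and
segmentation error, partial-volume effects at region boundaries, spatially
correlated noise, between-subject biological variability beyond age, and
any VF_M↔myelin proportionality mis-scaling. Results on the synthetic
cohort validate the computational pipeline, not the imaging assumptions.

Determinism: one `numpy` Generator seeded from the cohort spec drives all
draws in a fixed subject/region order, so identical (spec, seed) gives
bit-identical volumes, and the end-to-end pipeline writes hash-identical
artifacts across runs with the same seed (plain `.nii`, no compression
timestamps; the manifest records SHA-256 per output).

## Verification of the shipped tables

The package ships the reference per-region fit coefficients and asymptote
values. `verify_published_tables()` evaluates every fit at 10,000 days and
compares after rounding: all 10 left-hemisphere cells and 9/10 right cells
agree exactly; the right-cerebellar cell disagrees (computed 0.91 vs
shipped 0.84) — an internal inconsistency of the source tables that is
flagged as an expected mismatch rather than silently accepted or patched.
The shipped F statistics are carried for completeness only; their printed
significance marks are internally inconsistent (the smallest statistics
are marked significant) and are not reproduced or used.

## Problem sizes

Defaults were chosen so the whole suite is desk-scale: 32³ grids
(≈33k voxels, 18 subjects) for end-to-end runs, 16³ for unit fixtures,
200 replicates for slope-recovery checks, 1000–2000 replicates for the
F-test and partial-correlation calibrations. The full test suite runs in
well under a minute; the acceptance script in a few seconds.

## Known limitations

- The logistic VF_M calibration targets the published g curves through the
  index formula; it reproduces shapes, not exact coefficients, so
  synthetic asymptotes sit ~0.01–0.02 above the published ones.
- Regional SDs use the population convention (divide by n); error-bar
  semantics in the source are unspecified.
- Hemisphere merging is voxel-count-weighted (equal to pooling voxels); an
  unweighted switch exists for atlases with asymmetric region sizes.
- The logarithmic model has no true asymptote (g → −∞ as age → ∞); the
  10,000-day evaluation is a convention for a plateau estimate, and the
  model is known to deviate at the oldest ages.
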