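# Methods

## The problem

Deep brain stimulation (DBS) of the subthalamic nucleus (STN) treats
four quite different disorders — dystonia, Parkinson's disease,
Tourette's syndrome and obsessive-compulsive disorder — and the
clinical benefit a patient obtains depends on *where* within the
subthalamic region their stimulation field falls and *which*
fronto-subcortical connections it modulates.  Given a cohort of
patients with (i) an electric-field magnitude volume per implanted
hemisphere in a common template space, (ii) a normative streamline set
in the same space, and (iii) a percent clinical improvement per
patient, `stimmap` estimates two group-level models:

- **Sweet-spot mapping** (voxel level).  For every voxel covered by at
  least a fraction *c* of E-fields above a magnitude threshold *t*
  (defaults: *c* = 0.5, *t* = 200 V/m, the usual estimate of the field
  needed to activate axons), the vector of per-field magnitudes is
  Spearman-rank-correlated with the improvements, giving a map of
  positively (sweet) and negatively (sour) associated voxels.
- **Fiber filtering** (streamline level).  Each candidate streamline —
  one traversing > 0.8 V/mm in strictly more than 0.5 % of the
  cohort's fields — is tagged with the rank correlation between the
  peak field magnitude sampled along its course per E-field and the
  improvements.  The top 1 % of the candidate r distribution (positive
  side) forms the *sweet streamline* set.

Both models double as outcome estimators. The **Sweet Spot Score** of
an E-field is the mean over mask voxels of (magnitude × voxel r); the
**weighted peak-5 % Fiber R score** sums, over sweet streamlines
touched by the field, the largest ⌈5 %⌉ of (streamline r × peak
magnitude) products.  Patient scores average the two hemispheres.
Model validity is assessed by Spearman correlation of scores against
empirical improvements, in-sample and under fivefold cross-validation
with permutation p-values.

## Observation unit and hemisphere handling

The correlation stage treats each E-field (hemisphere) as one
observation, paired with its patient's improvement; fields are pooled
across hemispheres.  For a unilateral region of interest, bilateral
fields are pooled onto one hemisphere by flipping the world x
coordinate about the template midline (x = 0); this is the default
(`mirror=True`) — with genuinely bilateral implants and no mirroring,
no voxel can be covered by ≥ 50 % of the *pooled* fields, and the
coverage mask is empty.  A `patient_max` aggregation (voxel-wise
maximum of one patient's fields, one observation per patient) is
available as a flag.

## Rank statistics

Ties receive average ranks.  Two-sided p-values use the t
approximation for n ≥ 10 and an exact permutation distribution below
that (full enumeration up to 7!, else 10,000 seeded Monte-Carlo
draws).  Voxel- and streamline-wise maps are mass-univariate and
descriptive; no multiple-testing correction is applied by design —
validation is delegated to cross-validated estimation.  Constant
improvement vectors raise an error (the correlation is undefined);
constant magnitude columns (voxels or streamlines no field modulates)
yield r = 0, p = 1.

## Cross-validation and permutation inference

`stats.kfold_cv` assigns folds by a seeded uniform shuffle followed by
contiguous chunking (sizes differ by at most one); models are fitted
on training patients only, including coverage masks and candidate
selection, so no information leaks from held-out patients.  The
permutation p-value is two-sided with the add-one rule,
p = (1 + #{|ρ_perm| ≥ |ρ_obs|}) / (1 + n_iter), and never returns 0.

Two permutation schemes exist:

- `kfold_cv(...)` (default) permutes outcomes at the final correlation
  stage with the cross-validated estimates held fixed.  This is cheap,
  but under the null it is **anti-conservative**: each held-out
  estimate is a function of the *other* folds' outcomes, which inflates
  the variance of the observed correlation relative to the fixed-
  estimates permutation null (we measure a null rejection rate of
  roughly 15–20 % at α = 0.05 on phantom cohorts of n = 40).
  `refit=True` re-runs the whole CV per permutation and is exact but
  slow in the generic path.
- `sweetspot.cv_permutation_test` performs the exact full-refit
  permutation efficiently.  The key observation is that the coverage
  mask and the voxel-wise magnitude *ranks* depend only on the fields,
  never on outcomes; re-fitting a fold under permuted outcomes
  therefore reduces to one matrix product, and because the Sweet Spot
  Score is linear in the voxel map, held-out estimates for all
  permutations follow from a second product.  This scheme is calibrated
  by construction and is the one the calibration tests exercise.

## Compromise power analysis

`stats.compromise_power` solves, for a one-sided test of ρ = 0 against
ρ = ρ₁ under a bivariate-normal model, for the critical sample
correlation r_c such that β(r_c)/α(r_c) equals a stated ratio.  The
null tail uses the exact t transform of the sample correlation; the
alternative integrates the exact sampling density of r (including its
(n−2) normalization factor, easily dropped by mistake), with the
bias-corrected Fisher-z approximation (mean atanh ρ + ρ/(2(n−1)),
variance 1/(n−3)) available as `method="fisher"`.  Both methods agree
to two decimals on all four cohort sizes of interest (n = 56, 94, 14,
19 at ρ₁ = 0.4, ratio 1 → powers 0.94, 0.98, 0.77, 0.81).

## Placement control analyses

Three checks separate outcome-driven structure from mere electrode
placement: (1) k-sample and pairwise chi-square tests of equal
proportions (no continuity correction by default) for overlap
bookkeeping; (2) pooled-variance two-sample t-tests (Welch by flag)
comparing contact coordinates between disorders; (3) a placement-only
streamline selection that fits a 3-D Gaussian to each disorder's
standard (second-to-lowest) contact coordinates and selects
streamlines passing within a Mahalanobis distance of the Gaussian
(default cut 2.0 — a declared choice, the literature is silent);
singular covariances are ridge-regularized with a logged epsilon.
Per-streamline **specificity** divides a streamline's own-model r by
the mean r it received from the remaining disorders' models
(non-candidates contribute 0; a zero denominator yields NaN, never
infinity).

## The phantom generator

`synthetic.make_scene` builds a template box (default 1 mm isotropic,
~48×40×40 mm) with two ellipsoidal nuclei at x = ±10 mm (semi-axes
3×5×3 mm, roughly STN-sized) and three streamline groups per
hemisphere: two coherent bundles whose waypoints flank the nucleus
(separated by ≥ 3 mm plus jitter margin) and a diffuse background fan.
Streamlines are cubic Bézier curves from below the nucleus to distinct
"cortical" patches; adjacent-segment turning angles stay below 60°.

`make_cohort` implants, per patient and hemisphere, a vertical
four-contact lead (2 mm spacing) with Gaussian placement jitter
(default SD 1.5 mm, a realistic stereotactic targeting error) and
activates the standard (second-to-lowest) contact at an amplitude
drawn from N(2.5, 0.5) mA (floored at 0.5).  The E-field magnitude is
an analytic inverse-square profile, κ·A/max(r, 0.5 mm)², with κ
calibrated so a 2 mA contact crosses 200 V/m at 3.5 mm — a stand-in
preserving the monotone decay the mapping methods rely on, not a
physics model.  Planted-target engagement is the field magnitude at a
planted spot (mirrored across hemispheres) or the mean peak magnitude
over a planted bundle's streamlines, averaged across hemispheres.
Improvement is 50 + effect·z(engagement) + N(0, σ); defaults
effect = 15 improvement points per engagement SD and σ chosen so noise
is 15 % of the total outcome SD (`noise_sd_for_fraction`).  Follow-up
scores are back-computed from a fixed baseline of 40 points so percent
improvements map linearly onto the signal; outcomes are not clipped
and may be negative.  All randomness flows from one master seed via
spawned `SeedSequence`s; written cohorts are byte-reproducible.

What the phantom does *not* emulate: tissue anisotropy and FEM field
shapes, directional leads, realistic STN somatotopy, registration
error, and between-center heterogeneity of scales and protocols.
Passing recovery tests therefore demonstrates the *statistical
machinery* recovers planted structure under the stated noise model,
not that the method is robust to those real-data complications.

## Numerical choices

- World coordinates in mm; 0-based continuous voxel indices; a voxel's
  center maps through the affine (NIfTI convention).
- Trilinear interpolation with zero padding beyond the grid
  (`grid-constant`), so samples fade linearly to 0 at the boundary and
  out-of-grid points contribute 0 — appropriate for compactly
  supported fields.
- Streamline sampling step 0.5 mm (below typical voxel size so peaks
  are not missed); original vertices retained during resampling.
- Density maps count a streamline at most once per voxel, with voxel
  membership by nearest voxel center at a half-voxel sampling step.
- Gaussian smoothing takes FWHM in mm with per-axis sigma from the
  voxel size; FWHM 0 is the identity.
- Sweet threshold = the (1 − 0.01) quantile (linear interpolation) of
  candidate r values; sweet streamlines additionally require r > 0.
- Peak-5 % count = ⌈0.05 × touched⌉ with a floor of 1 so sparse
  intersections still score; sour (negative-r) streamlines are
  excluded from scoring by default.
- Streamline "certainty" weights are −log₁₀(p); the base is
  configurable.
- On-disk volumes are float32 NIfTI-1; statistics run in double
  precision.

## Problem sizes in the test suite

Recovery and calibration tests run at desk scale as the package's own
choice: 1 mm phantom grids for spot/bundle recovery (20 seeds, n = 60
patients), a 2 mm grid with n = 40 per cohort for the 200-cohort null
calibration (1,000 permutations), and n = 100 for the planted-effect
power check.  The quantile thresholds, noise level and acceptance
margins (18/20 within 2 mm; 19/20 bundle ranking wins; mean AUC ≥ 0.9;
binomial 95 % band around the 5 % rejection rate) were fixed before
the runs.

## Known limitations

- The fixed-estimates permutation default mirrors common practice but
  over-rejects under the null (see above); use
  `cv_permutation_test` or `refit=True` when calibration matters.
- One field per hemisphere is assumed; multi-lead hemispheres must be
  supplied pre-combined.
- The specificity ratio is scale-free only within a shared streamline
  index space; models fitted on different connectomes cannot be
  compared.
- `gaussian_contact_control`'s Mahalanobis cut and per-hemisphere
  pooling are declared defaults, not community standards.
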