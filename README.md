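# stimmap

Group-level mapping of deep-brain-stimulation (DBS) effects: where in
the subthalamic region stimulation helps, and which fronto-subcortical
connections carry that benefit.

`stimmap` is written for researchers analysing cohorts of DBS patients
whose stimulation fields have been reconstructed in a common template
space.  From per-hemisphere E-field magnitude volumes (NIfTI, V/m), a
normative streamline set (TRK/TCK, mm coordinates) and a cohort table
of clinical scores, it estimates:

- **Sweet-spot maps** — voxel-wise Spearman rank correlations ρ(v)
  between the E-field magnitudes E_i(v) delivered to voxel *v* and the
  percent clinical improvements y_i, restricted to voxels where at
  least 50 % of fields exceed 200 V/m;
- **Fiber filtering** — a per-streamline weight
  r_s = ρ(peak_i(s), y_i), where peak_i(s) is the peak magnitude of
  field *i* sampled along streamline *s*, computed for candidate
  streamlines traversing > 0.8 V/mm in more than 0.5 % of fields; the
  top 1 % of candidate r values form the *sweet streamline* set;
- **Outcome estimators** from both models (the Sweet Spot Score
  mean_v E(v)·ρ(v), and the weighted peak-5 % Fiber R score
  Σ top⌈5 %⌉ {r_s · peak(s)} over touched sweet streamlines), with
  fivefold cross-validation and permutation inference, cross-disorder
  specificity matrices, electrode-placement controls, and a
  β/α-compromise power analysis for correlation tests.

Patient imaging is rarely shareable, so the package ships a phantom
generator (`stimmap.synthetic`) that emulates the statistical
structure the methods assume — bilateral four-contact electrodes near
a small nucleus, analytic monotonically decaying fields, streamline
bundles, outcomes = planted-target engagement + noise — making the
whole pipeline testable end-to-end with known ground truth.

## Worked example

Fit a sweet-spot model on a simulated 60-patient cohort with a planted
dysfunctional spot, then cross-validate it with exact refit
permutations:

```python
import stimmap as sm
from stimmap.sweetspot import cv_permutation_test

scene = sm.make_scene(seed=42)
truth = sm.SimulationTruth(
    "spot", planted_spot_center=scene.nucleus_center,
    effect_size=15.0, noise_sd=sm.noise_sd_for_fraction(15.0, 0.15),
    seed=42)
cohort, _ = sm.make_cohort(scene, 60, truth)

res = sm.SweetSpotMapper.from_cohort(cohort, mirror=True).fit()
print(res.summary())

rep = cv_permutation_test([r.efields for r in cohort],
                          cohort.improvements, k=5, seed=42,
                          n_permutations=5000)
print(rep.summary())
```

```
Sweet-spot mapping results
  observations (E-fields): 120
  mask voxels:             144
  magnitude threshold:     200.0 V/m
  coverage fraction:       0.5
  r range in mask:         [+0.028, +0.588]
  peak (sweet) voxel mm:   [-10.0, -2.0, -2.0]

K-fold cross-validation
  folds:          5
  n patients:     60
  Spearman rho:   +0.700
  permutation p:  0.0002  (5000 iterations)
  seed:           42
```

The 120 bilateral fields (mirrored onto the left hemisphere) cover 144
voxels at ≥ 50 % coverage above 200 V/m; the strongest positive voxel
sits exactly at the planted target (−10, −2, −2) mm.  Held-out Sweet
Spot Scores rank-correlate with empirical improvements at ρ = 0.70,
and none of 5,000 full-refit permutations reaches that value
(p = 1/5001 ≈ 0.0002): the model's explanatory value is not a
circularity artifact.

Power of a cohort of 56 patients to detect the field-typical effect
size ρ = 0.4 under a compromise β/α = 1 design:

```python
print(sm.compromise_power(56, rho1=0.4).summary())
```

```
Compromise power analysis (H0 rho=0 vs H1 rho=0.4, one-sided, beta/alpha=1.0)
  n:           56
  critical r:  0.2106
  alpha:       0.0596
  power:       0.9404
  method:      exact
```

The same pipeline is available from the shell:

```bash
stimmap simulate  --seed 5 --out cohort/ --n-patients 60
stimmap sweetspot --config cohort/resolved_config.yaml --out maps/
stimmap crossval  --config cohort/resolved_config.yaml --out cv/
```

Each stage writes its artifacts (`r_map.nii.gz`, `scores.csv`,
`cv_report.json`, …) plus the fully resolved configuration, and reruns
from that file reproduce deterministic outputs byte-identically.

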