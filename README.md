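# trajmix

Growth mixture modelling of serial body-mass index (BMI) across birth
cohorts: who follows which life-course weight trajectory, and how does the
mix of trajectories shift between generations?

`trajmix` is aimed at epidemiologists analysing longitudinal anthropometric
data — irregular series of BMI measurements per person, taken at a handful
of study "sweeps" between childhood and mid-adulthood, pooled across cohort
studies born in different eras. It provides:

- **Growth mixture models** (`trajmix.gmm_core`): finite mixtures of latent
  growth curves. Conditional on class *k*,
  *y<sub>i</sub>* ~ MVN(*X<sub>i</sub>β<sub>k</sub>*,
  *Z<sub>i</sub>Ψ<sub>k</sub>Z<sub>i</sub>′ + R<sub>ik</sub>*), with a cubic
  age polynomial, random intercept/slope, sweep-heteroskedastic residual SDs
  σ<sub>jk</sub>, and AR(1) residual correlation
  ρ<sub>k</sub><sup>|j−l|</sup> over measurement occasions. Fitted by
  multi-start EM; individuals may deviate from their class's mean curve
  (within-class variance is freely estimated, unlike group-based trajectory
  models which fix it at zero).
- **Class enumeration** (`trajmix.model_selection`): grids over the number
  of classes (1–7) and a ladder of covariance structures, compared by
  BIC = −2·loglik + p·ln n. Entropy (classification sharpness) is reported
  but never used for selection.
- **3-step covariate analysis** (`trajmix.three_step`): Vermunt's
  classification-error-corrected multinomial regression of class membership
  on covariates such as birth cohort (the method behind the R3STEP option),
  plus the uncorrected baseline it improves on.
- **A synthetic three-cohort generator** (`trajmix.synthetic_data`)
  emulating British cohorts born 1946/1958/1970 — per-cohort sweep
  schedules, cohort-specific latent class mixes, sweep dropout — so the
  whole pipeline runs and is testable without access to gated cohort data.
- **Reporting** (`trajmix.reporting`): cohort × class contingency tables,
  class proportions, uncorrected contingency odds ratios (clearly labelled
  as such), and fitted mean curves with adult BMI bands.

See `docs/methods.md` for the model, estimation details and design choices.

## Worked example

```python
import numpy as np
from trajmix import (
    default_scenario, simulate, filter_min_observations, center_ages,
    ModelSpec, fit, assign_modal, misclassification_matrix, fit_step3,
)
from trajmix.synthetic_data import implied_odds_ratios

# three cohorts, three resolvable classes (lowest / increasing / highest)
cfg = default_scenario(scale=0.12, sex="male", n_classes=3)
ds, truth = simulate(cfg, seed=7)
ds = center_ages(filter_min_observations(ds, 3), cfg.centering_age)

spec = ModelSpec(K=3, n_sweeps=5, degree=3, ar1=True,
                 class_specific_residuals=True,
                 class_specific_intercept_var=True)
res = fit(ds, spec, n_starts=5, seed=1, n_full=2, short_iter=10, max_iter=150)
print(f"loglik={res.loglik:.1f}  BIC={res.bic:.1f}  entropy={res.entropy:.2f}")
print("class shares:", np.round([p.pi for p in res.params], 3))

labels = assign_modal(res.posteriors)
cohorts = np.array([s.cohort for s in ds.subjects])
Q = misclassification_matrix(res.posteriors, labels)
step3 = fit_step3(labels, Q, cohorts, reference_class=1,
                  reference_level="NSHD1946")
print(step3.or_table[step3.or_table["class"] == 2].to_string(index=False))
print("true ORs:", implied_odds_ratios(cfg))
```

Output from this exact run:

```
loglik=-12262.5  BIC=24793.5  entropy=0.77
class shares: [0.721 0.225 0.055]
 class covariate_level       or   ci_low  ci_high  se_logor
     2         BCS1970 1.401353 0.819811 2.395419  0.273536
     2        NCDS1958 0.758356 0.445246 1.291656  0.271702
     2        NSHD1946 1.000000 1.000000 1.000000  0.000000
true ORs: {'NCDS1958': {2: 1.0102916771435757, 3: 1.8256769759450175}, 'BCS1970': {2: 1.8243509047993707, 3: 2.6016830294530155}}
```

Reading it: the fitted classes are ordered lowest → highest by mean BMI at
the centering age (23.64 y), so class 2 is the rapidly "increasing"
trajectory. The fitted class shares (72.1 / 22.5 / 5.5%) track the
generator's pooled mix, and the corrected odds ratio for being in the
increasing class (vs lowest) in the 1970 cohort relative to the 1946 cohort
is 1.40 with CI (0.82, 2.40), bracketing the true value of 1.82 implied by
the cohort class mixes; the 1958 cohort shows no excess, matching its true
OR of 1.01. At this reduced scale (~1400 subjects) single-run odds ratios
are noisy — the classification-error correction keeps them centred on the
truth where the uncorrected regression would be attenuated toward 1.

A command-line interface mirrors the library:

```bash
trajmix simulate --scale 0.1 --seed 7 --out synth.csv --truth truth.csv
trajmix summarize --input synth.csv
trajmix fit --input synth.csv --sex male --classes 4 --seed 17 \
            --out fit.json --posteriors post.csv
trajmix select --input synth.csv --sex male --kmax 5 --seed 17 --out sel.csv
trajmix threestep --posteriors post.csv --input synth.csv \
                  --ref-level NSHD1946 --out or_table.csv
trajmix report --fit fit.json --posteriors post.csv --input synth.csv \
               --out-dir report/
```

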