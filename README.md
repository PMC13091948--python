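# tinntraj

Latent-class trajectory analysis for daily tinnitus diary (EMA) data.

Clinical tinnitus trials usually compare groups on questionnaires taken before
and after treatment, which hides the very different paths individual patients
take while being treated. When patients instead answer a short smartphone
prompt every evening — e.g. "how much did you think about your tinnitus
today?" on a 0–100 visual-analogue scale — the resulting daily series can be
clustered into a small number of latent trajectory classes (deterioration,
stable course, early improvement, late improvement, ...). `tinntraj`
implements that analysis end to end for biostatisticians working with
intensive longitudinal treatment data:

- a **synthetic-data generator** that emulates a 12-week, 147-patient EMA
  study with four latent trajectory classes, subject-level random intercepts,
  correlated secondary symptom streams (loudness, distress, jaw tension,
  negative emotion) and 22.5 % missing prompts — with full ground truth for
  recovery testing;
- **preprocessing**: compliance filtering (≥ 50 % of 84 prompts → 42
  observations; 10 % sensitivity threshold → 8), a centered seven-day moving
  average, robust (MAD-rule) outlier screening, and missingness reporting;
- a **growth mixture model**: for subject *i* in latent class *g*,

  ```
  y_ij = x(t_ij)' β_g + b_i + ε_ij,    b_i ~ N(0, σ_b²),  ε_ij ~ N(0, σ²),
  P(class = g) = π_g,
  ```

  where `x(t)` is an intercept plus a natural cubic spline of time with
  3 degrees of freedom, and the random-intercept and residual variances are
  shared across classes (compound-symmetry marginal covariance). Estimation
  is by EM with a GLS M-step and a 30-start grid search seeded from the
  one-class fit;
- **class enumeration and selection**: AIC/BIC, relative entropy, posterior
  probability of membership (PPM), class sizes, and an explicit triangulation
  rule that ranks candidate solutions;
- **class contrasts**: chi-square / one-way ANOVA across classes with
  Holm–Bonferroni adjustment, and pre–post questionnaire changes (THI, TFI,
  PHQ-9) per class against minimal clinically important differences
  (THI = 11, TFI = 9, PHQ-9 = 6);
- **symptom dynamics**: per-class mean trajectories with 95 % CIs, weekly
  loudness–distress correlations, and the intra-individually standardized
  difference z = (d − mean{d})/sd{d} with d = maximum loudness − daily
  distress.

## Worked example

```python
import numpy as np
import tinntraj as tj

cfg = tj.default_study_config(seed=1)          # 147 subjects, 84 days, 4 classes
panel, truth = tj.simulate_panel(cfg)

filtered, excluded = tj.compliance_filter(panel, tj.PRIMARY_ITEM, 0.5, 84)
smoothed = tj.smooth_panel(filtered, 84, items=[tj.PRIMARY_ITEM])
data = tj.build_model_data(smoothed, tj.PRIMARY_ITEM)

fit = tj.grid_search_fit(data, tj.LCGMMSpec(4, data.basis, data.time_scale),
                         n_starts=30, burn_iters=30, seed=1)
mapping, acc = tj.align_to_truth(fit.assignment, truth.class_label, 4)
print(np.round(fit.params.pi, 3), round(acc, 3),
      round(tj.relative_entropy(fit.posterior), 3))
```

prints

```
[0.204 0.415 0.231 0.15 ] 1.0 1.0
```

i.e. the four fitted mixing proportions (matching the realized class
frequencies of this draw; the generating proportions are 0.184/0.401/0.204/
0.211), a modal-assignment accuracy of 1.0 against the simulation's true
labels after Hungarian label alignment, and a relative entropy of 1.0
(perfectly separated classes at these noise levels).

The same pipeline is available from the shell:

```bash
tinntraj run --seed 1 --out-dir run1          # full pipeline + JSON report
tinntraj simulate --seed 1 --out panel.csv
tinntraj preprocess --panel panel.csv --out smoothed.csv
tinntraj compare --run-a run1/final_fit.json --run-b run2/final_fit.json
```

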