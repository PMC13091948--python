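# Methods

## The model

`tinntraj` estimates a growth mixture model (a latent-class linear mixed
model) for daily diary outcomes on a 0–100 visual-analogue scale. Subject
*i* with latent class *g* contributes observations

    y_ij = x(t_ij)' β_g + b_i + ε_ij,
    b_i ~ N(0, σ_b²),   ε_ij ~ N(0, σ²),   P(class = g) = π_g,

with `x(t) = (1, N₁(t), …, N_df(t))` an intercept plus a natural cubic
spline basis of time. Both variance components are shared across classes, so
each subject's marginal covariance is compound-symmetric,
`Σ_i = σ_b² J + σ² I`. The class-membership model is intercept-only: no
covariates enter either the trajectory or the membership model.

Key modelling defaults, all configurable:

| parameter | default | meaning |
|---|---|---|
| spline df | 3 | basis columns; 2 interior knots |
| interior knots | terciles of pooled observed times | boundary knots at observed min/max |
| time scale | max observed day | time mapped to [0, 1] for conditioning |
| compliance fraction | 0.5 (sensitivity 0.1) | floor(fraction × 84) observed days required |
| smoothing window | 7 days, centered | truncated at study edges |
| grid search | 30 starts × 30 burn-in iterations | retried once with 50 starts on failure |
| EM tolerance | 1e-8 relative log-likelihood change | max 500 iterations |

### Likelihood and estimation

Per-subject likelihoods use the rank-one closed form of the
compound-symmetry inverse and determinant (`Σ⁻¹ = σ⁻²[I − c J]` with
`c = σ_b²/(σ² + n σ_b²)`), so only the per-subject residual sum and sum of
squares are needed; no dense matrix is built and subjects with any number of
observations are handled uniformly.

Estimation is by EM:

- **E-step**: posterior class probabilities `p_ig ∝ π_g exp(ℓ_ig)`, computed
  with log-sum-exp stabilization.
- **M-step**: `π_g` = mean posterior; `β_g` by posterior-weighted
  generalized least squares under the compound-symmetry covariance (exact
  maximizer of the expected complete-data log-likelihood given the
  variances); the two variance components by direct Nelder–Mead maximization
  of the observed mixture log-likelihood over (log σ_b², log σ²) with the
  residual statistics held fixed, accepting the step only if it improves.

Each part of the cycle is monotone, so the observed-data log-likelihood is
non-decreasing across iterations; the test suite asserts this on every
fitted panel. The reference estimator for this model family uses a
Marquardt-type quasi-Newton ascent instead; both target a stationary point
of the same marginal likelihood, and the one-class special case is verified
against `statsmodels` MixedLM (ML). `σ` is floored at 1e-4 to avoid
degenerate spikes; a class whose posterior mass falls below one
subject-equivalent marks the run as non-converged with a diagnostic rather
than silently continuing.

Multi-start grid search: starting points perturb the one-class solution,
`β_g = β̂₁ + N(0, (c·SE)²)` per class with `c = 1` by default and uniform
mixing proportions; each start runs 30 burn-in EM iterations and the best
log-likelihood is refined to full convergence. All draws derive from a
single seed, so fits are exactly reproducible.

Mixture labels are arbitrary; for stable reporting `relabel_by_baseline`
orders classes by fitted day-0 mean (descending), and recovery tests align
labels to ground truth with the Hungarian algorithm on the confusion matrix.

### Confidence bands

Pointwise 95 % bands for class trajectories use the delta method with the
per-class weighted-GLS information: `Var(x'β_g) = x' I_g⁻¹ x`,
`I_g = Σ_i p_ig X_i' Σ_i⁻¹ X_i`. This treats posterior weights as known and
therefore slightly understates uncertainty near class boundaries; it is a
deliberate, documented simplification — the band construction for the
original figures is not specified anywhere.

## Class enumeration and selection

`enumerate_classes` fits G = 1…10 (configurable) and tabulates
log-likelihood, parameter count (`G(1+df) + (G−1) + 2`), AIC, BIC (sample
size = number of subjects, the subject-level-mixture convention), relative
entropy `1 − Σ_i Σ_g −p_ig ln p_ig / (N ln G)`, per-class mean posterior of
assigned members (PPM), class proportions and convergence. Non-convergent
rows are flagged, never dropped.

`select_model` encodes the triangulation explicitly: candidates with any
class below 5 % (default) or without convergence are flagged; among the
remaining preferred solutions (default G ∈ {3, 4, 5}) it ranks by entropy,
then mean PPM, then BIC, comparing entropy and PPM at 3 decimals so that
numerically indistinguishable classifications fall through to BIC instead of
being decided by floating-point noise. Undefined entropy (G = 1) ranks below
any defined value. The report lists every candidate with reasons; the
recommendation is never a silent single answer.

On data smoothed with a seven-day moving average the residuals are serially
correlated beyond what the random intercept absorbs, so AIC/BIC decrease
almost monotonically in G without a clean minimum — the enumeration tables
produced here reproduce that pattern, which is why the entropy/PPM/size
criteria carry the selection weight.

## Contrasts and clinical relevance

Baseline variables are compared across latent classes with chi-square tests
of independence (categoricals; one test per variable) and classical one-way
ANOVA (continuous; Welch's correction is not applied, matching the common
default). All testable variables form a single Holm–Bonferroni family; the
step-down adjustment is implemented directly and cross-checked against
`statsmodels.multipletests` in tests. Constant variables are reported as
untestable and excluded from the family.

Pre-to-post questionnaire changes (THI, TFI, PHQ-9) are tested per class
with paired t-tests (Holm-adjusted within each instrument) and flagged
clinically relevant when the mean class improvement reaches the MCID
(THI = 11, TFI = 9, PHQ-9 = 6); the boundary counts as relevant. Treatment
arm by class is exported as a count table only — cell sizes in studies of
this scale do not support testing.

## Symptom dynamics

Weekly correlations between two symptom streams pool all (subject, day)
pairs within each class-week (days 0–6 = week 1); a per-subject-averaged
variant is available, and correlations are computed on smoothed series by
default (raw available). r is withheld below 3 pairs or for constant
streams. The standardized difference uses d = maximum loudness − daily
distress per day, z-scored within subject with the sample (n−1) standard
deviation; subjects with constant d are excluded from class summaries and
counted. Daily class-mean z series are trend-smoothed with a centered
rolling mean (14-day span) purely for display.

## The synthetic-data generator

The generator mirrors the study design the analysis assumes: 147 subjects ×
84 days, four latent classes with mixing proportions
(0.184, 0.401, 0.204, 0.211) and anchor trajectories

- deterioration: 38 → 56,
- stable course: 41 → 34 (day 34) → 39,
- early improvement: 60 → 36 (day 42) → 32,
- late improvement: 36 → 40 (day 26) → 25,

interpolated with shape-preserving monotone cubics (PCHIP), so curves pass
exactly through the anchors and never overshoot the scale. Subject random
intercepts are N(0, 8²) and daily residuals N(0, 6²) — the printed study
reports no variance components, so these were fixed once as plausible
magnitudes for 0–100 VAS diary data. Values are clamped (not censored) at
the scale bounds; the fitted model ignores the bounds, a documented mismatch
that is benign because the default class means stay well inside them.
Five secondary items (daily distress, maximum and momentary loudness, jaw
tension, negative emotion) are linear in the primary outcome plus Gaussian
noise, with offsets/slopes chosen so distress tracks the outcome closely,
loudness is rated highest and jaw tension weakest.

Missingness removes whole subject-days. MCAR draws an exact-count uniform
sample at the 22.5 % target; MAR makes the per-day removal probability
logistic-increasing in age, rescaled to the same expected fraction. Day
indexing is 0-based (day 0 = first treatment day, days 0–83). A single seed
governs all draws.

What the generator does **not** emulate: streaky, subject-clustered
non-response (real compliance varies much more between subjects, so the
50 % filter excludes almost no simulated subjects while it excluded ~40 % of
the real cohort); within-day timing of momentary items; treatment-arm
effects; and residual autocorrelation beyond what the seven-day smoothing
itself induces. Passing recovery tests therefore demonstrates that the
estimator recovers the generating process under idealized missingness — not
that every feature of field EMA data is harmless. Relatedly, smoothing
nearly eliminates missingness here (<0.1 % residual vs ~3 % in the real
data), because MCAR gaps are rarely 7 days long.

The baseline/outcome table draws covariates independently of class by
default (the null scenario the reference cohort exhibits — no baseline
variable predicted membership); configurable per-class mean shifts inject
signal for power checks. Questionnaire post scores are pre + class-specific
change + noise, clamped to instrument ranges; the default class-change
vectors qualitatively reproduce the published pattern of which classes reach
each instrument's MCID.

## Numerical and design choices

- Compliance thresholds round down (`floor`), reconciling 42 = 50 % of 84
  and 8 = 10 % of 84.
- The moving average is centered and truncated at edges, requiring ≥ 1 raw
  value in the window; partial edge windows are kept (the alternative —
  dropping edge days — is a flagged sensitivity, not the default).
- Outlier screening replaces irreproducible visual inspection with a MAD
  rule: a subject is flagged when its smoothed-series median is more than
  k = 4 scaled MADs (1.4826 × MAD) from the cohort median of medians;
  flagged, not auto-removed.
- The natural cubic spline basis is the truncated-power ("d_k − d_{K−1}")
  construction: linear beyond the boundary knots, C² inside, df columns;
  tests verify span-equivalence with patsy's `cr` basis on identical knots.
- Holm, entropy and PPM variants are the standard normalized forms; the
  exact variants used by the reference implementation are not published, so
  ours are documented alternatives.
- Problem sizes in the test suite follow the study design (147 × 84 for
  recovery and selection-consistency checks; 10 seeded replicates at 10
  grid-search starts for enumeration; 1000 small cohorts for type-I-error
  calibration).

## Known limitations

- No random slopes, no class-specific variances, no covariates in the
  membership model, no Bayesian estimation, no bootstrap likelihood-ratio
  test for G — all outside the analysis this package reproduces.
- Missing data are never imputed; MNAR mechanisms beyond age-linked MAR are
  not simulated.
- Posterior-weight uncertainty is ignored in trajectory bands (see above).
- The EM variance step uses a derivative-free local search; it is robust at
  these problem sizes but slower than a closed-form update would be.
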