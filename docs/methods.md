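# Methods

This note documents the modelling choices behind the package: what is
computed, under which assumptions, with which defaults, and what the
synthetic-data tests do and do not demonstrate.

## Risk-factor coding

Thirteen risk factors are coded 0/1 from raw measurements by disjunctions
of threshold conditions. Boundary operators are applied literally as the
cutoff table states them: `≥` cutoffs (obesity, hypertension, diabetes,
dyslipidemia thresholds, pack-years, alcohol frequency) fire at the
threshold value; `>` cutoffs (liver enzymes, pure-tone average,
tachycardia) and `<` cutoffs (bradycardia, anemia, FEV₁/FVC, FEV₁
%predicted, VO₂max) are strict. The normal resting-heart-rate band is
therefore the closed interval [50, 100] beats/min, and a VO₂max exactly at
the reference lower bound is *not* low fitness.

Missing data at the coding stage: a disjunction is evaluated over the
constituents that are present; the flag is *missing* only when every
constituent is absent, in which case it counts as 0 in the tier sums and a
warning is logged. This is deliberately conservative — absent measurements
never invent risk — and is separate from the regression-stage imputation
below. FEV₁/FVC must arrive on the percent scale; values in (0, 2] are
rejected as probable 0–1 ratios rather than silently coded.

The VO₂max reference is a per-sex table of half-open age bands, shipped as
an editable YAML. The packaged default values are **placeholders** in the
plausible range for healthy adults (5-year bands, male bounds 36→24 and
female 28→17 mL/kg/min from ages 18 to 65+); occupational-guideline tables
are licensed documents and users applying a specific guideline must supply
its band bounds. The band structure (no gaps, no overlaps, [18, 120)
coverage) is validated at load time.

## Outcome and category

The total risk count maps to suitable (0–3), caution (4–5), unsuitable
(≥6). The *unsuitable* indicator — a deterministic function of the flags —
is the dependent variable of the weighting regression. This circularity is
intentional and inherited from the index's design: the regression's role is
to distribute weight across factors according to how strongly each
co-occurs with rule-based unsuitability, not to discover an external
outcome. The package never claims discrimination against specialist
judgment, for which no data are available.

## Weighting fit

Design matrix: 13 flags plus age (years) and sex (male = 1, female = 0,
fixed and documented as an arbitrary but stable coding). Columns are
mean-imputed (means from the training rows only) and z-scored (population
SD; zero-variance columns standardize to all-zeros rather than NaN). The
fitted imputation/scaling parameters are reused verbatim for held-out rows.

The penalty is parameterised as `(1/n)·deviance + λ‖β‖₁` (the lasso/glmnet
convention), mapped to scikit-learn's saga solver via `C = 1/(n·λ)`; the
intercept is unpenalized. `λ = "auto"` (default) minimises stratified
k-fold cross-validated deviance over a 20-point log grid spanning
`[λ_max/100, λ_max]`, where `λ_max = max|X'(y − ȳ)|/n` is the smallest
penalty that zeroes every coefficient; folds default to k = 5 (reduced to
the minority-class count when that is smaller), shuffled with a fixed seed;
deviance ties resolve to the larger λ. No λ-selection policy is part of the
index's published definition, so this is the package's own, reproducible
convention — exact reproduction of any particular published coefficient
magnitude is not a goal, only the coefficient→weight arithmetic, which is
exact.

Weights: factor coefficients (covariates excluded) are truncated at zero
and normalized to sum to 1. If every coefficient is ≤ 0 the weight set is
emitted as an explicit all-zero *degenerate* set with a hard warning rather
than an exception — small bootstrap resamples need this robustness. Note a
documented scale caveat, kept for fidelity to the index's published
construction: coefficients are estimated on z-scored predictors but applied
to raw 0/1 flags, so a factor's weight partly reflects its prevalence
(`sd = √(p(1−p))`), not purely its log-odds effect.

Scores: `raw = Σ w_f·x_f ∈ [0, 1]`, `CSSI = 100·raw`; missing flags
contribute 0.

## Internal validation

LOOCV refits the *entire* pipeline (imputation means, scaling, λ if
"auto", fit) on each n−1 training set; nothing about the held-out worker
touches the fold's transform or model. A fold whose training outcome is
single-class yields the training prevalence as the held-out probability and
is counted as degenerate. The thresholded classifier uses the penalized
model's predicted probability at 0.50 — a threshold only meaningful on the
probability scale, not on the 0–100 additive score.

AUROC is the midrank Mann–Whitney statistic (ties count ½); AUPRC is
step-wise average precision with tied probabilities grouped as one step.
Both are implemented directly because these tie policies are part of the
contract, and are cross-checked in tests against scikit-learn and against
brute-force pairwise/threshold-sweep oracles. Degenerate ratios (0/0)
return an explicit `None`; report values are rounded half-up to 3 decimals
for display with full precision retained in `*_raw` fields.

Bootstrap stability draws B resamples of size n with replacement
(unstratified), refits the pipeline, and counts a factor as *selected* when
its raw coefficient is strictly positive — mirroring the positive-weight
rule; a "nonzero" rule is available by flag. Resamples with fewer than 2
unsuitable workers are redrawn (bounded retries, redraw count reported).

## Synthetic cohort generator

The generator emulates the published cohort's *marginal* structure: per-sex
mean ± SD for each of 22 continuous variables, a 72/111 male fraction, and
per-sex prevalences for the binary inputs. The joint distribution is a
Gaussian copula; the correlation matrix defaults to identity because the
source tables report no correlation structure, with a clearly-labelled
non-published "realistic" preset available (BMI–waist 0.8, SBP–DBP 0.7,
total–LDL cholesterol 0.9, AST–ALT 0.7).

Marginal families are chosen per variable from its mean/SD and physiologic
bounds:

* SD = 0 → constant (female pack-years, published as 0.0 ± 0.0);
* normal out-of-bounds mass ≤ 1% → normal draw with per-entry rejection
  (≤ 20 rounds) then clipping;
* otherwise → moment-matched gamma on `value − floor`, reproducing the
  published mean and SD exactly with support ≥ 0.

The gamma branch exists because a normal truncated at zero cannot attain a
coefficient of variation above ≈ 1, while several published marginals
exceed it (male pack-years CV 1.44, female alcohol frequency CV 2.33);
liver enzymes, triglycerides and exposure variables are right-skewed in
real populations, so the skewed family is also the more realistic choice.
Age is exempt from optional missingness injection since coding requires it
for the VO₂max bands.

Medication-use prevalences are not published; the defaults
(antihypertensive 0.08, antidiabetic 0.02, lipid-lowering 0.04) are
plausible for a working-age cohort and are user-configurable. ECG
abnormality uses the published per-sex fractions (11/72 male, 4/39 female).

**What passing synthetic tests show and don't show.** The generator
reproduces marginals, not the real joint distribution: real metabolic risk
factors cluster, so the synthetic rule-based unsuitable prevalence (~2%)
is lower than the published cohort's (5.4%), and synthetic discrimination
estimates do not transfer to any real population. Parameter-recovery and
bootstrap-stability results demonstrate that the machinery recovers known
planted structure — not that the published weights are correct.

## Problem sizes and numerical choices

Test and demonstration sizes are chosen as the smallest that make each
property sharp: n = 600 for end-to-end pipeline demonstrations (enough
rule-based unsuitable workers for stable stratified CV), n = 2000 × 50
seeds for planted-effect rank recovery, B = 200 × n = 500 for bootstrap
stability, n = 10,000 for generator calibration (4-standard-error bands,
with the SD's standard error adjusted for the gamma marginals' excess
kurtosis). Fixed moderate penalties (λ = 0.01–0.05) are used in
planted-truth checks, where nested λ selection would only add noise to the
property being measured; the LOOCV demonstrations reuse the full-sample
cross-validated λ per fold (both per-fold reselection and reuse are
supported). The saga solver runs with tol 1e-6 and up to 20,000 iterations;
non-convergence raises an explicit fitting error rather than returning a
silent partial solution.

## Known limitations

* The VO₂max reference bands are placeholders; reproducing any specific
  guideline's coding requires supplying that guideline's table.
* Weights inherit prevalence dependence from the z-scored-fit /
  raw-flag-scoring mismatch described above.
* The unsuitable outcome is derived from the same flags it is regressed
  on; the validation quantifies internal consistency, not clinical
  validity against specialist judgment.
* Bootstrap "selection" of a factor is sensitive to λ; frequencies are
  comparable only within one λ policy.
* The generator models no measurement error, no informative missingness,
  and no dependence between medication flags and measured values.
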