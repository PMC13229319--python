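# cssi — Confined-Space Suitability Index

A Python package for building and internally validating an additive
fitness-for-duty screening score for confined-space work, intended for
occupational-health researchers and biostatisticians who work with routine
health-examination data.

Confined spaces combine poor ventilation, heat load, respiratory protective
equipment, and delayed rescue. Screening workers before entry therefore has
to weigh cardiopulmonary reserve, metabolic stability, sensory function and
lifestyle exposures together. The CSSI summarises these as a single 0–100
score built from 13 dichotomous risk factors in three tiers:

* **Tier 1 — anthropometric/metabolic (7):** obesity, hypertension,
  diabetes, dyslipidemia, elevated liver enzymes, abnormal resting heart
  rate, anemia;
* **Tier 2 — functional/physiological (4):** hearing loss, abnormal
  pulmonary function, abnormal ECG, low cardiorespiratory fitness
  (VO₂max below the age/sex reference lower bound);
* **Tier 3 — lifestyle (2):** significant smoking history (≥ 20
  pack-years), habitual alcohol use (≥ 2 times/week).

## The model

Each worker's measurements are coded into flags `x_f ∈ {0, 1}` by fixed
clinical cutoffs (e.g. hypertension: SBP ≥ 140 mmHg, DBP ≥ 90 mmHg, or
antihypertensive medication). The total count drives a rule-based category:

    0–3 suitable · 4–5 caution · ≥6 unsuitable

The *unsuitable* indicator `y` is then regressed on the 13 flags (plus age
and sex as covariates, mean-imputed and z-scored) with an L1-penalized
logistic model,

    min_{β0, β}  (1/n) Σ_i log(1 + e^{−ỹ_i(β0 + x_i'β)}) + λ‖β‖₁ ,

and the factor coefficients are truncated at zero and normalized,

    w_f = max(β_f, 0) / Σ_g max(β_g, 0) ,         CSSI_i = 100 · Σ_f w_f x_{if} .

A negative coefficient would read as "protective", which a screening index
must not encode; truncation forces every factor to contribute ≥ 0.
Internal validation uses leave-one-out cross-validation (the whole
pipeline — imputation, scaling, fit — refit per fold), AUROC/AUPRC on the
pooled out-of-fold probabilities, a confusion matrix at probability 0.50,
and a bootstrap that reports how often each factor is selected (coefficient
> 0) across resamples.

Because the underlying worker-level study data are not publicly deposited,
the package ships a seeded synthetic-cohort generator whose per-sex
marginal means/SDs reproduce the published summary table, so every stage is
testable end to end.

## Worked example

```python
from cssi import (CohortParams, FitSpec, code_cohort, compute_score,
                  derive_weights, fit_weights, generate_cohort)

# published positive coefficients -> additive weights
coef = {"dyslipidemia": 6.075, "low_fitness": 3.242,
        "abnormal_resting_hr": 3.063, "hypertension": 2.992,
        "abnormal_ecg": 2.343, "habitual_alcohol": 1.030,
        "abnormal_pulmonary": 0.730, "elevated_liver_enzymes": 0.586,
        "obesity": 0.465}
weights = derive_weights(coef)
print({f: round(w, 3) for f, w in weights.normalized.items() if w > 0})

# full synthetic pipeline
cohort = generate_cohort(CohortParams(), 600, seed=11)
profiles = code_cohort(cohort)
print("unsuitable:", sum(p.category.value == "unsuitable" for p in profiles))
ws, model, _ = fit_weights(profiles, cohort, FitSpec(penalty_lambda="auto",
                                                     seed=0))
s = compute_score(profiles[0], ws)
print(f"worker {s.worker_id}: CSSI {s.cssi_score:.1f} ({s.category.value})")
```

prints

```
{'obesity': 0.023, 'hypertension': 0.146, 'dyslipidemia': 0.296,
 'elevated_liver_enzymes': 0.029, 'abnormal_resting_hr': 0.149,
 'abnormal_pulmonary': 0.036, 'abnormal_ecg': 0.114, 'low_fitness': 0.158,
 'habitual_alcohol': 0.05}
unsuitable: 15
worker W00000: CSSI 29.8 (suitable)
```

The first block is the published coefficient table renormalized by the
package: dyslipidemia carries 29.6% of the additive score, low fitness
15.8%, and so on (they sum to 1). The synthetic 600-worker cohort contains
15 rule-based unsuitable workers; worker `W00000`'s flags weighted by the
freshly fitted weights give a CSSI of 29.8 on the 0–100 scale, inside the
suitable band.

The same stages are available from the shell:

```sh
cssi simulate --n 600 --seed 11 --out cohort.csv
cssi code --in cohort.csv --out profiles.csv
cssi fit --profiles profiles.csv --cohort cohort.csv --seed 0 --out weights.json
cssi score --profiles profiles.csv --weights weights.json --out scores.csv
cssi run --n 600 --seed 11 --out bundle/        # everything at once
```

## Layout

| Module | Contents |
| --- | --- |
| `cssi.cohort` | synthetic cohort generator, outcome planting |
| `cssi.risk` | cutoff tables, 13-factor coding, fitness category |
| `cssi.weighting` | preprocessing, L1 logistic fit, weights, scoring |
| `cssi.evaluation` | LOOCV, confusion/ranking metrics, bootstrap |
| `cssi.io` | CSV/JSON/YAML formats, `RunConfig`, full pipeline |
| `cssi.cli` | `cssi` command-line verbs |

See `docs/methods.md` for modelling assumptions, parameter defaults, and
known limitations.
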