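# ntcpx

Multivariate logistic NTCP modelling of patient-rated xerostomia after
intensity-modulated radiotherapy (IMRT) for head-and-neck cancer, with
LASSO-based prognostic-factor selection.

## The problem

Xerostomia (dry mouth) is the most common late toxicity of head-and-neck
radiotherapy. A normal tissue complication probability (NTCP) model predicts
each patient's risk of moderate-to-severe (grade 3+) patient-rated
xerostomia — a score of 66 ("quite a lot") or 100 ("a lot") on the
four-point Likert xerostomia item of the EORTC QLQ-H&N35 — at 3 or 12
months after IMRT, from the mean doses to the contralateral and ipsilateral
parotid glands (Dmean-c, Dmean-i, in Gy) and 14 clinical factors (age,
gender, education, staging, smoking, baseline xerostomia, ...). Patients who
already report grade 3+ xerostomia at baseline are excluded, since the
interest lies in radiation-induced symptoms.

The model is a multivariate logistic regression

```
NTCP = e^S / (1 + e^S),    S = β₀ + Σᵢ βᵢ xᵢ ,
```

whose factor set is chosen from 16 candidates by an L1-constrained
(LASSO) fit: maximising the binomial log-likelihood subject to
`Σ|βⱼ| ≤ t` shrinks coefficients and zeroes weak ones. As the budget `t`
relaxes, factors enter one by one; the entry order ranks them. Two model
sizes are then derived:

* **optimal** — the tuning parameter minimising the validation deviance in
  nested stratified 10-fold cross-validation;
* **suboptimal (compact)** — walk the ranking, accept the first prefix whose
  Hosmer-Lemeshow test shows calibration (p ≥ 0.05), then keep adding
  factors only while the AUC still gains ≥ 5%.

A bootstrap forward-selection-by-likelihood comparator and a performance
panel (AUC with bootstrap 95% CI, scaled Brier score, Nagelkerke R²,
Omnibus likelihood-ratio test, Hosmer-Lemeshow test) complete the pipeline.
Because the underlying patient records are not public, the package ships a
synthetic-cohort generator that reproduces the reported factor marginals
and draws outcomes from a known (by default, published) coefficient set, so
every stage is testable end to end.

## Worked example

```python
from ntcpx import (SyntheticConfig, generate_cohort, derive_endpoint,
                   NtcpLogisticRegression, evaluate_model, published_model)

cfg = SyntheticConfig(n_patients=500, seed=7, timepoint_label="12m")
cohort = generate_cohort(cfg)
ep = derive_endpoint(cohort.frame, "12m")
print("assessed:", ep.n_assessed, "| excluded at baseline:", ep.n_excluded_baseline,
      "| analysable:", len(ep.included), "| events:", ep.n_events)

est = NtcpLogisticRegression(factors=["dmean_i", "dmean_c", "smoking"]).fit(
    ep.included, ep.included["outcome"])
report = evaluate_model(est.model_, ep.included, ep.included["outcome"],
                        n_boot=500, seed=7)
```

prints

```
assessed: 500 | excluded at baseline: 51 | analysable: 449 | events: 106
S = -8.942  0.120*dmean_i + 0.058*dmean_c + 1.282*smoking
AUC 0.842 (95% CI 0.802-0.881) | scaled Brier 0.286 | R2 0.385 | HL p 0.432
published 12m compact NTCP for this patient: 0.281
```

51 of 500 simulated patients carry grade 3+ xerostomia at baseline and are
excluded; the three-factor refit recovers dose and smoking effects close to
the generating values; apparent discrimination (AUC 0.84) and calibration
(HL p = 0.43) are what a correctly specified compact model should show on
its development data. The last line evaluates the published 12-month
compact model for a patient with Dmean-i = 45 Gy, Dmean-c = 20 Gy, a
smoker with senior-school education and a T2 tumour.

The same analysis is available from the shell:

```bash
ntcpx simulate --n 500 --seed 7 --timepoint 12m --out cohort.csv
ntcpx run-all --cohort cohort.csv --timepoint 12m --seed 7 --out-dir results/
```

which writes the endpoint summary, tidy LASSO-path CSV, entry-order
ranking, selection traces (suboptimal, nested-CV optimal, forward-LL),
model JSONs with odds-ratio tables, and the performance report.

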