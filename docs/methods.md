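# Methods

## Model

The endpoint is binary grade 3+ patient-rated xerostomia: a score of 66 or
100 on the four-point Likert xerostomia item (0 / 33 / 66 / 100) at the 3-
or 12-month follow-up. Patients scoring 66+ already at baseline are
excluded before modelling; the exclusion threshold deliberately equals the
endpoint cut. Reported event rates are counted against all assessed
patients (before the baseline exclusion), matching the usual cohort
accounting.

Risk is modelled by multivariate logistic regression,
`NTCP = expit(β₀ + Σ βᵢ xᵢ)`. Continuous predictors enter untransformed —
parotid mean doses in Gy, age in years — so coefficients live on those
scales; binary factors enter as 0/1; categorical factors (education, AJCC
stage, T stage, financial status) are reference-coded into indicator
columns. Reference levels default to the first declared level and are
configurable per factor (`CodingScheme.with_reference`), because published
coefficient tables for this endpoint use inconsistent reference choices
(e.g. T stage referenced on T4). Maximum-likelihood fitting and Wald
standard errors come from the observed information (statsmodels); perfect
or quasi-separation raises a diagnostic `SeparationError` rather than
returning divergent coefficients. Odds ratios are `exp(β)` with Wald 95%
CIs `exp(β ± 1.96·se)`.

## LASSO path, ranking, and tuning

Factor selection uses L1-constrained logistic regression: maximise the
binomial log-likelihood subject to a budget `Σ|βⱼ| ≤ t` on the
*standardized* coefficients (columns scaled to unit variance; intercept
unpenalized; categorical dummies penalized individually). The solver works
in the equivalent Lagrangian form — cyclic coordinate descent on IRLS
quadratic approximations with active-set sweeps and warm starts along a
descending penalty grid, the standard path algorithm for this problem; it
agrees with an independent L1 solver to ~1e-7 in the tests. Budget-form
fits invert the penalty-to-budget map by bisection and report the achieved
budget, which never exceeds the request.

The default grid holds 100 log-spaced penalties from the smallest penalty
that zeroes every coefficient down to 1e-3 of it. Factors are ranked by
entry order — the first grid point at which any of their design columns
becomes nonzero (threshold 1e-8); ties break by the larger absolute
standardized coefficient at the least-constrained fit, and never-entered
factors are ordered last by the same magnitude.

The *optimal* tuning parameter minimises the mean validation deviance in
stratified 10-fold cross-validation, nested inside an outer 10-fold loop
whose per-fold factor subsets are reported as a stability audit; the final
subset is read off the full-data path at the inner-CV-chosen penalty.

## Suboptimal (compact) selection

Walking the ranking in order, the maximum-likelihood model is fitted at
each prefix size. The first size whose Hosmer-Lemeshow p-value is ≥ 0.05
passes the calibration gate; thereafter a larger prefix is accepted only
while its AUC gain over the current accepted model is at least 5%. The
gain is interpreted as a *relative* change (configurable to absolute),
reading "did not increase significantly (<5%)" as a percentage change. If
no prefix ever calibrates, the trace reports an explicit "no calibrated
model" status instead of silently falling back.

## Bootstrap forward selection

The comparator draws bootstrap resamples (2000 by default; resamples with
a single outcome class are redrawn, capped at 100 retries), runs greedy
forward selection by fitted log-likelihood within each resample, and
scores every model order by the mean per-record out-of-bag log-likelihood.
The order with the highest mean out-of-bag score wins; the definitive set
consists of the factors most frequently selected up to that order across
resamples. Out-of-bag records were chosen as the evaluation set because
the procedure needs an out-of-sample likelihood and the bootstrap already
provides one without a second data split.

## Performance panel

* **AUC** — Mann-Whitney concordance (ties ½), with a stratified
  percentile-bootstrap 95% CI (2000 resamples by default, cases and
  controls resampled separately).
* **Brier / scaled Brier** — `1 − Brier / (p̄(1−p̄))`, the skill relative to
  always predicting the prevalence; exactly 0 for the prevalence predictor
  on any dataset.
* **Nagelkerke R²** — Cox-Snell `1 − exp(2(ll₀−ll)/n)` divided by its
  maximum `1 − exp(2·ll₀/n)`.
* **Omnibus** — likelihood-ratio χ² against the intercept-only model, df =
  number of added design columns (each dummy counts).
* **Hosmer-Lemeshow** — deciles of predicted risk,
  `Σ (O−E)²/(n_g p̄_g(1−p̄_g))`, df = groups − 2 for predictions fitted on
  the same data (pass `df=groups` for externally supplied probabilities);
  degenerate risk groups merge into their neighbour with a warning.

All panel metrics are apparent (computed on the fitting data), which is how
development-cohort performance tables are conventionally reported; honest
out-of-sample estimates are available through the CV machinery.

## Synthetic cohorts

The generator emulates the reported cohort structure so the whole pipeline
is testable without patient data:

* Continuous factors are drawn from scaled Beta distributions on the
  reported ranges (Dmean-c 4.9–68.3 Gy, Dmean-i 12.2–70 Gy, age 26–89 y)
  with the mode at the reported median and concentration a+b = 6, giving a
  realistic unimodal spread (~19% of the range as one SD). Only range and
  median are reported, so any bounded unimodal family is defensible; Beta
  was chosen for exact range support.
* Categorical factors follow the reported level frequencies (normalised —
  one reported row does not sum exactly to its cohort size).
* Factors are drawn independently; no covariance structure is reported.
* Outcomes are Bernoulli draws from a known logistic model, by default the
  published 12-month compact coefficient set, and the follow-up Likert
  score is set consistently with the drawn outcome (66/100 vs 0/33).
* A configurable fraction of patients (default 21/206 ≈ 10.2%) receives a
  baseline score of 66, exercising the exclusion path; injected counts are
  exact (`round(prevalence·n)`).
* One root seed; factor draws, outcome draws, score assignment and
  baseline injection each use a deterministic child stream, so identical
  configs give byte-identical cohorts.

What passing tests on these cohorts do **not** show: real cohorts have
correlated factors (dose with stage, smoking with gender), measurement
drift in patient-reported scores, and informative 12-month dropout; none
of these are simulated, so recovery and selection results here bound the
method's behaviour under ideal sampling only.

A note on effect sizes: the published coefficient set used as the default
truth implies far stronger discrimination than the AUC ≈ 0.84 reported for
the real cohort (the age term alone, 0.285 per year across a 63-year
range, nearly separates independent draws). Under these generating
conditions the compact-selection rule usually stops at one factor — the
univariate age model already calibrates and further AUC gains fall under
5% — even though the LASSO ranking reliably places all generating factors
on top. Both behaviours are faithful consequences of the printed numbers.

## Numerical choices and scaled-down defaults

* Coordinate descent converges on coefficient change < 1e-7 or penalized
  objective change < 1e-11; budget bisection tolerance 1e-6 (relative).
* Logistic Newton fits inside resampling loops use step-halving and flag
  (rather than chase) separation beyond |β| = 35 on the working scale.
* Probabilities are clipped to [1e-12, 1−1e-12] before log-likelihoods.
* Empty indicator columns (a level nobody occupies) are dropped with a
  logged notice; they are inestimable.
* Test and acceptance runs use scaled-down sizes chosen for desk-scale
  turnaround: cohorts of 500–5000, 10–60-point penalty grids, 25–50
  bootstrap resamples, 10–20 seeds per stochastic claim. Defaults in the
  API remain at the full analysis settings (100-point grid, 2000
  bootstraps, 10-fold nesting).

## Known limitations

* No grouped penalty for categorical factors; a factor "enters" when its
  first dummy does.
* The AUC CI is percentile-bootstrap only; no analytic (DeLong) variance.
* Forward selection's "modal" definitive set is frequency-based; exact
  subset voting is not implemented.
* No decision-curve analysis or graphical calibration beyond the HL
  grouping; the tidy path CSV is exported for external plotting.
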