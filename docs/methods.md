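# Methods notes

## Model and procedure

The pipeline compares quality-indicator (QI) outcomes between two national
breast cancer registries while correcting for case-mix differences and
without moving patient-level data.

1. **Eligibility.** Per QI, each registry node filters its own rows to the
   QI's denominator minus exclusions (a local operation; nothing is
   released). The propensity model is refitted per QI on that QI's eligible
   population, because eligibility changes the case mix and hence the
   balance problem.
2. **Federated propensity fit.** The propensity score is the logistic
   probability of belonging to the reference country given the nine
   dummy-coded covariates (year, age band, histology, grade, pT, pN, HER2,
   ER, PR; 24 design columns including intercept). IRLS is run by an
   in-process aggregator: nodes return Σwxxᵀ (p×p), Σwxz (p), their deviance
   contribution and n; the aggregator solves and broadcasts β. Because these
   partial sums are exactly additive, the federated solution equals the
   centralized one up to floating-point associativity; the pooled
   statsmodels GLM is kept as an independent validation route, never as the
   implementation.
3. **Stratification.** Fitted scores are released (score + country label —
   the single per-record exchange) and cut at pooled-sample quantiles into
   k equal-count strata. Quantiles are taken on the pooled distribution so
   that strata are common to both countries.
4. **Balance.** The standardized mean difference is computed per covariate
   *level* (dummy proportion), not aggregated per variable, because single
   levels can remain imbalanced while the rest of the variable balances.
   After stratification, per-stratum SMDs are combined as a mean weighted by
   total stratum size; strata empty for one country are excluded with a
   warning. |SMD| > 0.1 flags imbalance.
5. **Estimation.** Crude proportion (Wilson 95% CI); stratum-averaged
   proportion (unweighted mean over occupied strata; 95% CI from the
   between-stratum standard deviation, est ± 1.96·sd/√k_eff); stratified
   Mantel-Haenszel odds ratio with Robins-Breslow-Greenland CI; verdicts
   against the EUSOMA minimum standard and target using the
   stratum-averaged estimate, with boundary values counting as met (≥).

## Key parameters

| parameter | default | rationale |
| --- | --- | --- |
| IRLS tolerance | relative deviance change < 1e-8 | standard GLM stopping rule |
| IRLS iteration cap | 25 | logistic fits on registry-scale data converge in < 10 |
| candidate stratum counts | {5, 6, 7, 8, 9} | spans the range where subclassification removes ~90%+ of measured confounding while keeping strata populated |
| SMD imbalance threshold | 0.1 | the conventional balance cut-off |
| sparse-cell warning | any (country, stratum) cell < 30 | small cells make stratum proportions unstable; warn, never fail |
| separation guard | ‖β‖∞ > 50 during IRLS | flags (quasi-)separation; a 1e-8 ridge keeps coefficients finite and `converged_` is set False |
| weight floor | 1e-10 | prevents division blow-ups when fitted probabilities touch 0/1 |

**Stratum-count selection.** k is chosen to minimize the maximum absolute
after-stratification SMD. Exact ties never occur under sampling noise, so
"ties toward smaller k" is operationalized as: the smallest candidate whose
maximum |SMD| lies within 0.01 (absolute) of the minimum wins. In an
unconfounded scenario every k is equivalent and k=5 is returned; in strongly
confounded scenarios larger k wins only when it buys a real improvement.

**Reference levels.** Dummy coding drops the first declared level of each
covariate (2017, <40, ductal, well, <2cm, pN0, HER2-negative, ER-negative,
PR-negative). The choice is arbitrary but fixed and documented so that
coefficients are comparable across runs.

**All-zero design columns.** When a level occurs nowhere in the pooled
eligible population (e.g. pT unknown after the QI6a guard below), the
aggregator detects it from the aggregate XᵀWX diagonal at β=0, fixes the
coefficient at 0 and reports it in `dropped_columns_`; a pseudoinverse
backstop handles any other singularity with a collinearity warning.

## Quality-indicator rules

Numerators, denominators and exclusions follow the EUSOMA definitions:
QI6a operated patients, PST excluded, standard 10%; QI6b PST patients,
M1 excluded, standard 60% / target 90%; QI9a operated patients,
reconstruction and DCIS-only excluded, standard 80% / target 90%; QI9c
mastectomy patients, standard 40%; QI10a breast-conserving-therapy patients,
M1 excluded, standard 90% / target 95%.

Two interpretation decisions were genuinely open:

* **QI6a pTx guard.** Patients with unknown tumour size are additionally
  dropped before the QI6a propensity fit: they are rare in the eligible
  population and destabilize stratification. This is an analysis-level
  exclusion (`analysis_exclusion`), kept separate from the clinical
  exclusion (PST).
* **Single breast operation.** "Single operation" counts operations on the
  breast only (`n_breast_operations == 1`); axillary-only reoperations do
  not count against it.
* **MRI around PST.** The indicator accepts MRI at any time point relative
  to PST (one boolean flag), not a specific one.

## Synthetic registries

The generator emulates two national registries whose categorical covariate
margins follow the published composition of the Dutch and Norwegian
2017–2018 invasive breast cancer cohorts (stored as per-level counts;
probabilities are counts/N so each margin sums to one exactly). Treatment
and outcome flags are drawn from logistic assignment models in the
covariates, with country-specific intercepts where practice plausibly
differs (MRI uptake, reoperation rate, systemic-therapy uptake); the
intercepts and effects are package defaults chosen to land prevalences near
realistic registry rates, and they are written to a truth sidecar so that
estimators can be audited by parameter recovery.

What the generator deliberately does **not** emulate:

* **Joint covariate structure.** Covariates are sampled independently —
  only margins are publicly reported, not cross-tabulations. A real cohort
  has correlated stage/grade/receptor status. Balance and recovery results
  therefore validate the machinery, not the magnitude of real-world
  confounding. (A dependence hook can be added at the config level; the
  default is independence.)
* **Continuous age.** Age exists only as the six bands used by the
  analysis.
* Survival times, longitudinal events, hospital-level clustering.

"Unknown" is a first-class generated level for grade, pT, pN, HER2, ER and
PR — it is a real registry category, not missingness to impute. Structural
gates (immediate reconstruction ⇒ mastectomy; operation counts ≥ 1 iff
operated; MRI-around-PST only for PST patients; BCT = operated without
mastectomy) are applied after sampling, so gated flags follow their
logistic model only within the gated subpopulation.

The confounded test scenario shifts the comparison country toward older
age, worse grade and heavier nodal stage (a dozen levels with |SMD| > 0.1)
and adds a synthetic outcome whose risk rises with those covariates plus a
known country effect γ on the log-odds scale, so the stratified MH odds
ratio can be checked against exp(γ).

## Problem sizes

Unit and property tests run at 1,500–9,000 patients per country: large
enough for stable fits, small enough for a fast suite. The stochastic
properties (balance reduction, effect recovery) use 20 seeds at 2,500–3,000
patients per country; the reproduction script runs the full default
benchmark at the complete cohort sizes (32,786 + 6,377).

## Known limitations

* **Quasi-separation in small subcohorts.** When a covariate level is held
  by only one country within a small QI-eligible population (e.g. a rare
  HER2-unknown level inside a few-hundred-patient PST cohort), the logistic
  MLE is unstable and federated and pooled routes — both correct — can stop
  at visibly different coefficients. The convergence flag and the
  `validate` discrepancy table surface this; at full registry sizes it does
  not occur.
* **Non-collapsibility.** The MH odds ratio across propensity strata
  estimates a partially marginalized odds ratio; with strong covariate
  effects on the outcome it is mildly attenuated relative to the
  conditional odds ratio even under perfect balance. Recovery tests use
  moderate effect sizes where the attenuation is well inside Monte-Carlo
  noise.
* **Harmonization.** Receptor-positivity cutoffs differ between registries
  (ER ≥10% vs >1%); the schema stores each registry's own call and no
  re-harmonization is attempted, mirroring how the registries themselves
  report.
* The between-stratum CI for the stratum-averaged proportion is a normal
  approximation on k points; with k = 5 it is wide and should be read as
  indicative.
* The federation is in-process. The node interface is the seam where a real
  transport layer would attach; encryption, authentication and deployment
  are out of scope.
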