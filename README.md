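# scalesel

Spatial-scale selection for area-level covariates in regression models of
pediatric BMI z-scores.

## The problem

Neighborhood variables — population density, median household income,
crime indices, park density — are usually available at several nested
census geographies: the census block (CBK), block group (CBG), and tract
(CT). Conventional practice forces every area-level covariate into a
regression at one common scale, yet different covariates plausibly act at
different scales. `scalesel` treats the choice of scale as part of model
selection: each *concept* (one substantive covariate, e.g. median household
income) is represented by one candidate column per scale, and a
variable-selection path algorithm is constrained so that at most one scale
per concept is ever active.

Four constrained path algorithms are provided, all operating on a fully
standardized design and outcome with no intercept:

* **SS forward stepwise** — greedy OLS selection; a candidate is accepted
  when it lowers AIC by at least ε (default ε = 1).
* **SS incremental forward stagewise** — repeated coefficient increments of
  δ = 0.001 toward the eligible column most correlated with the residual,
  stopping when no eligible |correlation| exceeds 0.01.
* **SS LARS** — least angle regression: the active set grows at
  correlation ties and coefficients move along the equiangular direction,
  with sibling scales of active concepts excluded from entry.
* **SS lasso** — LARS with the drop modification, tracing the L1-penalized
  solution path; a dropped concept's sibling scales regain eligibility.

For LARS/lasso paths the reported model is the knot with minimum OLS-based
AIC, `AIC = n·ln(RSS/n) + 2(k+1)`. The selected covariate sets are then
refit by OLS for approximate p-values, compared against all-CBG and all-CT
constrained refits, extended with random intercepts at the CBG and/or CT
(ML estimation, nested when both), and augmented with nine
clinician-specified interaction terms built on Gelman-rescaled predictors
(binary covariates centered, continuous covariates divided by two standard
deviations).

Because the underlying patient records are not public, the package ships a
synthetic-data generator that reproduces the data's structure — visits
nested in CBKs within CBGs within CTs, area covariates correlated ρ across
scales, known effect scales, group-level random intercepts, and rows that
trip each exclusion rule — so every stage is testable end to end.

## Worked example

Write a config and run the exclusion filter and one selection:

```yaml
# config.yaml
seed: 42
output_dir: scratch/readme_run
scenario:
  n_ct: 40
  cbgs_per_ct: 3
  cbks_per_cbg: 2
  n_total: 6000
  rho: 0.7
  sigma_cbg: 0.15
  sigma_eps: 0.9
  n_underweight: 300
  n_race_excluded: 90
  n_missing: 2
  effects:
    VisitAge: [individual, 0.08]
    Black: [individual, 0.04]
    POPDENS: [CT, -0.10]
    MEDHINC: [CT, -0.15]
    PHWHITE: [CBG, 0.10]
    EX_EQ: [CBG, -0.12]
```

```text
$ scalesel filter -c config.yaml
observations in:        6000
excluded underweight:   300
excluded race:          90
excluded missing:       2
retained for analysis:  5608

$ scalesel select -c config.yaml -a lasso
lasso: 11 terms, AIC -652.2
  VisitAge, Black, POPDENS_CT, PBLACK_CT, PHWHITE_CBG, PHBLACK_CT,
  MEDHINC_CT, PRENTER_CBG, CRMCYPERC_CBG, CRMCYPROC_CT, EX_EQ_CBG
```

The filter report shows the sequential exclusion accounting (each row is
counted once, at the first rule it trips). The selection output lists the
active columns of the minimum-AIC knot: every true effect is recovered at
its true scale (`POPDENS_CT`, `MEDHINC_CT`, `PHWHITE_CBG`, `EX_EQ_CBG`),
along with a handful of small noise terms, and no concept appears at two
scales. `scalesel run-all -c config.yaml` runs the full workflow — paths,
selected-model reports, single-scale AIC comparisons, random-effect AIC
tables, group-intercept predictions, and interaction models — writing one
CSV per report plus a manifest with the seed and config hash.

The same functionality is available as a library:

```python
from scalesel import (SyntheticScenario, simulate_study, scenario_design,
                      standardize_full, ss_lasso, final_model)

sc = SyntheticScenario(seed=42)
geo, tables, cohort, raw, truth = simulate_study(sc)
design = scenario_design(sc, cohort, tables)
X, y, recipe = standardize_full(design, cohort["BMIZ"].to_numpy())
model = final_model(ss_lasso(X, y), X, y)
```

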