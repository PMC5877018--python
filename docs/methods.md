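# Methods

## Data model

The unit of analysis is a patient visit. Each visit carries a BMI z-score
outcome (`BMIZ`), four individual covariates (visit age in years, male and
black indicators, distance to the medical center in miles), and the
identifiers of the census block (CBK), block group (CBG), and tract (CT) of
residence. Geography nesting is declared by explicit mapping tables
(CBK→CBG, CBG→CT) and validated row by row; it is never inferred from
identifier structure, so synthetic identifiers behave exactly like FIPS
codes.

A *concept* is one substantive covariate; an area-level concept contributes
one design column per scale at which it is observed. The study's candidate
pool has 4 individual covariates, population density at three scales, and
twelve further area concepts at CBG and CT — 31 columns over 17 concepts.
Columns carry `(concept, scale, variable_number)` metadata; the variable
number orders deterministic tie-breaking everywhere.

Two standardization schemes are used, both with sample SD on the n−1
denominator:

* **Full standardization** (selection and main-effects inference): every
  predictor and the outcome to mean 0, SD 1, which removes the intercept
  from all path algorithms.
* **Gelman rescaling** (interaction models): binary predictors centered
  only; continuous predictors centered and divided by 2·SD; outcome left
  raw, so these models carry an explicit intercept. Coefficients of binary
  and continuous terms are then on a comparable low-to-high contrast scale.

Each recipe records centers and divisors and can invert itself; area
covariates are standardized within the analysis sample (the alternative —
standardizing over the full geography — is not implemented, and the recipe
makes the choice auditable).

Filtering is complete-case with sequential exclusion rules — clinically
underweight (BMIZ below the standard-normal 5th percentile, z < −1.6449,
strict inequality; configurable), race outside the black/white study
population (unknown codes excluded here), then missingness in any modeled
column. A row is attributed to the first rule it trips, so the per-rule
counts always sum to the input count. Whether the rules overlapped in the
original records is unknowable; the sequential attribution is a declared
reporting convention, not a claim about the source data.

## Constrained selection paths

All four algorithms enforce one invariant: at every step, at most one scale
per concept is active. Eligibility is recomputed each step: a column is
eligible if it is neither active nor excluded and its concept has no active
sibling. Siblings are frozen out at entry (stepwise, LARS, lasso) or at a
column's first increment (stagewise); when the lasso drops a column, its
concept's siblings regain eligibility — the invariant is preserved without
permanently barring a concept. Sibling scales compete simultaneously for
entry (no pre-screening); ties in correlation or AIC are broken by the
smallest variable number, making every path deterministic.

* **Stepwise**: each eligible candidate is tried by OLS on
  {active ∪ candidate}; the minimum-AIC candidate is accepted iff it lowers
  the *current model's* AIC by at least ε (default 1; AIC differences of
  4–7 are conventionally "substantial", so ε = 1 is permissive). The model
  is the last accepted step.
* **Stagewise**: at each iteration the coefficient of the eligible column
  with the largest |Pearson correlation| with the current residual moves by
  δ·sign (δ = 0.001); iteration stops when that maximum falls below the
  tolerance 0.01. Increments are computed with Gram-matrix updates (O(p)
  per step); the stored path keeps all first-entry events plus every 100th
  increment, which bounds memory without losing entry order. The model is
  the nonzero set at termination — the min-AIC scan applies only to
  LARS/lasso paths. A `max_steps` cap (default 200,000) returns a
  truncation-flagged path rather than failing.
* **LARS**: standard least-angle knots (enter at the correlation tie, move
  along the equiangular direction of the sign-adjusted active set), with
  entry restricted to eligible columns. On single-scale designs this
  reproduces the unconstrained textbook path to machine precision (verified
  knot-by-knot against an independent implementation).
* **Lasso**: LARS with the drop modification — when an active coefficient's
  path crosses zero it is dropped at that knot and the direction is
  recomputed. At every knot the active columns share a common absolute
  residual correlation, and no eligible inactive column exceeds it (the
  L1-penalized optimality conditions, checked in the tests).

AIC along paths and in OLS refits is `n·ln(RSS/n) + 2(k+1)` with k active
coefficients and the error variance counted as one parameter. A zero RSS
yields −∞ with a warning rather than an error. This omits the Gaussian
constant `n(1+ln 2π)`, which cancels in any OLS-vs-OLS comparison; where an
OLS fit is compared against mixed-model AICs the constant is added back
(`FittedModel.aic_full`) so both sit on the full-likelihood scale.

## Inference and comparisons

Selected sets are refit by OLS (no intercept on standardized data; residual
df = n − k) for coefficients, t-based two-sided p-values, and significance
marks (`*` p<0.05, `+` p<0.1). These are approximate p-values: no
post-selection correction is applied, deliberately. Single-scale comparison
models swap every selected area term to its all-CBG or all-CT sibling and
refit; percent change between two effect estimates is
`100·(|b|−|a|)/|a|`, rounded to the nearest integer for reporting.

Random-intercept models at CBG, CT, or both (CBG strictly nested within CT;
crossed effects are not offered because geography is strictly nested) are
estimated by maximum likelihood — not REML — so AIC is comparable across
fixed-effect sets. Estimation is delegated to statsmodels' `MixedLM`;
fixed-effect p-values are Wald tests, the conventional companion of ML
estimation. The mixed AIC is `−2·loglik + 2·(#fixed + #variance components
+ 1)`. Group-intercept predictions (EBLUPs) are returned per unit; at a
zero-variance boundary they shrink exactly to zero. The likelihood is
maximized with l-bfgs first; because that optimizer occasionally collapses
onto a degenerate boundary or stops short, bfgs and Powell are tried in
turn and the best finite converged fit is kept — in practice this makes the
AIC tables reproducible at well below the ±0.5 level.

Interaction models force in the male indicator when not selected, build the
nine clinician-specified products (male and black each crossed with
population density, income, park density, and exercise equipment; distance
crossed with income) on Gelman-rescaled parents, and skip any pair whose
base concept was not selected — the product columns themselves are not
re-centered, so removing one never perturbs a parent column. Pruning keeps
interactions with p < 0.05 in a single pass (no iteration); main effects
are never pruned. Final models are refit with and without random effects
and tabulated by AIC.

## Synthetic data generator

The generator emulates the study's structure, not its geography: a balanced
nesting (configurable counts of CTs, CBGs per CT, CBKs per CBG), visits
allocated to CBKs uniformly at random, and for each area concept a
top-down draw — tract values standard normal, each child unit
`ρ·parent + √(1−ρ²)·noise` — so every scale is marginally N(0,1) and the
child–parent correlation is ρ (default 0.7). The outcome is a linear
combination of empirically standardized true-scale columns plus Gaussian
random intercepts per CBG and CT and residual noise. Defaults mirror the
study conditions: 29,471 visits; exclusion counts 1,482 / 449 / 2
(filtering to 27,538); small standardized effects (0.01–0.08) at the scales
the analysis reported; residual SD 0.95 so the outcome variance is near 1.
All randomness flows through one seeded PCG64 generator, so scenarios are
bit-reproducible across platforms.

The raw (pre-filter) table is constructed so each exclusion rule trips an
exact count: the configured number of rows is pushed below the underweight
cutoff (naturally low z-scores first), any other below-cutoff row is
reflected just above it, and race/missingness markers are placed on
disjoint rows. The raw table is therefore an input for the exclusion
workflow; the untouched clean cohort remains the modeling truth.

What the generator does **not** emulate: spatial adjacency or
autocorrelation between neighboring units, realistic census marginals,
unbalanced or skewed covariate distributions, repeated visits by the same
child, and measurement error in the outcome. Passing tests demonstrate the
algorithms' operating characteristics under clean hierarchical Gaussian
conditions, not performance on real clinical records.

## Simulation study sizes

The replicated experiments (in `scalesel.evaluation`, rerun by
`scripts/acceptance.py`) use: scale recovery — 50 replicates at n = 5,000,
ρ = 0.7, standardized effects of 0.1–0.2 at mixed scales over the full
31-column pool; AIC ordering — 20 seeds at n = 4,000 on the same effect
structure; constraint invariant — 50 small scenarios (n = 250) including a
three-scale concept; random-effect placement — 20 seeds at n = 2,000 with
σ_CBG = 0.35 and σ_CT = 0; variance recovery — 50 replicates of 200 groups
× 20 with σ²_CBG = 0.25, fit on the raw outcome (variance components live
on the outcome scale, so recovery is not judged on the standardized
outcome). These sizes give stable rates while keeping a full run to a few
minutes on one CPU.

## Known limitations

* Inference after selection is naive; selected-term p-values are
  optimistic.
* The stagewise tolerance (0.01) is an absolute correlation threshold; at
  small n it sits below the sampling noise of a null correlation, so
  stagewise models keep more small noise terms than the other algorithms.
* Cross-validated penalty selection, forced-in confounders inside the path
  algorithms, random-effect selection, and spatially correlated random
  effects are out of scope.
* `compare_re_specs` refits the nested model from scratch per
  specification; no warm starts.
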