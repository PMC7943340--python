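# Methods

`multiadhere` implements the outcome construction and statistical analysis of a
two-arm randomized controlled trial of a multibehavior adherence intervention in
type 2 diabetes, together with a synthetic cohort generator that reproduces the
statistical structure such a trial assumes. This note records the models, the
defaults and why they were chosen, and what the synthetic data do and do not
establish.

## The composite outcome model

Four treatment behaviors are scored per participant and wave:

| behavior | instrument | score | units / range |
|---|---|---|---|
| physical activity | SQUASH-style activity diary | Σ days/week × min/day over activities with MET ≥ 3 | min/week |
| unhealthy snacking | snack FFQ | Σ portions/week × kcal/portion | kcal/week |
| oral-medication adherence | 18 binary items | sum of adherent items | 0–18 |
| insulin adherence | 9-item adaptation | sum of adherent items | 0–9 |

For each behavior `b`, the change score is Δ_b = follow-up − baseline, with the
snack change sign-reversed so that larger always means improvement. Each Δ_b is
divided by the pooled SD of that behavior's change scores across the two arms
(classical two-sample pooled estimator with (n−1) denominators), giving z_b. The
composite is C = Σ z_b over the participant's *applicable* behaviors (insulin
items exist only for insulin users, etc.), without rescaling by the number of
terms; an optional mean-rescaling variant exists but is off by default because
the primary outcome is defined as the plain sum. Finally D = C / pooledSD(C).
By construction the pooled SD of D is 1, so the between-arm difference in mean
D is a Cohen *d*, and the intervention coefficient of any linear model for D is
on the effect-size scale.

Assumptions worth stating: the composite weights behaviors equally on the
standardized-change scale (no clinical weighting); participants with fewer
applicable behaviors have intrinsically smaller-variance composites, which the
plain sum does not correct; standardization constants are estimated on the
complete-pairs sample and then **frozen** — multiply imputed or
scenario-imputed datasets are evaluated against the same constants, keeping the
scale of D fixed across analyses.

## Effect estimation

Patients are nested in recruiting nurses. Effects are estimated with a linear
mixed model (REML) carrying a random intercept per nurse:
`D ~ intervention (+ covariates)`. Denominator df use a between-within
approximation (observations − clusters − within-cluster fixed effects); the
underlying fitter offers no Satterthwaite approximation, and at this design's
cluster counts (~30–60 nurses, df in the hundreds) the two are practically
identical. The df method is recorded on every estimate. A singular fit (nurse
variance estimated at zero) falls back to single-level OLS with a warning and
`df_method="ols-residual"`.

The adjusted model codes categorical covariates against fixed reference levels
(control arm, diabetes nurse, combined medication, current depression, female,
disabled/incapacitated work status, living alone, high education, above-average
income) so that coefficient signs are stable across runs.

Attrition is analyzed by logistic regression of the retention flag on baseline
predictors (Wald CIs); a closed-form 2×2 odds ratio (`crude_or`) serves as its
analytic twin. Separation is raised as an estimation failure rather than
reported.

## Missing data

Two deliberately distinct paths:

* **Chained-equation MI (intention to treat).** Predictive-mean-matching MICE
  over one numeric row per participant: arm, coded covariates, a nurse-level
  baseline summary, baseline scores and (partially missing) follow-up scores.
  Outcomes are rebuilt per completed dataset against the frozen constants, the
  mixed model is fitted on each, and estimates are pooled with Rubin's rules
  using Barnard–Rubin df. Default m = 20 (configurable; the analysis plan the
  package follows does not fix m, and 20 is a standard modern default).
  Structurally missing scores — instruments not applicable given medication
  type — are not imputation targets: they are frozen at the observed mean
  during the sweeps (as neutral predictor values) and re-masked afterwards.
  Observed values are never altered.
* **Scenario imputation (sensitivity).** Operates directly on D. For arm *g*
  with observed mean m_g and SD s_g, each missing D is drawn from
  Normal(m_g ± shift_g·s_g, s_g): sign + for the optimistic scenarios, − for
  the pessimistic; shift 1.0 in both arms in the *equal* variant, and 1.0
  (intervention) / 1.5 (control) in the *unequal* variant. The draw SD equals
  the arm's observed SD of D — the most literal reading of "assuming a normal
  distribution of the outcome"; it is exposed through the spec object. The
  four scenarios plus the complete-case estimate form the sensitivity suite.

## Design calculations

`required_n` uses the normal-approximation two-sample formula inflated by the
cluster design effect 1+(m−1)ρ, then converts to a baseline inclusion target by
dividing by the expected retention. With d = 0.4, α = 0.05 two-sided, power
0.80, ρ = 0.02 and m = 8 this gives 112 per group (the protocol's stated 116
cannot be reproduced exactly without knowing the assumed cluster size; the
`n_group` override reproduces the 116 → 464 baseline-target arithmetic).

`simulate_power` checks a design point empirically: whole trials are generated
by the cohort module and pushed through the full pipeline and the unadjusted
mixed model. Note that with *individual* randomization stratified within
nurses, the random intercept largely cancels from the treatment contrast, so
the simulated power at the design point (~0.86) exceeds the design-effect
formula's implied 0.80 — the formula is conservative for this randomization
scheme.

## The synthetic cohort generator

The generator emulates: Table-style baseline moments for the four behaviors,
medication-type applicability shares (61.5% oral-only / 6.7% insulin-only /
31.8% both), individual randomization within nurses (~8 patients per nurse,
both arms present in every nurse), a between-nurse ICC of 0.02 on the composite
change, covariate marginals (age, sex, education, income with ~23% missing,
work, BMI, HbA1c, depression), and differential dropout (53% intervention,
27.5% control), optionally covariate-dependent through a logistic retention
model with per-arm coefficients and intercepts solved to keep the marginal
rates on target.

Mechanics per behavior: latent baseline and follow-up standard normals with
test-retest correlation c_b (defaults 0.40 PA, 0.60 snacks, 0.55 adherence
scales — chosen as plausible 6-month stabilities of self-reported behavior;
published follow-up SDs are consistent with this order) are mapped through
moment-matched marginals — gamma for PA minutes and snack kcal (their published
SDs exceed their means, so a truncated normal cannot match both moments; the
gamma matches them exactly on a non-negative support) and beta-binomial on the
0–18 / 0–9 integer ranges for the adherence sums. The treatment effect is a
location shift of the follow-up marginal (sign-flipped for snacks), calibrated
by a deterministic internal quadrature so the shift equals the requested effect
in pooled-change-SD units. Because the shift moves the whole bounded marginal,
no clipping occurs and standardized effects are recovered without ceiling
attenuation (clipping schemes tested during development attenuated the
composite effect by >10%).

The nurse intercept loads on each behavior's latent follow-up innovation with a
per-participant weight solved so the nurse share of the latent composite-change
variance equals the ICC regardless of how many behaviors apply. Item-level
responses are emitted backwards from the scores (k randomly chosen adherent
items for a sum of k; activity minutes split over random qualifying activities,
occasionally adding a sub-threshold activity to exercise the exclusion rule);
re-scoring the items reproduces the scores exactly, which is what licenses the
score-level fast path (`items=False`) used in simulation studies.

One pseudo-random stream per logical stage (structure, latent scores, item
encoding, dropout, scenarios), each derived from the master seed; generation is
bit-reproducible under a fixed seed.

**What the generator does not emulate:** behavioral trajectories or seasonal
activity patterns; item-response (psychometric) structure of the adherence
scales; joint covariate dependence (covariates are independent, as only
marginals are published); any direct dependence of dropout on unobserved
change (dropout is MCAR or covariate-MAR by construction). A green test
therefore establishes the *statistical machinery* — standardization,
composition, clustering, imputation, pooling, operating characteristics — not
behavioral realism.

## Numerical choices

* Effect calibration: fixed-point `δ = d·sd_Δ(δ)`, three iterations over a
  200 000-draw deterministic quadrature with a fixed internal stream
  (independent of the user seed); residual bias ≈ 0.2%.
* MET threshold comparison is inclusive (≥ 3.0), so an exactly-3-MET activity
  qualifies.
* Adherence-scale missing items: ≤ 2 of 18 (≤ 1 of 9) missing are scored as
  non-adherent and flagged; more yield a missing score. Conservative and
  testable; the instruments' sources are silent on the rule.
* Pooled SDs require ≥ 2 observed changes per arm and are strictly positive;
  degenerate variance raises a `StandardizationError` naming the behavior.
* Mixed-model singular fits fall back to OLS (see above); p-values are
  two-sided t throughout; no multiplicity adjustment across the four
  secondary outcomes (matching the source analysis; a Holm flag would be a
  one-line extension).
* JSON artifacts keep full float precision; the markdown report rounds to 2–3
  decimals.

## Known limitations

* Between-within df are mildly conservative relative to Satterthwaite in
  small-cluster designs.
* MICE uses the numpy legacy global RNG internally; the package scopes and
  restores the global state around each run, but concurrent imputations in one
  process would interleave draws.
* The MI model imputes behavior scores linearly (PMM keeps draws among
  observed values, hence in-range), not through the item layer.
* The default MET and kcal tables are documented stand-ins: analyses of real
  data must supply locally validated tables (both are plain YAML/JSON).
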