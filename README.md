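# multiadhere

Analysis toolkit for **multibehavior treatment-adherence trials** — randomized
controlled trials in type 2 diabetes (or similar chronic-care settings) whose
primary outcome is a *composite standardized change score* across several
treatment behaviors: physical activity, diet, and adherence to oral medication
and insulin therapy. It is written for trial statisticians and methods
researchers who need the full chain from item-level questionnaire responses to
pooled effect estimates, and a synthetic cohort generator to exercise that
chain without access to participant data.

## The outcome model

Each behavior *b* is scored per participant and wave (SQUASH MET-minutes/week,
FFQ snack kcal/week, 0–18 and 0–9 adherence sums). With Δ_b the follow-up
minus baseline change (snack reversed so larger = better):

```
z_b = Δ_b / s_pooled(Δ_b)          pooled over both arms, (n−1) denominators
C   = Σ_b z_b                      over the participant's applicable behaviors
D   = C / s_pooled(C)
```

D has pooled SD 1 by construction, so the between-arm difference in mean D —
and the intervention coefficient of the nurse-nested linear mixed model
`D ~ arm (+ covariates) + (1 | nurse)` — is a Cohen *d*. Around this core the
package provides intention-to-treat multiple imputation with Rubin's-rules
pooling, four optimistic/pessimistic scenario imputations of the primary
outcome, per-protocol analyses, attrition logistic regression, and
cluster-adjusted sample-size / simulated-power calculations.

## Worked example

Simulate a 480-participant trial (60 nurses × 8 patients, ICC 0.02, a true
standardized effect of 0.22 on each behavior's change score, dropout 53% vs
27.5%), then run the full analysis:

```sh
cat > cohort.yaml <<EOF
n_nurses: 60
patients_per_nurse: 8
icc: 0.02
true_effects: {pa: 0.22, snack: 0.22, oha: 0.22, insulin: 0.22}
dropout_rate_by_arm: [0.530, 0.275]
EOF

multiadhere simulate --config cohort.yaml --seed 7 --out data
multiadhere analyze  --data data --seed 7 --m 5 --out results
```

`results/effects.json` (rendered in `results/report.md`) then contains, for
this seed:

```
unadjusted:   d=0.44 (95% CI 0.160 to 0.713), p=0.004    # ITT, MI-pooled
adjusted:     d=0.42 (95% CI 0.146 to 0.698), p=0.005
per-protocol: d=0.48 (95% CI 0.244 to 0.718), p=8.2e-05  # completers only
scenario:optimistic-equal    d=0.73
scenario:optimistic-unequal  d=0.65
scenario:pessimistic-equal   d=0.22
scenario:pessimistic-unequal d=0.41
attrition (arm-only), OR control vs intervention: 3.23
```

Reading it: four per-behavior effects of 0.22 compose to a true Cohen *d* of
≈0.40 on the composite (the z_b are nearly independent, so the sum scales by
≈√k̄); the ITT estimate recovers it, the completers-only estimate sits close
by, and the scenario imputations bracket it from the optimistic side (dropouts
assumed to improve by +1 SD) and the pessimistic side (−1 SD; the unequal
variants move the control arm by 1.5 SD). The attrition odds ratio reflects
the differential dropout built into the simulation.

Design calculations:

```sh
$ multiadhere power --n-group 116
design effect: 1.140
follow-up requirement per group: 116
baseline inclusion target: 464
```

Everything is also available as a library — `generate_cohort`,
`score_items_frame`, `build_outcomes`, `fit_mixed`, `mi_estimate`,
`run_sensitivity_suite`, `required_n`, `simulate_power` — see the docstrings
and `docs/methods.md` for the statistical detail.

## Acceptance script

`scripts/acceptance.py` recomputes, from scratch, the operating
characteristics of the trial design by Monte-Carlo simulation of whole trials
through the generator, the composite pipeline and the mixed model: the
simulated power at the design point (116 per group at follow-up, true
composite effect 0.4, ICC 0.02, clusters of 8, two-sided α = 0.05) and the
empirical type-I error rate of the same test under a null effect. Run it as

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

(~10 minutes on one CPU; the seed drives every random stream).
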