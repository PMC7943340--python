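"""Multiple imputation, Rubin pooling and scenario sensitivity analyses."""

import numpy as np
import pandas as pd
import pytest

from multiadhere.cohort import (
    CohortParams,
    TrialDataset,
    _calibrate,
    apply_dropout,
    generate_cohort,
)
from multiadhere.errors import ParameterError, StandardizationError
from multiadhere.missing import (
    ScenarioSpec,
    completed_scores_frame,
    default_scenarios,
    impute_chained,
    mi_estimate,
    pool_rubin,
    run_sensitivity_suite,
    scenario_impute,
)
from multiadhere.models import EffectEstimate
from multiadhere.outcomes import build_outcomes
from tests.conftest import fill_covariates

_TAG_SCENARIO = 21  # mirror of the module-internal stream tag


def _est(d, se, df=200.0):
    return EffectEstimate(
        d=d, ci_low=d - 2 * se, ci_high=d + 2 * se,
        t=d / se if se else 0.0, df=df, p=0.5, se=se,
    )


def _outcome_table(rng, n=60, missing_int=0, missing_ctrl=0, shift=0.0):
    arm = np.array(["intervention", "control"] * (n // 2))
    d = rng.normal(0, 1, n) + shift * (arm == "intervention")
    nurse = np.array([f"n{i % 6}" for i in range(n)])
    t = pd.DataFrame({
        "participant_id": [f"p{i}" for i in range(n)],
        "arm": arm, "nurse_id": nurse, "D": d,
    })
    for arm_name, k in (("intervention", missing_int), ("control", missing_ctrl)):
        idx = t.index[t["arm"] == arm_name][:k]
        t.loc[idx, "D"] = np.nan
    return t


class TestScenarioSpec:
    def test_variants_differ_only_in_control_shift(self):
        equal = ScenarioSpec("optimistic", "equal")
        unequal = ScenarioSpec("optimistic", "unequal")
        assert equal.shift_int == unequal.shift_int == 1.0
        assert equal.shift_ctrl == 1.0 and unequal.shift_ctrl == 1.5

    def test_sign_follows_direction(self):
        assert ScenarioSpec("optimistic", "equal").sign == 1.0
        assert ScenarioSpec("pessimistic", "equal").sign == -1.0

    def test_default_set_covers_the_four_scenarios(self):
        tags = {s.tag for s in default_scenarios()}
        assert tags == {
            "scenario:optimistic-equal", "scenario:optimistic-unequal",
            "scenario:pessimistic-equal", "scenario:pessimistic-unequal",
        }

    def test_invalid_direction_rejected(self):
        with pytest.raises(ParameterError):
            ScenarioSpec("hopeful", "equal")


class TestScenarioImpute:
    def test_observed_values_never_modified(self):
        rng = np.random.default_rng(60)
        t = _outcome_table(rng, missing_int=8, missing_ctrl=4)
        out = scenario_impute(t, ScenarioSpec("pessimistic", "unequal"), seed=3)
        obs = t["D"].notna()
        assert (out.loc[obs, "D"] == t.loc[obs, "D"]).all()
        assert out["D"].notna().all()

    def test_worked_oracle_with_same_stream(self):
        """Imputed values equal an independently coded draw from the
        specified normals using the same derived RNG stream."""
        rng = np.random.default_rng(61)
        t = _outcome_table(rng, n=10, missing_int=2, missing_ctrl=2)
        spec = ScenarioSpec("optimistic", "unequal")
        out = scenario_impute(t, spec, seed=9)

        oracle_rng = np.random.default_rng(
            np.random.SeedSequence([9, _TAG_SCENARIO, 0, 1])
        )
        expect = t.copy()
        for arm, shift in (("intervention", 1.0), ("control", 1.5)):
            obs = t.loc[(t["arm"] == arm), "D"].dropna()
            miss = (t["arm"] == arm) & t["D"].isna()
            mu = obs.mean() + shift * obs.std(ddof=1)
            expect.loc[miss, "D"] = oracle_rng.normal(
                mu, obs.std(ddof=1), size=int(miss.sum())
            )
        np.testing.assert_array_equal(out["D"].to_numpy(), expect["D"].to_numpy())

    def test_zero_shift_centers_on_arm_means(self):
        rng = np.random.default_rng(62)
        t = _outcome_table(rng, n=4000, missing_int=1200, missing_ctrl=1200)
        spec = ScenarioSpec("optimistic", "equal", shift_int=0.0, shift_ctrl=0.0)
        out = scenario_impute(t, spec, seed=5)
        for arm in ("intervention", "control"):
            obs = t.loc[t["arm"] == arm, "D"].dropna()
            imp = out.loc[(t["arm"] == arm) & t["D"].isna(), "D"]
            se = obs.std(ddof=1) / np.sqrt(len(imp))
            assert abs(imp.mean() - obs.mean()) < 3.5 * se

    def test_seed_reproducibility_and_distributional_stability(self):
        rng = np.random.default_rng(63)
        t = _outcome_table(rng, n=20000, missing_int=5000, missing_ctrl=5000)
        spec = ScenarioSpec("pessimistic", "equal")
        a = scenario_impute(t, spec, seed=1)
        b = scenario_impute(t, spec, seed=1)
        pd.testing.assert_frame_equal(a, b)
        c = scenario_impute(t, spec, seed=2)
        miss = t["D"].isna()
        assert not np.array_equal(a.loc[miss, "D"], c.loc[miss, "D"])
        from scipy import stats

        ks = stats.ks_2samp(a.loc[miss, "D"], c.loc[miss, "D"])
        assert ks.pvalue > 0.01

    def test_insufficient_observed_arm_rejected(self):
        rng = np.random.default_rng(64)
        t = _outcome_table(rng, n=10, missing_int=4)  # one observed in arm
        t.loc[t["arm"] == "intervention", "D"] = np.nan
        with pytest.raises(StandardizationError):
            scenario_impute(t, ScenarioSpec("optimistic", "equal"), seed=0)


class TestSensitivitySuite:
    def test_no_missing_data_reproduces_complete_case(self):
        rng = np.random.default_rng(65)
        t = _outcome_table(rng, n=80, shift=0.3)
        results = run_sensitivity_suite(t, seed=4)
        cc = results["complete-case"]
        for spec in default_scenarios():
            assert results[spec.tag].d == pytest.approx(cc.d, abs=1e-12)

    def test_scenario_ordering_under_differential_dropout(self):
        """Optimistic >= complete-case >= pessimistic when the
        intervention arm loses more participants."""
        params = CohortParams(
            n_nurses=180, patients_per_nurse=8, seed=66,
            dropout_rate_by_arm=(0.530, 0.275),
        )
        trial = apply_dropout(generate_cohort(params, items=False), params)
        css = build_outcomes(trial.analysis_frame())
        results = run_sensitivity_suite(css.table, seed=8)
        cc = results["complete-case"].d
        assert results["scenario:optimistic-equal"].d > cc
        assert results["scenario:optimistic-unequal"].d > results["scenario:pessimistic-unequal"].d
        assert results["scenario:pessimistic-equal"].d < cc

    def test_incomplete_scenario_set_rejected(self):
        rng = np.random.default_rng(67)
        t = _outcome_table(rng, n=40)
        with pytest.raises(ParameterError):
            run_sensitivity_suite(t, seed=0, specs=[ScenarioSpec("optimistic", "equal")])


class TestPoolRubin:
    def test_identical_estimates_pass_through(self):
        pooled = pool_rubin([_est(0.3, 0.1), _est(0.3, 0.1), _est(0.3, 0.1)])
        assert pooled.d == pytest.approx(0.3)
        assert pooled.se == pytest.approx(0.1)

    def test_worked_two_dataset_example(self):
        # points 0.2 and 0.4 with SE 0.1 each:
        # pooled 0.3; total variance 0.01 + 1.5 * 0.02 = 0.04
        pooled = pool_rubin([_est(0.2, 0.1), _est(0.4, 0.1)])
        assert pooled.d == pytest.approx(0.3)
        assert pooled.se == pytest.approx(np.sqrt(0.04))
        assert pooled.df_method == "barnard-rubin"

    def test_pooled_ci_not_narrower_than_within(self):
        ests = [_est(0.2, 0.1), _est(0.5, 0.1), _est(0.3, 0.1)]
        pooled = pool_rubin(ests)
        narrowest = min(e.ci_high - e.ci_low for e in ests)
        assert pooled.ci_high - pooled.ci_low >= narrowest

    def test_needs_two_estimates(self):
        with pytest.raises(ParameterError):
            pool_rubin([_est(0.2, 0.1)])

    def test_zero_within_variance_rejected(self):
        with pytest.raises(StandardizationError):
            pool_rubin([_est(0.2, 0.0), _est(0.4, 0.0)])


class TestImputeChained:
    @pytest.fixture(scope="class")
    def dropped_trial(self):
        params = CohortParams(
            n_nurses=30, patients_per_nurse=8, seed=70,
            dropout_rate_by_arm=(0.4, 0.25),
        )
        return fill_covariates(
            apply_dropout(generate_cohort(params, items=False), params)
        ), params

    def test_no_missing_values_returns_input(self):
        params = CohortParams(
            n_nurses=12, patients_per_nurse=8, seed=71,
            dropout_rate_by_arm=(0.0, 0.0),
        )
        trial = fill_covariates(generate_cohort(params, items=False))
        completed = impute_chained(trial, m=3, seed=1)
        merged = trial.analysis_frame()
        base = merged[merged["wave"] == "baseline"].set_index("participant_id")
        for snap in completed:
            scores = completed_scores_frame(snap)
            b = scores[scores["wave"] == "baseline"].set_index("participant_id")
            np.testing.assert_allclose(
                b.loc[base.index, "pa_min"], base["pa_min"], rtol=1e-12
            )

    def test_observed_values_bitwise_untouched(self, dropped_trial):
        trial, _ = dropped_trial
        completed = impute_chained(trial, m=2, seed=2, n_between=2)
        frame = trial.analysis_frame()
        fup = frame[frame["wave"] == "followup"].set_index("participant_id")
        snap_scores = completed_scores_frame(completed[0])
        snap_fup = snap_scores[snap_scores["wave"] == "followup"].set_index(
            "participant_id"
        )
        observed = fup["pa_min"].dropna()
        np.testing.assert_array_equal(
            snap_fup.loc[observed.index, "pa_min"].to_numpy(), observed.to_numpy()
        )

    def test_structurally_missing_scores_stay_missing(self, dropped_trial):
        trial, _ = dropped_trial
        completed = impute_chained(trial, m=2, seed=3, n_between=2)
        meta = trial.meta(covariates=True).set_index("participant_id")
        insulin_free = meta.index[meta["medication_type"] == "oha-only"]
        for snap in completed:
            assert snap.loc[insulin_free, "base_insulin"].isna().all()
            assert snap.loc[insulin_free, "fup_insulin"].isna().all()

    def test_fully_missing_column_rejected(self, dropped_trial):
        trial, _ = dropped_trial
        broken = TrialDataset(
            trial.participants,
            trial.scores.assign(
                pa_min=np.where(
                    trial.scores["wave"] == "followup", np.nan, trial.scores["pa_min"]
                )
            ),
            None,
        )
        # every follow-up PA value missing -> nothing to match on
        with pytest.raises(ParameterError, match="100%"):
            broken_all = TrialDataset(
                broken.participants,
                broken.scores.assign(pa_min=np.nan),
                None,
            )
            impute_chained(broken_all, m=2, seed=0)

    def test_m_floor(self, dropped_trial):
        trial, _ = dropped_trial
        with pytest.raises(ParameterError):
            impute_chained(trial, m=1, seed=0)


class TestMiInference:
    def test_mcar_null_is_unbiased(self):
        """Pooled MI estimate is unbiased under MCAR dropout and a null
        effect (desk-scale replication of the MCAR property)."""
        from tests.conftest import fast_mi_d, fill_covariates

        params = CohortParams(
            n_nurses=30, patients_per_nurse=8, icc=0.02, seed=0,
            dropout_rate_by_arm=(0.30, 0.30),
        )
        cal = _calibrate(params)
        pooled = []
        for rep in range(20):
            pr = params.replace(seed=500 + rep)
            trial = fill_covariates(
                apply_dropout(generate_cohort(pr, items=False, calibration=cal), pr)
            )
            pooled.append(fast_mi_d(trial, seed=500 + rep)[0])
        pooled = np.array(pooled)
        assert abs(pooled.mean()) < 3 * pooled.std(ddof=1) / np.sqrt(len(pooled))

    def test_mar_beats_complete_case_on_same_draws(self):
        """Dropout driven by the baseline adherence score in the
        intervention arm biases the complete-case contrast (regression to
        the mean among the selectively retained); chained imputation using
        the baseline scores removes most of that bias on the same draws."""
        from tests.conftest import fast_mi_d, fill_covariates

        params = CohortParams(
            n_nurses=32, patients_per_nurse=8, icc=0.02, seed=0,
            dropout_rate_by_arm=(0.50, 0.25),
            dropout_mechanism="covariate",
            dropout_betas={"oha": (3.0, 0.0)},
        )
        cal = _calibrate(params)
        cc_ds, mi_ds = [], []
        for rep in range(16):
            pr = params.replace(seed=700 + rep)
            trial = fill_covariates(
                apply_dropout(generate_cohort(pr, items=False, calibration=cal), pr)
            )
            mi_d, cc_d = fast_mi_d(trial, seed=700 + rep)
            cc_ds.append(cc_d)
            mi_ds.append(mi_d)
        cc_bias = abs(np.mean(cc_ds))
        mi_bias = abs(np.mean(mi_ds))
        # the configuration must actually induce complete-case bias
        assert cc_bias > 2 * np.std(cc_ds, ddof=1) / np.sqrt(len(cc_ds))
        assert mi_bias < cc_bias

    def test_mi_estimate_freezes_complete_pair_constants(self):
        params = CohortParams(
            n_nurses=20, patients_per_nurse=8, seed=77,
            dropout_rate_by_arm=(0.3, 0.2),
        )
        trial = fill_covariates(
            apply_dropout(generate_cohort(params, items=False), params)
        )
        res = mi_estimate(trial, m=3, seed=1, n_between=2)
        expected = build_outcomes(trial.analysis_frame()).constants
        assert res.constants == pytest.approx(expected)
        assert res.pooled.model_tag.startswith("mi-pooled")
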