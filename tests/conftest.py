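import warnings

import pytest

from multiadhere.cohort import (
    CohortParams,
    TrialDataset,
    _calibrate,
    behavior_effects_for_composite,
    generate_cohort,
)

warnings.filterwarnings("ignore", message="singular or failed mixed fit")

#: restricted imputation-model predictors used by the simulation tests
#: (markedly faster than the full covariate set, same outcome model)
MI_PREDICTORS = [
    "treat", "base_pa", "base_snack", "base_oha", "base_insulin",
    "nurse_base_mean",
]


def fill_covariates(trial: TrialDataset) -> TrialDataset:
    """Remove covariate missingness so MI only targets follow-up scores."""
    p = trial.participants.copy()
    p["income"] = p["income"].fillna("above")
    p["education"] = p["education"].fillna("middle")
    return TrialDataset(p, trial.scores, trial.items)


def fast_mi_d(trial: TrialDataset, seed: int, m: int = 4) -> tuple[float, float]:
    """(MI-pooled d, complete-case d) with the restricted imputation model."""
    from multiadhere.missing import (
        completed_scores_frame, impute_chained, pool_rubin,
    )
    from multiadhere.models import fit_mixed
    from multiadhere.outcomes import build_outcomes

    css = build_outcomes(trial.analysis_frame())
    cc = fit_mixed(css.table).d
    completed = impute_chained(
        trial, m=m, seed=seed, n_between=2, predictors=MI_PREDICTORS
    )
    meta = trial.meta(covariates=True)
    ests = [
        fit_mixed(
            build_outcomes(
                meta.merge(
                    completed_scores_frame(snap), on="participant_id", how="left"
                ),
                constants=css.constants,
            ).table
        )
        for snap in completed
    ]
    return pool_rubin(ests).d, cc


@pytest.fixture(scope="session")
def base_params() -> CohortParams:
    """Small null cohort (96 participants, 12 nurses)."""
    return CohortParams(n_nurses=12, patients_per_nurse=8, seed=11)


@pytest.fixture(scope="session")
def small_trial(base_params):
    """Two-wave cohort with item-level responses, no dropout applied."""
    return generate_cohort(base_params)


@pytest.fixture(scope="session")
def effect_params() -> CohortParams:
    """Cohort parameters with a true composite effect of 0.4."""
    p = CohortParams(n_nurses=60, patients_per_nurse=8, icc=0.02, seed=5)
    return p.replace(true_effects=behavior_effects_for_composite(0.4, p))


@pytest.fixture(scope="session")
def effect_calibration(effect_params):
    return _calibrate(effect_params)
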