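"""Missing-data handling: multiple imputation and scenario sensitivity.

Two distinct paths, mirroring the trial's analysis plan:

* **Intention-to-treat multiple imputation** (:func:`impute_chained`,
  :func:`mi_estimate`): chained-equation imputation of missing follow-up
  behavior scores and missing covariates (predictive mean matching via
  ``statsmodels`` MICE), after which outcomes are rebuilt against the
  standardization constants frozen from the complete-pairs sample, the
  mixed model is fitted per completed dataset and estimates are pooled
  with Rubin's rules (Barnard-Rubin degrees of freedom).  Valid under
  missing-at-random.
* **Optimistic/pessimistic scenario imputation**
  (:func:`scenario_impute`, :func:`run_sensitivity_suite`): the four
  bespoke scenarios operate directly on the standardized composite D.
  Each missing D in arm *g* is drawn from
  ``Normal(mean_g + sign * shift_g * SD_g, SD_g)`` where the mean and SD
  are those of the arm's observed D, ``sign`` is +1 (optimistic) or -1
  (pessimistic) and ``shift_g`` is the SD multiplier (1.0 in the equal
  variant for both arms; the unequal variant uses 1.5 in the control
  arm, per the explicit scenario formula).  Observed values are never
  modified by either path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import BEHAVIORS, SCORE_COLUMNS, TrialDataset
from .errors import ParameterError, StandardizationError
from .models import EffectEstimate, fit_mixed
from .outcomes import ChangeScoreSet, build_outcomes

_TAG_SCENARIO, _TAG_MI = 21, 22

#: Default number of completed datasets for the chained-equation path.
DEFAULT_M = 20


@dataclass(frozen=True)
class ScenarioSpec:
    """One sensitivity-imputation scenario.

    ``direction`` maps to the sign of the mean shift (+1 optimistic,
    -1 pessimistic) applied in both arms; ``variant`` sets the control
    arm's SD multiplier (1.0 equal, 1.5 unequal); the intervention arm's
    multiplier is 1.0 in both variants.
    """

    direction: str  # "optimistic" | "pessimistic"
    variant: str    # "equal" | "unequal"
    shift_int: float = 1.0
    shift_ctrl: Optional[float] = None

    def __post_init__(self) -> None:
        if self.direction not in ("optimistic", "pessimistic"):
            raise ParameterError(f"unknown direction {self.direction!r}")
        if self.variant not in ("equal", "unequal"):
            raise ParameterError(f"unknown variant {self.variant!r}")
        if self.shift_ctrl is None:
            object.__setattr__(
                self, "shift_ctrl", 1.0 if self.variant == "equal" else 1.5
            )
        if self.shift_int < 0 or self.shift_ctrl < 0:
            raise ParameterError("SD-shift multipliers must be >= 0")

    @property
    def sign(self) -> float:
        return 1.0 if self.direction == "optimistic" else -1.0

    @property
    def tag(self) -> str:
        return f"scenario:{self.direction}-{self.variant}"


def default_scenarios() -> tuple[ScenarioSpec, ...]:
    """The four protocol scenarios: {optimistic, pessimistic} x {equal, unequal}."""
    return tuple(
        ScenarioSpec(direction=d, variant=v)
        for d in ("optimistic", "pessimistic")
        for v in ("equal", "unequal")
    )


def scenario_impute(
    outcomes: pd.DataFrame, spec: ScenarioSpec, seed: int = 0
) -> pd.DataFrame:
    """Fill missing D values according to one scenario.

    ``outcomes`` is a :class:`~multiadhere.outcomes.ChangeScoreSet` table
    (or any frame with ``participant_id, arm, D``).  Each arm's observed
    D supplies the mean and SD of the normal from which that arm's
    missing values are drawn, with the scenario's signed SD-multiple
    added to the mean.  Reproducible under ``seed``; observed values are
    returned untouched.
    """
    if "D" not in outcomes.columns or "arm" not in outcomes.columns:
        raise ParameterError("outcomes frame needs 'D' and 'arm' columns")
    out = outcomes.copy()
    rng = np.random.default_rng(np.random.SeedSequence([
        int(seed), _TAG_SCENARIO,
        0 if spec.direction == "optimistic" else 1,
        0 if spec.variant == "equal" else 1,
    ]))
    for arm, shift in (("intervention", spec.shift_int), ("control", spec.shift_ctrl)):
        in_arm = out["arm"] == arm
        observed = out.loc[in_arm, "D"].dropna()
        if len(observed) < 2:
            raise StandardizationError(
                f"arm {arm!r} has {len(observed)} observed outcomes; "
                "cannot form scenario moments"
            )
        miss = in_arm & out["D"].isna()
        n_miss = int(miss.sum())
        if n_miss:
            mu = observed.mean() + spec.sign * shift * observed.std(ddof=1)
            out.loc[miss, "D"] = rng.normal(mu, observed.std(ddof=1), size=n_miss)
    return out


def run_sensitivity_suite(
    outcomes: pd.DataFrame,
    seed: int = 0,
    specs: Optional[Sequence[ScenarioSpec]] = None,
    alpha: float = 0.05,
) -> dict[str, EffectEstimate]:
    """Complete-case estimate plus one mixed-model estimate per scenario.

    Returns a mapping from model tag (``complete-case`` and
    ``scenario:<direction>-<variant>``) to the unadjusted nurse-nested
    mixed-model effect on the completed outcome.
    """
    if specs is None:
        specs = default_scenarios()
    covered = {(s.direction, s.variant) for s in specs}
    expected = {(d, v) for d in ("optimistic", "pessimistic") for v in ("equal", "unequal")}
    if covered != expected:
        raise ParameterError(
            "scenario specs must cover {optimistic, pessimistic} x {equal, unequal}"
        )
    results: dict[str, EffectEstimate] = {}
    results["complete-case"] = fit_mixed(
        outcomes, alpha=alpha, model_tag="complete-case"
    )
    for spec in specs:
        completed = scenario_impute(outcomes, spec, seed=seed)
        results[spec.tag] = fit_mixed(completed, alpha=alpha, model_tag=spec.tag)
    return results


# ---------------------------------------------------------------------------
# chained-equation multiple imputation
# ---------------------------------------------------------------------------

_MI_CATEGORICAL_CODES = {
    "gender": {"male": 0.0, "female": 1.0},
    "education": {"low": 0.0, "middle": 1.0, "high": 2.0},
    "income": {"under": 0.0, "above": 1.0},
    "living": {"alone": 0.0, "together": 1.0},
    "work": {"salaried": 0.0, "none": 1.0, "retired": 2.0, "disabled": 3.0},
    "medication_type": {"oha-only": 0.0, "insulin-only": 1.0, "both": 2.0},
    "nurse_type": {"diabetes": 0.0, "practice": 1.0},
    "depression": {"never-past": 0.0, "current": 1.0},
}
_MI_CONTINUOUS = ("age", "bmi", "hba1c")


def _mi_wide_frame(trial: TrialDataset) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One numeric row per participant for the imputation model.

    Returns ``(numeric frame, meta frame)``; the numeric frame holds
    coded covariates, a nurse-level summary, baseline scores and
    follow-up scores (missing for dropouts).
    """
    meta = trial.meta(covariates=True)
    scores = trial.scores
    if scores is None:
        raise ParameterError("trial dataset has no scores")
    wide = meta.set_index("participant_id")
    num = pd.DataFrame(index=wide.index)
    num["treat"] = (wide["arm"] == "intervention").astype(float)
    for cov, codes in _MI_CATEGORICAL_CODES.items():
        if cov in wide:
            num[cov] = wide[cov].map(codes)
    for cov in _MI_CONTINUOUS:
        if cov in wide:
            num[cov] = wide[cov].astype(float)
    for wave, prefix in (("baseline", "base"), ("followup", "fup")):
        sub = scores[scores["wave"] == wave].set_index("participant_id")
        for b in BEHAVIORS:
            num[f"{prefix}_{b}"] = sub[SCORE_COLUMNS[b]].reindex(num.index)
    # nurse-level summary: mean coarse baseline z across the nurse's patients
    zcols = []
    for b in BEHAVIORS:
        col = num[f"base_{b}"]
        zcols.append((col - col.mean()) / col.std())
    zbar = pd.concat(zcols, axis=1).mean(axis=1)
    num["nurse_base_mean"] = (
        zbar.groupby(wide["nurse_id"]).transform("mean").fillna(0.0)
    )
    return num, wide.reset_index()


def impute_chained(
    trial: TrialDataset,
    m: int = DEFAULT_M,
    seed: int = 0,
    n_between: int = 5,
    predictors: Optional[Sequence[str]] = None,
) -> list[pd.DataFrame]:
    """Chained-equation imputation of a post-dropout trial dataset.

    Builds one numeric row per participant (arm, coded covariates, a
    nurse-level summary, baseline and follow-up behavior scores), runs
    predictive-mean-matching MICE and returns ``m`` completed copies.
    Behavior scores that are structurally missing (instrument not
    applicable given medication type) are re-masked to missing after
    imputation; genuinely observed values are never altered.

    ``predictors`` optionally restricts every imputation model's
    right-hand side to the named columns (default: all other columns),
    which is markedly faster in simulation studies.
    """
    if m < 2:
        raise ParameterError("m must be >= 2")
    from statsmodels.imputation.mice import MICEData

    num, meta = _mi_wide_frame(trial)
    all_missing = [c for c in num.columns if num[c].isna().all()]
    if all_missing:
        raise ParameterError(
            f"column(s) with 100% missingness cannot be imputed: {all_missing}"
        )
    constant = [
        c for c in num.columns if num[c].isna().any() and num[c].nunique(dropna=True) < 2
    ]
    if constant:
        raise ParameterError(f"column(s) with constant observed part: {constant}")

    applicable = {
        "oha": meta["medication_type"].isin(["oha-only", "both"]).to_numpy(),
        "insulin": meta["medication_type"].isin(["insulin-only", "both"]).to_numpy(),
    }
    # structurally missing scores (instrument not applicable) are not
    # imputation targets: freeze them at the observed mean so the chained
    # sweeps only visit genuinely missing values; they are re-masked below
    for b, mask in applicable.items():
        for col in (f"base_{b}", f"fup_{b}"):
            fill = num.loc[mask, col].mean()
            num.loc[~mask, col] = fill

    # MICEData consumes the numpy global state; scope it to a derived seed
    state = np.random.get_state()
    np.random.seed(
        int(np.random.SeedSequence([int(seed), _TAG_MI]).generate_state(1)[0] % 2**31)
    )
    try:
        md = MICEData(num.reset_index(drop=True))
        if predictors is not None:
            unknown = set(predictors) - set(num.columns)
            if unknown:
                raise ParameterError(f"unknown predictor column(s): {sorted(unknown)}")
            for col in num.columns:
                if num[col].isna().any():
                    rhs = [p for p in predictors if p != col]
                    md.set_imputer(col, " + ".join(rhs))
        completed: list[pd.DataFrame] = []
        for _ in range(m):
            md.update_all(n_between)
            snap = md.data.copy()
            snap.index = num.index
            for b, mask in applicable.items():
                snap.loc[~mask, [f"base_{b}", f"fup_{b}"]] = np.nan
            completed.append(snap)
    finally:
        np.random.set_state(state)
    return completed


def completed_scores_frame(completed: pd.DataFrame) -> pd.DataFrame:
    """Convert a completed wide imputation frame back to the two-wave
    score layout consumed by the outcome pipeline."""
    frames = []
    for wave, prefix in (("baseline", "base"), ("followup", "fup")):
        frames.append(pd.DataFrame({
            "participant_id": completed.index,
            "wave": wave,
            **{
                SCORE_COLUMNS[b]: completed[f"{prefix}_{b}"].to_numpy()
                for b in BEHAVIORS
            },
        }))
    return pd.concat(frames, ignore_index=True)


def decode_covariates(
    table: pd.DataFrame, completed: pd.DataFrame, covariates: Sequence[str]
) -> pd.DataFrame:
    """Overwrite covariate columns of an outcome table with the (possibly
    imputed) values of a completed wide frame, mapping numeric category
    codes back to their labels for the model formulas."""
    out = table.copy()
    for cov in covariates:
        vals = completed[cov].reindex(out["participant_id"]).to_numpy()
        if cov in _MI_CATEGORICAL_CODES:
            inv = {v: k for k, v in _MI_CATEGORICAL_CODES[cov].items()}
            out[cov] = pd.Series(vals).round().map(inv).to_numpy()
        else:
            out[cov] = vals
    return out


@dataclass
class ImputationResult:
    """Per-dataset estimates and their Rubin-pooled summary."""

    m: int
    estimates: list[EffectEstimate]
    pooled: EffectEstimate
    constants: dict[str, float] = field(default_factory=dict)


def pool_rubin(
    estimates: Sequence[EffectEstimate], alpha: float = 0.05
) -> EffectEstimate:
    """Pool per-dataset effect estimates with Rubin's rules.

    Point estimate: mean of the per-dataset points.  Total variance:
    within-imputation mean plus ``(1 + 1/m)`` times the between-imputation
    variance.  Degrees of freedom follow Barnard-Rubin, with the smallest
    per-dataset df as the complete-data df.
    """
    from scipy import stats

    if len(estimates) < 2:
        raise ParameterError("Rubin pooling needs m >= 2 estimates")
    m = len(estimates)
    q = np.array([e.d for e in estimates])
    w = np.array([e.se**2 for e in estimates])
    if np.all(w == 0):
        raise StandardizationError("zero within-imputation variance in all datasets")
    qbar = float(q.mean())
    w_bar = float(w.mean())
    b = float(q.var(ddof=1))
    total = w_bar + (1.0 + 1.0 / m) * b
    se = float(np.sqrt(total))
    nu_com = float(min(e.df for e in estimates))
    if b == 0.0:
        nu = nu_com
    else:
        lam = (1.0 + 1.0 / m) * b / total
        nu_old = (m - 1) / lam**2
        nu_obs = (nu_com + 1.0) / (nu_com + 3.0) * nu_com * (1.0 - lam)
        nu = 1.0 / (1.0 / nu_old + 1.0 / nu_obs)
    t = qbar / se
    p = 2.0 * float(stats.t.sf(abs(t), nu))
    half = float(stats.t.ppf(1.0 - alpha / 2.0, nu)) * se
    tag = estimates[0].model_tag
    return EffectEstimate(
        d=qbar, ci_low=qbar - half, ci_high=qbar + half,
        t=t, df=nu, p=p, se=se,
        model_tag=f"mi-pooled:{tag}", df_method="barnard-rubin",
    )


def mi_estimate(
    trial: TrialDataset,
    m: int = DEFAULT_M,
    seed: int = 0,
    covariates: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
    n_between: int = 5,
) -> ImputationResult:
    """Intention-to-treat effect estimate via multiple imputation.

    Freezes the standardization constants on the complete-pairs sample,
    imputes ``m`` completed datasets, rebuilds the composite outcome per
    dataset against the frozen constants, fits the nurse-nested mixed
    model (optionally adjusted) on each, and pools with Rubin's rules.
    """
    analysis = trial.analysis_frame(covariates=True)
    complete_case: ChangeScoreSet = build_outcomes(analysis)
    constants = complete_case.constants

    completed = impute_chained(trial, m=m, seed=seed, n_between=n_between)
    meta = trial.meta(covariates=True)
    estimates = []
    for snap in completed:
        scores = completed_scores_frame(snap)
        frame = meta.merge(scores, on="participant_id", how="left")
        css = build_outcomes(frame, constants=constants)
        # covariates imputed numerically: map codes back for the formula
        table = css.table
        if covariates:
            table = decode_covariates(table, snap, covariates)
        estimates.append(
            fit_mixed(
                table, covariates=covariates, alpha=alpha,
                model_tag="adjusted" if covariates else "unadjusted",
            )
        )
    pooled = pool_rubin(estimates, alpha=alpha)
    return ImputationResult(
        m=m, estimates=estimates, pooled=pooled, constants=dict(constants)
    )
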