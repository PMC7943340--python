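"""Effect estimation, attrition analysis and design calculations.

The trial nests patients within recruiting nurses, so intervention
effects on the standardized composite (and on the per-behavior
standardized changes) are estimated with linear mixed models carrying a
random intercept per nurse.  Because the outcome is on the Cohen-d scale,
the coefficient of the intervention indicator is itself an effect size.

Denominator degrees of freedom use a between-within approximation
(observations minus clusters minus within-cluster fixed effects); a
Satterthwaite approximation is not available from the underlying fitter,
and with the trial's cluster counts the two are practically
indistinguishable.  The method used is recorded on every estimate.

Sample-size arithmetic uses the classical normal-approximation formula
inflated by the cluster design effect 1 + (m-1)*rho; `simulate_power`
checks a design point empirically by simulating whole trials through the
synthetic-cohort generator and the full outcome pipeline.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .errors import EstimationError, ParameterError

__all__ = [
    "EffectEstimate",
    "OddsRatioEstimate",
    "DesignSpec",
    "PowerEstimate",
    "DEFAULT_ADJUSTED_COVARIATES",
    "fit_mixed",
    "attrition_logistic",
    "crude_or",
    "required_n",
    "simulate_power",
]


@dataclass
class EffectEstimate:
    """An intervention effect on the Cohen-d scale with its uncertainty."""

    d: float
    ci_low: float
    ci_high: float
    t: float
    df: float
    p: float
    se: float
    model_tag: str = "unadjusted"
    df_method: str = "between-within"

    def __post_init__(self) -> None:
        if np.isfinite(self.ci_low) and not (self.ci_low <= self.d <= self.ci_high):
            raise ParameterError("CI must bracket the point estimate")

    def to_dict(self) -> dict:
        return {
            "d": self.d, "ci_low": self.ci_low, "ci_high": self.ci_high,
            "t": self.t, "df": self.df, "p": self.p, "se": self.se,
            "model_tag": self.model_tag, "df_method": self.df_method,
        }


@dataclass
class OddsRatioEstimate:
    """Odds ratio with Wald 95% CI."""

    or_value: float
    ci_low: float
    ci_high: float
    p: float

    def __post_init__(self) -> None:
        if min(self.or_value, self.ci_low, self.ci_high) <= 0:
            raise ParameterError("odds ratio and CI bounds must be positive")
        if not (self.ci_low <= self.or_value <= self.ci_high):
            raise ParameterError("CI must bracket the odds ratio")

    def to_dict(self) -> dict:
        return {
            "or": self.or_value, "ci_low": self.ci_low,
            "ci_high": self.ci_high, "p": self.p,
        }


@dataclass
class DesignSpec:
    """Design inputs for the sample-size and power calculations.

    Defaults reproduce the trial's design point: a composite effect of
    0.4 SD, two-sided alpha 0.05, 80% power, between-nurse ICC 0.02,
    about 8 patients recruited per nurse, and 50% expected attrition.
    """

    d_target: float = 0.4
    alpha: float = 0.05
    power: float = 0.80
    icc: float = 0.02
    cluster_size: int = 8
    attrition: float = 0.50

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ParameterError("alpha must be in (0, 1)")
        if not 0 < self.power < 1:
            raise ParameterError("power must be in (0, 1)")
        if not 0 <= self.icc < 1:
            raise ParameterError("icc must be in [0, 1)")
        if self.cluster_size < 1:
            raise ParameterError("cluster_size must be >= 1")
        if not 0 <= self.attrition < 1:
            raise ParameterError("attrition must be in [0, 1)")


@dataclass
class PowerEstimate:
    """Monte-Carlo power estimate with its binomial standard error."""

    power: float
    se: float
    replicates: int
    rejections: int
    alpha: float
    seed: int


#: Covariates of the adjusted model, in the trial's covariate set.
DEFAULT_ADJUSTED_COVARIATES = (
    "gender", "age", "education", "income", "living", "work",
    "bmi", "hba1c", "medication_type", "nurse_type", "depression",
)

#: Reference categories for the adjusted-model coding (the omitted level
#: of each categorical covariate).
CATEGORICAL_REFERENCES = {
    "gender": "female",
    "education": "high",
    "income": "above",
    "living": "alone",
    "work": "disabled",
    "medication_type": "both",
    "nurse_type": "diabetes",
    "depression": "current",
}


def _effect_from_fit(
    coef: float, se: float, df: float, alpha: float,
    model_tag: str, df_method: str,
) -> EffectEstimate:
    t = coef / se
    p = 2.0 * float(stats.t.sf(abs(t), df))
    half = float(stats.t.ppf(1.0 - alpha / 2.0, df)) * se
    return EffectEstimate(
        d=float(coef), ci_low=float(coef - half), ci_high=float(coef + half),
        t=float(t), df=float(df), p=p, se=float(se),
        model_tag=model_tag, df_method=df_method,
    )


def fit_mixed(
    data: pd.DataFrame,
    outcome: str = "D",
    covariates: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
    model_tag: Optional[str] = None,
) -> EffectEstimate:
    """Nurse-nested linear mixed model for the intervention effect.

    Fits ``outcome ~ intervention (+ covariates)`` with a random intercept
    per ``nurse_id`` (REML) and returns the intervention coefficient; on
    the standardized composite this is the Cohen-d primary end point.
    Rows with a missing outcome (or missing covariates, in the adjusted
    model) are dropped -- impute first for an intention-to-treat analysis.

    A singular fit (zero nurse variance) falls back to the corresponding
    single-level OLS model with a logged warning.
    """
    required = {outcome, "arm", "nurse_id"}
    if not required <= set(data.columns):
        raise ParameterError(f"data lacks columns: {sorted(required - set(data.columns))}")
    df_in = data.copy()
    df_in["treat"] = (df_in["arm"] == "intervention").astype(float)
    cols = [outcome, "treat", "nurse_id"] + list(covariates or ())
    df_in = df_in[cols].dropna()
    if not len(df_in):
        raise EstimationError(f"no rows with observed outcome {outcome!r}")
    if df_in["treat"].nunique() < 2:
        raise EstimationError("both arms must be present after dropping missing rows")
    if model_tag is None:
        model_tag = "adjusted" if covariates else "unadjusted"

    if covariates:
        terms = ["treat"]
        for cov in covariates:
            ref = CATEGORICAL_REFERENCES.get(cov)
            if ref is not None:
                terms.append(f"C({cov}, Treatment('{ref}'))")
            else:
                terms.append(cov)
        formula = f"{outcome} ~ " + " + ".join(terms)
        model = smf.mixedlm(formula, df_in, groups=df_in["nurse_id"])
        coef_name = "treat"
    else:
        endog = df_in[outcome].to_numpy()
        exog = np.column_stack([np.ones(len(df_in)), df_in["treat"].to_numpy()])
        model = sm.MixedLM(endog, exog, groups=df_in["nurse_id"].to_numpy())
        coef_name = 1  # positional: [intercept, treat]

    n_obs = len(df_in)
    n_groups = df_in["nurse_id"].nunique()

    singular = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = model.fit(reml=True)
        singular = float(np.asarray(result.cov_re)[0, 0]) < 1e-8
        converged = getattr(result, "converged", True)
    except (np.linalg.LinAlgError, ValueError):
        singular, converged, result = True, False, None

    if singular or not converged:
        warnings.warn(
            "singular or failed mixed fit (nurse variance ~ 0); "
            "falling back to the single-level model",
            stacklevel=2,
        )
        if covariates:
            ols = smf.ols(formula, df_in).fit()
        else:
            ols = sm.OLS(endog, exog).fit()
        coef = ols.params[coef_name]
        se = ols.bse[coef_name]
        return _effect_from_fit(
            coef, se, ols.df_resid, alpha, model_tag, "ols-residual"
        )

    coef = float(result.params[coef_name])
    se = float(result.bse[coef_name])
    k_fixed = result.k_fe
    # between-within: within-cluster df for covariates varying inside nurses
    ddf = max(n_obs - n_groups - (k_fixed - 1), 1)
    return _effect_from_fit(coef, se, ddf, alpha, model_tag, "between-within")


def crude_or(
    table: Sequence[Sequence[float]],
    alpha: float = 0.05,
    continuity: Optional[float] = None,
) -> OddsRatioEstimate:
    """Closed-form odds ratio from a 2x2 table ``[[a, b], [c, d]]``.

    Rows are groups, columns are (event, no event); the returned OR is
    the odds of the event in row 1 relative to row 2, with a Wald CI from
    the standard log-OR standard error sqrt(1/a + 1/b + 1/c + 1/d).

    A zero cell raises unless ``continuity`` is given (e.g. ``0.5`` adds
    the Haldane-Anscombe correction to all four cells).
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ParameterError(f"expected a 2x2 table, got shape {arr.shape}")
    if (arr < 0).any():
        raise ParameterError("cell counts must be non-negative")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ParameterError("2x2 table has a zero margin")
    if (arr == 0).any():
        if continuity is None:
            raise ParameterError(
                "zero cell in 2x2 table; pass continuity=0.5 to correct"
            )
        arr = arr + continuity
    a, b = arr[0]
    c, d = arr[1]
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(1 - alpha / 2)
    p = 2 * float(stats.norm.sf(abs(log_or / se)))
    return OddsRatioEstimate(
        or_value=math.exp(log_or),
        ci_low=math.exp(log_or - z * se),
        ci_high=math.exp(log_or + z * se),
        p=p,
    )


def attrition_logistic(
    data: pd.DataFrame,
    predictors: Sequence[str],
    outcome: str = "retained",
    alpha: float = 0.05,
) -> dict[str, OddsRatioEstimate]:
    """Logistic regression of retention on baseline predictors.

    Numeric predictors enter as-is; categorical predictors are expanded
    into indicator columns (first level as reference).  Returns one
    odds-ratio estimate per design column.

    Raises
    ------
    EstimationError
        On (quasi-)separation or non-convergence, rather than returning
        silently absurd estimates.
    """
    if outcome not in data.columns:
        raise ParameterError(f"outcome column {outcome!r} missing")
    if not predictors:
        raise ParameterError("at least one predictor is required")
    cols = data[list(predictors)].copy()
    design = pd.get_dummies(cols, drop_first=True, dtype=float)
    design = sm.add_constant(design)
    y = data[outcome].astype(float)
    keep = design.notna().all(axis=1) & y.notna()
    design, y = design[keep], y[keep]
    if y.nunique() < 2:
        raise EstimationError("retention outcome is constant")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, design).fit(disp=0)
    except Exception as err:  # PerfectSeparationError et al.
        raise EstimationError(f"attrition logistic regression failed: {err}") from err
    if not res.mle_retvals.get("converged", True) or np.abs(res.params).max() > 15:
        raise EstimationError(
            "attrition logistic regression did not converge (separation?)"
        )
    z = stats.norm.ppf(1 - alpha / 2)
    out: dict[str, OddsRatioEstimate] = {}
    for name in design.columns:
        if name == "const":
            continue
        beta, se = res.params[name], res.bse[name]
        out[name] = OddsRatioEstimate(
            or_value=math.exp(beta),
            ci_low=math.exp(beta - z * se),
            ci_high=math.exp(beta + z * se),
            p=float(res.pvalues[name]),
        )
    return out


@dataclass
class SampleSize:
    """Follow-up requirement per arm and baseline inclusion target."""

    n_group: int
    baseline_total: int
    design_effect: float


def required_n(design: DesignSpec, n_group: Optional[int] = None) -> SampleSize:
    """Per-group follow-up sample size and baseline inclusion target.

    Uses the normal-approximation two-sample formula inflated by the
    cluster design effect::

        n_group = ceil( 2 (z_{1-alpha/2} + z_{power})^2 / d^2
                        * (1 + (m - 1) rho) )

    and converts to a baseline target by dividing the total follow-up
    requirement by the expected retention, ``baseline_total =
    ceil(2 n_group / (1 - attrition))``.  Pass ``n_group`` to override
    the formula (e.g. to reproduce a protocol-stated requirement).
    """
    deff = 1.0 + (design.cluster_size - 1) * design.icc
    if n_group is None:
        if design.d_target == 0:
            raise ParameterError("d_target must be non-zero")
        z_a = stats.norm.ppf(1 - design.alpha / 2)
        z_b = stats.norm.ppf(design.power)
        n_raw = 2.0 * (z_a + z_b) ** 2 / design.d_target**2 * deff
        n_group = int(math.ceil(n_raw - 1e-12))
    baseline_total = int(math.ceil(2.0 * n_group / (1.0 - design.attrition) - 1e-12))
    return SampleSize(n_group=n_group, baseline_total=baseline_total, design_effect=deff)


def simulate_power(
    design: DesignSpec,
    n_group: int,
    replicates: int,
    seed: int,
    progress: bool = False,
) -> PowerEstimate:
    """Empirical power of the primary-outcome test at a design point.

    Each replicate generates a complete trial of ``2 * n_group``
    follow-up participants (``cluster_size`` patients per nurse,
    individual randomization within nurses, ICC ``design.icc``) through
    the synthetic-cohort generator with per-behavior effects calibrated
    so the true composite effect equals ``design.d_target``, runs the
    full composite-outcome pipeline and the unadjusted nurse-nested
    mixed model, and records rejection at ``design.alpha``.

    With ``d_target = 0`` this estimates the empirical size of the test.
    Generation is score-level (item encoding skipped) for speed; item
    encoding and re-scoring are exact inverses of each other, which the
    scoring tests establish separately.
    """
    from .cohort import (
        CohortParams, behavior_effects_for_composite, generate_cohort,
        _calibrate,
    )
    from .outcomes import build_outcomes

    if replicates < 100:
        raise ParameterError("use at least 100 replicates")
    if n_group < 2:
        raise ParameterError("n_group must be >= 2")
    n_nurses = int(math.ceil(2.0 * n_group / design.cluster_size))
    params = CohortParams(
        n_nurses=n_nurses,
        patients_per_nurse=design.cluster_size,
        icc=design.icc,
        dropout_rate_by_arm=(0.0, 0.0),
        seed=0,
    )
    effects = behavior_effects_for_composite(design.d_target, params)
    params = params.replace(true_effects=effects)
    calibration = _calibrate(params)

    root = np.random.SeedSequence([int(seed), 0x504F]).generate_state(replicates)
    rejections = 0
    for i in range(replicates):
        rep_params = params.replace(seed=int(root[i]) % 2**31)
        trial = generate_cohort(rep_params, items=False, calibration=calibration)
        css = build_outcomes(trial.analysis_frame())
        est = fit_mixed(css.table, alpha=design.alpha)
        if est.p < design.alpha:
            rejections += 1
        if progress and (i + 1) % 100 == 0:
            print(f"  {i + 1}/{replicates} replicates, "
                  f"rejection rate {rejections / (i + 1):.3f}")
    power = rejections / replicates
    se = math.sqrt(max(power * (1 - power), 1e-12) / replicates)
    return PowerEstimate(
        power=power, se=se, replicates=replicates,
        rejections=rejections, alpha=design.alpha, seed=seed,
    )
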