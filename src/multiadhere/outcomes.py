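"""Composite standardized change-score construction.

The primary outcome of the trial is built in four steps, per participant:

1. **Raw change** per behavior: follow-up score minus baseline score.
2. **Orientation**: the snack change is sign-reversed so that a larger
   change always means improvement (more activity minutes, fewer snack
   kilocalories, higher adherence sums).
3. **Standardization**: each behavior's change is divided by the pooled
   SD of that behavior's change scores across the two trial arms
   (classical two-sample pooled estimator, (n-1) denominators), making
   the behaviors commensurable.
4. **Composition**: the standardized changes of the participant's
   applicable behaviors are summed into the composite C, which is then
   divided by the pooled SD of C itself.  The resulting D has pooled SD 1
   by construction, so a between-arm difference in mean D reads directly
   as a Cohen-d effect size.

Participants not using oral agents (or insulin) contribute no term for
that behavior; the composite sums over the applicable behaviors only,
without rescaling by their count (an optional per-count rescaling is
exposed but off by default).  Participants without a follow-up wave keep
a row with missing D so that downstream imputation can fill it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError, StandardizationError

BEHAVIORS = ("pa", "snack", "oha", "insulin")

#: Score-frame column per behavior.
SCORE_COLUMNS = {"pa": "pa_min", "snack": "snack_kcal", "oha": "oha", "insulin": "insulin"}

ARM_INTERVENTION = "intervention"
ARM_CONTROL = "control"


def pooled_sd(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """Two-sample pooled SD: sqrt(((n1-1)s1^2 + (n2-1)s2^2) / (n1+n2-2)).

    Raises
    ------
    StandardizationError
        If either arm has fewer than 2 non-missing values or the pooled
        SD is zero.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise StandardizationError(
            f"pooled SD needs >= 2 values per arm, got {len(a)} and {len(b)}"
        )
    s2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (
        len(a) + len(b) - 2
    )
    s = float(np.sqrt(s2))
    if s == 0.0:
        raise StandardizationError("pooled SD is zero (degenerate variance)")
    return s


def oriented_changes(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-participant oriented change scores from a two-wave score frame.

    ``scores`` has one row per participant x wave with columns
    ``participant_id, wave, pa_min, snack_kcal, oha, insulin`` (plus any
    metadata columns, which are carried through from the baseline row).
    Change is follow-up minus baseline; the snack change is negated so
    that positive means fewer kilocalories.  Behaviors missing at either
    wave (including all behaviors of participants without a follow-up
    row) yield missing changes, never zero.

    Returns one row per participant with columns ``d_pa, d_snack, d_oha,
    d_insulin`` plus the carried metadata.
    """
    waves = set(scores["wave"])
    if not waves <= {"baseline", "followup"}:
        raise ParameterError(f"unknown wave labels: {sorted(waves - {'baseline', 'followup'})}")
    meta_cols = [
        c for c in scores.columns
        if c not in ("wave", *SCORE_COLUMNS.values(), "oha_flag", "insulin_flag")
    ]
    base = scores[scores["wave"] == "baseline"].set_index("participant_id")
    if base.index.duplicated().any():
        raise ParameterError("duplicate baseline rows for some participants")
    fup = scores[scores["wave"] == "followup"].set_index("participant_id")
    out = base[[c for c in meta_cols if c != "participant_id"]].copy()
    for behavior, col in SCORE_COLUMNS.items():
        delta = fup[col].reindex(base.index) - base[col]
        if behavior == "snack":
            delta = -delta
        out[f"d_{behavior}"] = delta
    return out.reset_index()


@dataclass
class ChangeScoreSet:
    """Standardized change scores, the composite C, and the primary D.

    Attributes
    ----------
    table
        One row per participant: ``participant_id, arm, nurse_id`` (and
        other carried metadata), oriented changes ``d_*``, standardized
        changes ``z_*``, the composite ``C`` and the standardized
        composite ``D``.  Missing follow-up yields missing ``C``/``D``.
    behavior_sds
        Pooled SD of each behavior's change scores (the standardization
        constants of step 3).
    composite_sd
        Pooled SD of C (the constant of step 4).
    rescaled_by_count
        Whether C was divided by the number of applicable behaviors
        (non-default variant).
    """

    table: pd.DataFrame
    behavior_sds: dict[str, float] = field(default_factory=dict)
    composite_sd: float = float("nan")
    rescaled_by_count: bool = False

    @property
    def constants(self) -> dict[str, float]:
        out = dict(self.behavior_sds)
        out["composite"] = self.composite_sd
        return out


def standardize_and_compose(
    changes: pd.DataFrame,
    rescale_by_count: bool = False,
    constants: Optional[Mapping[str, float]] = None,
) -> ChangeScoreSet:
    """Standardize oriented changes and build the composite outcome.

    ``changes`` is the output of :func:`oriented_changes` and must carry
    an ``arm`` column.  Pooled SDs are estimated on the participants with
    an observed change for each behavior (complete pairs), across both
    arms; pass ``constants`` (mapping behavior -> SD, plus ``"composite"``)
    to reuse frozen constants instead, e.g. when re-scoring multiply
    imputed datasets against the original standardization.
    """
    if "arm" not in changes.columns:
        raise ParameterError("changes frame must carry an 'arm' column")
    arms = set(changes["arm"].dropna())
    if not arms <= {ARM_INTERVENTION, ARM_CONTROL}:
        raise ParameterError(f"unknown arm labels: {sorted(arms)}")

    table = changes.copy()
    is_int = table["arm"] == ARM_INTERVENTION
    behavior_sds: dict[str, float] = {}
    for behavior in BEHAVIORS:
        delta = table[f"d_{behavior}"]
        if delta.notna().sum() == 0:
            # behavior never observed (e.g. no insulin users): no z column
            table[f"z_{behavior}"] = np.nan
            continue
        if constants is not None:
            s = float(constants[behavior])
            if not np.isfinite(s) or s <= 0:
                raise StandardizationError(
                    f"frozen pooled SD for behavior {behavior!r} is degenerate"
                )
        else:
            try:
                s = pooled_sd(delta[is_int], delta[~is_int])
            except StandardizationError as err:
                raise StandardizationError(
                    f"behavior {behavior!r}: {err}"
                ) from None
        behavior_sds[behavior] = s
        table[f"z_{behavior}"] = delta / s

    z_cols = [f"z_{b}" for b in BEHAVIORS]
    n_applicable = table[z_cols].notna().sum(axis=1)
    # a participant with a follow-up wave has all applicable behaviors
    # observed; one without has none -> C missing
    comp = table[z_cols].sum(axis=1, min_count=1)
    if rescale_by_count:
        comp = comp / n_applicable.replace(0, np.nan)
    table["n_behaviors"] = n_applicable
    table["C"] = comp

    if constants is not None:
        c_sd = float(constants["composite"])
        if not np.isfinite(c_sd) or c_sd <= 0:
            raise StandardizationError("frozen composite pooled SD is degenerate")
    else:
        c_sd = pooled_sd(comp[is_int], comp[~is_int])
    table["D"] = comp / c_sd
    return ChangeScoreSet(
        table=table,
        behavior_sds=behavior_sds,
        composite_sd=c_sd,
        rescaled_by_count=rescale_by_count,
    )


def build_outcomes(
    scores: pd.DataFrame,
    rescale_by_count: bool = False,
    constants: Optional[Mapping[str, float]] = None,
) -> ChangeScoreSet:
    """Full pipeline from a two-wave score frame to the composite outcome."""
    return standardize_and_compose(
        oriented_changes(scores),
        rescale_by_count=rescale_by_count,
        constants=constants,
    )


def arm_effect_d(values: Sequence[float], arm: Sequence[str], alpha: float = 0.05):
    """Raw between-arm contrast of a standardized outcome.

    Returns an :class:`~multiadhere.models.EffectEstimate` with the
    intervention-minus-control mean difference, a classical two-sample
    (pooled-variance) t test and its CI.  When the outcome is the
    standardized composite D, the difference is a Cohen d.
    """
    from .models import EffectEstimate  # local import to avoid a cycle

    values = np.asarray(values, dtype=float)
    arm = np.asarray(arm)
    keep = ~np.isnan(values)
    values, arm = values[keep], arm[keep]
    arms = set(arm)
    if arms != {ARM_INTERVENTION, ARM_CONTROL}:
        raise ParameterError(
            f"both arms must be represented, got {sorted(arms)}"
        )
    a = values[arm == ARM_INTERVENTION]
    b = values[arm == ARM_CONTROL]
    diff = float(a.mean() - b.mean())
    s = pooled_sd(a, b)
    se = s * float(np.sqrt(1.0 / len(a) + 1.0 / len(b)))
    df = len(a) + len(b) - 2
    t = diff / se
    p = 2.0 * float(stats.t.sf(abs(t), df))
    half = float(stats.t.ppf(1.0 - alpha / 2.0, df)) * se
    return EffectEstimate(
        d=diff, ci_low=diff - half, ci_high=diff + half,
        t=t, df=float(df), p=p, se=se,
        model_tag="raw-contrast", df_method="two-sample",
    )
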