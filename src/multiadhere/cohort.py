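"""Synthetic item-level trial generator.

Emulates the statistical structure of a two-arm, individually randomized
adherence trial in type 2 diabetes: patients nested in recruiting nurses
(both arms present within every nurse), four behavior scores with the
published baseline moments, per-behavior treatment effects on the change
scores, a between-nurse intraclass correlation on the composite change,
and differential (optionally covariate-dependent) dropout.

Generation model
----------------
Scores are generated per behavior from a Gaussian copula: latent
baseline and follow-up normals with test-retest correlation ``c_b`` are
pushed through moment-matched marginals --

* gamma for activity minutes and snack kilocalories (their published
  SDs exceed their means, so a left-truncated normal cannot match both
  moments; the gamma matches them exactly on a non-negative support);
* beta-binomial on 0..18 / 0..9 for the adherence sum scores (exact
  moments on the legal integer range).

The intervention effect for behavior ``b`` is a location shift of the
follow-up marginal, calibrated (by a deterministic internal Monte-Carlo
quadrature) so that the shift equals ``true_effects[b]`` pooled change
SDs.  Because the shift moves the whole marginal rather than adding to
bounded draws, no clipping is needed and the standardized effect is
recovered without attenuation.

The nurse random intercept loads on each behavior's latent follow-up
innovation with a per-participant weight chosen so that the nurse share
of the variance of the participant's latent composite change equals the
target ICC, whatever the number of applicable behaviors.

Item-level responses are emitted backwards from the scores: any
response pattern consistent with the target score (e.g. ``k`` randomly
chosen adherent items for a sum score of ``k``).  The analysis consumes
scores only, so patterns need to be valid, not behaviorally realistic.

One pseudo-random stream is derived from the master seed per logical
stage (structure, latent scores, item encoding, dropout), so changing
one stage's consumption never perturbs another.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .errors import ParameterError
from .scoring import DEFAULT_KCAL_TABLE, DEFAULT_MET_TABLE, MET_THRESHOLD

BEHAVIORS = ("pa", "snack", "oha", "insulin")

#: Number of items of the bounded adherence instruments.
SCALE_ITEMS = {"oha": 18, "insulin": 9}

SCORE_COLUMNS = {"pa": "pa_min", "snack": "snack_kcal", "oha": "oha", "insulin": "insulin"}

# stream tags (SeedSequence spawn keys) per logical stage
_TAG_STRUCTURE, _TAG_LATENT, _TAG_ITEMS, _TAG_DROPOUT = 11, 12, 13, 14

#: Native-scale direction of improvement per behavior: +1 where higher
#: scores are better, -1 for snack kilocalories (the analysis reverses
#: the snack change, so a beneficial effect lowers follow-up kcal).
ORIENTATION = {"pa": 1.0, "snack": -1.0, "oha": 1.0, "insulin": 1.0}

#: Baseline covariate marginals emulating the published sample:
#: categorical levels with probabilities (a ``None`` level means missing)
#: and normal (mean, sd, lower clip) for continuous covariates.
COVARIATE_MARGINALS = {
    "gender": ((("female", 0.324), ("male", 0.676)),),
    "education": ((("low", 0.402), ("middle", 0.226), ("high", 0.357), (None, 0.015)),),
    "income": ((("under", 0.272), ("above", 0.500), (None, 0.228)),),
    "living": ((("together", 0.776), ("alone", 0.224)),),
    "work": ((("salaried", 0.433), ("none", 0.155), ("retired", 0.303), ("disabled", 0.109)),),
    "depression": ((("never-past", 0.946), ("current", 0.054)),),
}
_AGE = (60.2, 6.78, 40.0, 70.0)      # truncated normal on the inclusion range
_BMI = (31.0, 5.0, 16.0)
_HBA1C = (56.9, 11.8, 25.0)
_NURSE_PRACTICE_FRACTION = 0.715


@dataclass(frozen=True)
class CohortParams:
    """Parameters of the synthetic trial cohort.

    Defaults reproduce the published trial: ~8 patients per nurse,
    1:1 individual allocation, ICC 0.02 on the composite change,
    intervention-arm baseline moments for the four behaviors, Table-style
    applicability shares (oral-only / insulin-only / both), and dropout
    of 53% (intervention) vs 27.5% (control).
    """

    n_nurses: int = 60
    patients_per_nurse: int = 8
    allocation_ratio: float = 0.5
    icc: float = 0.02
    behavior_baselines: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "pa": (868.0, 1031.0),
            "snack": (1746.0, 1435.0),
            "oha": (13.5, 3.5),
            "insulin": (7.4, 1.8),
        }
    )
    true_effects: Mapping[str, float] = field(
        default_factory=lambda: {b: 0.0 for b in BEHAVIORS}
    )
    applicability: tuple[float, float, float] = (0.615, 0.067, 0.318)
    dropout_rate_by_arm: tuple[float, float] = (0.530, 0.275)
    dropout_mechanism: str = "mcar"  # or "covariate"
    dropout_betas: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    retest_corr: Mapping[str, float] = field(
        default_factory=lambda: {"pa": 0.40, "snack": 0.60, "oha": 0.55, "insulin": 0.55}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nurses < 1:
            raise ParameterError("n_nurses must be >= 1")
        if self.patients_per_nurse < 1:
            raise ParameterError("patients_per_nurse must be >= 1")
        if not 0 < self.allocation_ratio < 1:
            raise ParameterError("allocation_ratio must be in (0, 1)")
        if not 0 <= self.icc < 1:
            raise ParameterError("icc must be in [0, 1)")
        for b in BEHAVIORS:
            if b not in self.behavior_baselines:
                raise ParameterError(f"behavior_baselines missing behavior {b!r}")
            mean, sd = self.behavior_baselines[b]
            if sd <= 0:
                raise ParameterError(f"behavior_baselines[{b!r}]: SD must be > 0")
            if mean <= 0:
                raise ParameterError(f"behavior_baselines[{b!r}]: mean must be > 0")
            if b in SCALE_ITEMS and not 0 < mean < SCALE_ITEMS[b]:
                raise ParameterError(
                    f"behavior_baselines[{b!r}]: mean must lie inside (0, {SCALE_ITEMS[b]})"
                )
            c = self.retest_corr.get(b)
            if c is None or not 0 <= c < 1:
                raise ParameterError(f"retest_corr[{b!r}] must be in [0, 1)")
            if not np.isfinite(self.true_effects.get(b, np.nan)):
                raise ParameterError(f"true_effects[{b!r}] must be finite")
        if abs(sum(self.applicability) - 1.0) > 1e-9 or min(self.applicability) < 0:
            raise ParameterError("applicability fractions must be >= 0 and sum to 1")
        for i, rate in enumerate(self.dropout_rate_by_arm):
            if not 0 <= rate < 1:
                raise ParameterError(f"dropout_rate_by_arm[{i}] must be in [0, 1)")
        if self.dropout_mechanism not in ("mcar", "covariate"):
            raise ParameterError(
                f"dropout_mechanism must be 'mcar' or 'covariate', "
                f"got {self.dropout_mechanism!r}"
            )
        if self.seed < 0:
            raise ParameterError("seed must be a non-negative integer")

    def replace(self, **kwargs) -> "CohortParams":
        return dataclasses.replace(self, **kwargs)


@dataclass
class TrialDataset:
    """Participant x wave table plus item-level responses.

    ``participants`` has one row per participant and wave (covariates
    repeated across waves) with ``retained`` flags; ``scores`` holds the
    generator's behavior scores per participant-wave (ground truth that
    item scoring must reproduce); ``items`` is the long-form response
    table, present unless generation skipped item encoding.
    """

    participants: pd.DataFrame
    scores: Optional[pd.DataFrame] = None
    items: Optional[pd.DataFrame] = None

    def baseline(self) -> pd.DataFrame:
        return self.participants[self.participants["wave"] == "baseline"]

    def followup(self) -> pd.DataFrame:
        return self.participants[self.participants["wave"] == "followup"]

    def meta(self, covariates: bool = False) -> pd.DataFrame:
        """One row per participant: ids, arm, nurse, retention (and
        optionally all baseline covariates)."""
        cols = ["participant_id", "nurse_id", "arm", "retained"]
        if covariates:
            cols += [
                c for c in self.participants.columns
                if c not in cols + ["wave"]
            ]
        return self.baseline()[cols].reset_index(drop=True)

    def analysis_frame(self, covariates: bool = False) -> pd.DataFrame:
        """Scores merged with participant metadata, ready for the
        outcome pipeline."""
        if self.scores is None:
            raise ParameterError("dataset has no scores; score its items first")
        meta = self.meta(covariates=covariates)
        return meta.merge(self.scores, on="participant_id", how="left")

    def validate(self) -> None:
        """Check the structural invariants of the dataset."""
        base = self.baseline().set_index("participant_id")
        fup = self.followup().set_index("participant_id")
        if base.index.duplicated().any():
            raise ParameterError("duplicate baseline rows")
        all_ids = set(self.participants["participant_id"])
        if set(base.index) != all_ids:
            raise ParameterError("every participant needs a baseline row")
        retained = set(base.index[base["retained"]])
        if set(fup.index) != retained:
            raise ParameterError("follow-up rows must exist iff retained")
        nurse_per_pid = self.participants.groupby("participant_id")["nurse_id"].nunique()
        if (nurse_per_pid != 1).any():
            raise ParameterError("each participant must map to exactly one nurse")


# ---------------------------------------------------------------------------
# moment-matched marginals
# ---------------------------------------------------------------------------

class _GammaMarginal:
    """Gamma distribution parameterized by mean and SD (support >= 0)."""

    def __init__(self, mean: float, sd: float):
        if mean <= 0 or sd <= 0:
            raise ParameterError("gamma marginal needs mean > 0 and sd > 0")
        self.mean, self.sd = mean, sd
        self.shape = (mean / sd) ** 2
        self.scale = sd * sd / mean

    def ppf(self, u: np.ndarray) -> np.ndarray:
        return stats.gamma.ppf(u, self.shape, scale=self.scale)


class _BetaBinomMarginal:
    """Beta-binomial on 0..n parameterized by mean and SD."""

    def __init__(self, n: int, mean: float, sd: float):
        p = mean / n
        if not 0 < p < 1:
            raise ParameterError(f"mean {mean} outside the open range (0, {n})")
        npq = n * p * (1 - p)
        var = sd * sd
        if var <= npq:
            raise ParameterError(
                f"SD {sd} too small for a beta-binomial with mean {mean} on 0..{n} "
                f"(needs SD > {np.sqrt(npq):.3f})"
            )
        if var >= n * npq:
            raise ParameterError(f"SD {sd} too large for a beta-binomial on 0..{n}")
        rho = (var / npq - 1.0) / (n - 1.0)
        ab = (1.0 - rho) / rho
        self.n, self.mean, self.sd = n, mean, sd
        self.a, self.b = p * ab, (1 - p) * ab
        pmf = stats.betabinom.pmf(np.arange(n + 1), n, self.a, self.b)
        self._cdf = np.cumsum(pmf)
        self._cdf[-1] = 1.0

    def ppf(self, u: np.ndarray) -> np.ndarray:
        return np.searchsorted(self._cdf, u, side="left").astype(float)


def _marginal(behavior: str, mean: float, sd: float):
    if behavior in SCALE_ITEMS:
        return _BetaBinomMarginal(SCALE_ITEMS[behavior], mean, sd)
    return _GammaMarginal(mean, sd)


# ---------------------------------------------------------------------------
# effect calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Calibration:
    """Native-unit intervention shifts and change-score SDs per behavior."""

    delta: dict[str, float]
    change_sd: dict[str, float]


def _calibrate(params: CohortParams, n_mc: int = 200_000) -> Calibration:
    """Translate standardized effects into native follow-up mean shifts.

    For each behavior, computes the marginal SD of the change score
    implied by the copula (a deterministic internal quadrature with a
    fixed stream, independent of ``params.seed``) and solves the small
    fixed point ``delta = d * sd_change(delta)``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(0xCA11B))
    z0 = rng.standard_normal(n_mc)
    w = rng.standard_normal(n_mc)
    alloc = params.allocation_ratio
    delta: dict[str, float] = {}
    change_sd: dict[str, float] = {}
    for b in BEHAVIORS:
        mean, sd = params.behavior_baselines[b]
        c = params.retest_corr[b]
        z1 = c * z0 + np.sqrt(1.0 - c * c) * w
        u0, u1 = special.ndtr(z0), special.ndtr(z1)
        marg = _marginal(b, mean, sd)
        base = marg.ppf(u0)
        ctrl_delta = marg.ppf(u1) - base
        var_ctrl = ctrl_delta.var()
        d_b = params.true_effects.get(b, 0.0)
        if d_b == 0.0:
            delta[b] = 0.0
            change_sd[b] = float(np.sqrt(var_ctrl))
            continue
        shift = d_b * np.sqrt(var_ctrl)
        sd_pooled = np.sqrt(var_ctrl)
        for _ in range(3):
            marg_int = _marginal(b, mean + ORIENTATION[b] * shift, sd)
            var_int = (marg_int.ppf(u1) - base).var()
            sd_pooled = np.sqrt(alloc * var_int + (1 - alloc) * var_ctrl)
            shift = d_b * sd_pooled
        delta[b] = float(shift)
        change_sd[b] = float(sd_pooled)
    return Calibration(delta=delta, change_sd=change_sd)


def behavior_effects_for_composite(
    d_composite: float, params: CohortParams
) -> dict[str, float]:
    """Equal per-behavior effects that yield a target composite effect.

    The composite D sums the standardized changes of each participant's
    applicable behaviors and is re-standardized by its own pooled SD, so
    a per-behavior effect ``d0`` common to all behaviors produces a
    composite effect of roughly ``d0 * sum_b p_b / sd(C)``, with ``p_b``
    the fraction of participants for whom behavior ``b`` applies and
    ``sd(C)`` following from the applicability mix, the latent
    cross-behavior nurse covariance, and the ICC.  This helper inverts
    that relation (heterogeneity of the effect across applicability
    classes contributes negligibly to ``sd(C)`` and is ignored).
    """
    f_oha, f_ins, f_both = params.applicability
    rho = params.icc
    s = {b: np.sqrt(1.0 - params.retest_corr[b] ** 2) for b in BEHAVIORS}
    classes = (
        (f_oha, ("pa", "snack", "oha")),
        (f_ins, ("pa", "snack", "insulin")),
        (f_both, BEHAVIORS),
    )
    e_var_c = 0.0
    p_b = {b: 0.0 for b in BEHAVIORS}
    for frac, behaviors in classes:
        k = len(behaviors)
        s1 = sum(s[b] for b in behaviors)
        s2 = sum(s[b] ** 2 for b in behaviors)
        a2 = _nurse_loading_sq(rho, k, s1, s2)
        e_var_c += frac * (k + a2 * (s1**2 - s2))
        for b in behaviors:
            p_b[b] += frac
    d0 = d_composite * np.sqrt(e_var_c) / sum(p_b.values())
    return {b: float(d0) for b in BEHAVIORS}


def _nurse_loading_sq(rho: float, k: int, s1: float, s2: float) -> float:
    """Squared nurse loading a^2 making the nurse share of the latent
    composite-change variance equal rho for a participant with the given
    applicable-behavior sums s1 = sum s_b, s2 = sum s_b^2."""
    if rho == 0.0 or s1 == 0.0:
        return 0.0
    a2 = rho * k / (s1**2 * (1.0 - rho) + rho * s2)
    if a2 > 1.0:
        raise ParameterError(
            f"icc {rho} unattainable with the given retest correlations"
        )
    return a2


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _draw_categorical(rng, levels_probs, size):
    levels, probs = zip(*levels_probs)
    idx = rng.choice(len(levels), size=size, p=np.asarray(probs) / sum(probs))
    return np.array([levels[i] for i in idx], dtype=object)


def generate_cohort(
    params: CohortParams,
    items: bool = True,
    calibration: Optional[Calibration] = None,
) -> TrialDataset:
    """Generate a full two-wave trial dataset (all participants retained).

    Set ``items=False`` to skip item-level encoding (scores only), which
    is much faster for simulation studies; pass a precomputed
    ``calibration`` to amortize effect calibration across replicates with
    identical non-seed parameters.

    Apply :func:`apply_dropout` afterwards to impose attrition.
    """
    if calibration is None:
        calibration = _calibrate(params)

    n = params.n_nurses * params.patients_per_nurse
    m = params.patients_per_nurse
    ss = np.random.SeedSequence([int(params.seed), _TAG_STRUCTURE])
    rng = np.random.default_rng(ss)

    participant_id = np.array([f"p{i:05d}" for i in range(n)])
    nurse_index = np.repeat(np.arange(params.n_nurses), m)
    nurse_id = np.array([f"n{j:04d}" for j in nurse_index])

    # individual randomization stratified by nurse: each nurse gets
    # floor(m * ratio) intervention slots plus a Bernoulli remainder
    arm = np.empty(n, dtype=object)
    base_int = int(np.floor(m * params.allocation_ratio))
    frac = m * params.allocation_ratio - base_int
    for j in range(params.n_nurses):
        n_int = base_int + (rng.random() < frac)
        labels = np.array(
            ["intervention"] * n_int + ["control"] * (m - n_int), dtype=object
        )
        arm[j * m:(j + 1) * m] = rng.permutation(labels)

    nurse_type_by_nurse = np.where(
        rng.random(params.n_nurses) < _NURSE_PRACTICE_FRACTION, "practice", "diabetes"
    )
    f_oha, f_ins, f_both = params.applicability
    medication = _draw_categorical(
        rng, (("oha-only", f_oha), ("insulin-only", f_ins), ("both", f_both)), n
    )

    cov = {"medication_type": medication, "nurse_type": nurse_type_by_nurse[nurse_index]}
    for name, (levels_probs,) in COVARIATE_MARGINALS.items():
        cov[name] = _draw_categorical(rng, levels_probs, n)
    mean, sd, lo, hi = _AGE
    a_, b_ = (lo - mean) / sd, (hi - mean) / sd
    cov["age"] = stats.truncnorm.ppf(rng.random(n), a_, b_, loc=mean, scale=sd)
    cov["bmi"] = np.maximum(rng.normal(_BMI[0], _BMI[1], n), _BMI[2])
    cov["hba1c"] = np.maximum(rng.normal(_HBA1C[0], _HBA1C[1], n), _HBA1C[2])

    app = {
        "pa": np.ones(n, dtype=bool),
        "snack": np.ones(n, dtype=bool),
        "oha": np.isin(medication, ("oha-only", "both")),
        "insulin": np.isin(medication, ("insulin-only", "both")),
    }

    # latent scores ---------------------------------------------------------
    rng_lat = np.random.default_rng(np.random.SeedSequence([int(params.seed), _TAG_LATENT]))
    u_nurse = rng_lat.standard_normal(params.n_nurses)[nurse_index]
    s_b = {b: np.sqrt(1.0 - params.retest_corr[b] ** 2) for b in BEHAVIORS}
    s1 = sum(np.where(app[b], s_b[b], 0.0) for b in BEHAVIORS)
    s2 = sum(np.where(app[b], s_b[b] ** 2, 0.0) for b in BEHAVIORS)
    k = sum(app[b].astype(int) for b in BEHAVIORS)
    if params.icc > 0:
        denom = s1**2 * (1.0 - params.icc) + params.icc * s2
        a2 = np.where(s1 > 0, params.icc * k / np.where(denom > 0, denom, 1.0), 0.0)
        if (a2 > 1.0).any():
            raise ParameterError(
                f"icc {params.icc} unattainable with the given retest correlations"
            )
    else:
        a2 = np.zeros(n)
    a = np.sqrt(a2)

    is_int = arm == "intervention"
    base_scores: dict[str, np.ndarray] = {}
    fup_scores: dict[str, np.ndarray] = {}
    for b in BEHAVIORS:
        mean_b, sd_b = params.behavior_baselines[b]
        c = params.retest_corr[b]
        z0 = rng_lat.standard_normal(n)
        w = rng_lat.standard_normal(n)
        eta = a * u_nurse + np.sqrt(1.0 - a2) * w
        z1 = c * z0 + s_b[b] * eta
        marg = _marginal(b, mean_b, sd_b)
        base = marg.ppf(special.ndtr(z0))
        fup = marg.ppf(special.ndtr(z1))
        if calibration.delta[b] != 0.0:
            marg_int = _marginal(
                b, mean_b + ORIENTATION[b] * calibration.delta[b], sd_b
            )
            fup = np.where(is_int, marg_int.ppf(special.ndtr(z1)), fup)
        base_scores[b] = np.where(app[b], base, np.nan)
        fup_scores[b] = np.where(app[b], fup, np.nan)

    def _wave_frame(wave: str, score_dict: dict[str, np.ndarray]) -> pd.DataFrame:
        return pd.DataFrame({
            "participant_id": participant_id,
            "wave": wave,
            **{SCORE_COLUMNS[b]: score_dict[b] for b in BEHAVIORS},
            "oha_flag": False,
            "insulin_flag": False,
        })

    scores = pd.concat(
        [_wave_frame("baseline", base_scores), _wave_frame("followup", fup_scores)],
        ignore_index=True,
    )

    def _participants_wave(wave: str) -> pd.DataFrame:
        return pd.DataFrame({
            "participant_id": participant_id,
            "wave": wave,
            "nurse_id": nurse_id,
            "arm": arm,
            **cov,
            "retained": True,
        })

    participants = pd.concat(
        [_participants_wave("baseline"), _participants_wave("followup")],
        ignore_index=True,
    )

    items_frame = None
    if items:
        rng_items = np.random.default_rng(
            np.random.SeedSequence([int(params.seed), _TAG_ITEMS])
        )
        items_frame = _encode_items(scores, rng_items)

    return TrialDataset(participants=participants, scores=scores, items=items_frame)


def _encode_items(scores: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Emit a long-form item table consistent with the given scores."""
    qualifying = sorted(
        act for act, met in DEFAULT_MET_TABLE.items() if met >= MET_THRESHOLD
    )
    excluded = sorted(
        act for act, met in DEFAULT_MET_TABLE.items() if met < MET_THRESHOLD
    )
    snacks = sorted(DEFAULT_KCAL_TABLE)
    pieces = []

    pid = scores["participant_id"].to_numpy()
    wave = scores["wave"].to_numpy()
    n = len(scores)

    # SQUASH: split PA minutes across two qualifying activities ------------
    pa = scores["pa_min"].to_numpy()
    act_idx = np.argsort(rng.random((n, len(qualifying))), axis=1)[:, :2]
    shares = rng.dirichlet(np.ones(2), size=n)
    days = rng.integers(1, 8, size=(n, 2)).astype(float)
    minutes = np.nan_to_num(pa)[:, None] * shares / days
    rows = []
    for col in range(2):
        acts = np.array(qualifying, dtype=object)[act_idx[:, col]]
        rows.append(pd.DataFrame({
            "participant_id": pid, "wave": wave, "instrument": "squash",
            "item_id": np.char.add(acts.astype(str), ".days"), "value": days[:, col],
        }))
        rows.append(pd.DataFrame({
            "participant_id": pid, "wave": wave, "instrument": "squash",
            "item_id": np.char.add(acts.astype(str), ".min_per_day"),
            "value": minutes[:, col],
        }))
    # occasionally report a sub-threshold activity (excluded from the score)
    has_low = rng.random(n) < 0.3
    low_acts = np.array(excluded, dtype=object)[
        rng.integers(0, len(excluded), size=n)
    ]
    low_days = rng.integers(1, 8, size=n).astype(float)
    low_min = rng.uniform(5, 60, size=n)
    for suffix, vals in ((".days", low_days), (".min_per_day", low_min)):
        rows.append(pd.DataFrame({
            "participant_id": pid[has_low], "wave": wave[has_low],
            "instrument": "squash",
            "item_id": np.char.add(low_acts[has_low].astype(str), suffix),
            "value": vals[has_low],
        }))
    pieces.append(pd.concat(rows, ignore_index=True))

    # FFQ: split kcal across three snacks ----------------------------------
    kcal = scores["snack_kcal"].to_numpy()
    snack_idx = np.argsort(rng.random((n, len(snacks))), axis=1)[:, :3]
    shares3 = rng.dirichlet(np.ones(3), size=n)
    rows = []
    for col in range(3):
        ids = np.array(snacks, dtype=object)[snack_idx[:, col]]
        per_portion = np.array([DEFAULT_KCAL_TABLE[s] for s in ids])
        freq = np.nan_to_num(kcal) * shares3[:, col] / per_portion
        rows.append(pd.DataFrame({
            "participant_id": pid, "wave": wave, "instrument": "ffq",
            "item_id": ids, "value": freq,
        }))
    pieces.append(pd.concat(rows, ignore_index=True))

    # adherence scales: mark `score` randomly chosen items adherent --------
    for instrument, col in (("oha", "oha"), ("insulin", "insulin")):
        n_items = SCALE_ITEMS[instrument]
        vals = scores[col].to_numpy()
        mask = ~np.isnan(vals)
        if not mask.any():
            continue
        sub_n = int(mask.sum())
        ranks = np.argsort(np.argsort(rng.random((sub_n, n_items)), axis=1), axis=1)
        adherent = (ranks < vals[mask].astype(int)[:, None]).astype(float)
        item_ids = np.array([f"item{i + 1:02d}" for i in range(n_items)])
        rows = pd.DataFrame({
            "participant_id": np.repeat(pid[mask], n_items),
            "wave": np.repeat(wave[mask], n_items),
            "instrument": instrument,
            "item_id": np.tile(item_ids, sub_n),
            "value": adherent.ravel(),
        })
        pieces.append(rows)

    out = pd.concat(pieces, ignore_index=True)
    # drop rows for non-applicable instruments (score was NaN)
    nan_pa = set(pid[np.isnan(pa)])
    if nan_pa:
        out = out[~((out["instrument"] == "squash")
                    & out["participant_id"].isin(nan_pa))]
    return out.sort_values(
        ["participant_id", "wave", "instrument", "item_id"]
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# dropout
# ---------------------------------------------------------------------------

#: Numeric covariates usable in the covariate-dependent dropout mechanism
#: (z-scored internally); baseline behavior scores are addressed by their
#: score-column names.
_DROPOUT_NUMERIC = ("age", "bmi", "hba1c", "pa_min", "snack_kcal", "oha", "insulin")


def apply_dropout(data: TrialDataset, params: CohortParams) -> TrialDataset:
    """Impose attrition: flag retention and remove follow-up rows.

    Retention is Bernoulli with per-arm probability ``1 - dropout_rate``
    under the completely-at-random mechanism; under the
    covariate-dependent mechanism the retention probability follows a
    logistic model on z-scored baseline covariates (coefficients per arm
    from ``params.dropout_betas``, keyed ``covariate -> (intervention,
    control)``), with per-arm intercepts solved so the marginal retention
    still matches the target rates.  Zero coefficients therefore reduce
    exactly to the completely-at-random mechanism.
    """
    base = data.baseline().reset_index(drop=True)
    fup_ids = set(data.followup()["participant_id"])
    missing = set(base["participant_id"]) - fup_ids
    if missing:
        raise ParameterError(
            f"{len(missing)} participants lack a follow-up row; dropout must "
            "be applied to a complete two-wave dataset"
        )
    n = len(base)
    rate_int, rate_ctrl = params.dropout_rate_by_arm
    is_int = (base["arm"] == "intervention").to_numpy()
    target = np.where(is_int, 1.0 - rate_int, 1.0 - rate_ctrl)

    rng = np.random.default_rng(
        np.random.SeedSequence([int(params.seed), _TAG_DROPOUT])
    )
    if params.dropout_mechanism == "covariate" and params.dropout_betas:
        merged = base.merge(
            data.scores[data.scores["wave"] == "baseline"],
            on="participant_id", how="left",
        ) if data.scores is not None else base
        eta = np.zeros(n)
        for cov_name, betas in params.dropout_betas.items():
            if cov_name not in merged.columns or cov_name not in _DROPOUT_NUMERIC:
                raise ParameterError(
                    f"dropout_betas: unknown or non-numeric covariate {cov_name!r}"
                )
            vals = merged[cov_name].to_numpy(dtype=float)
            col = np.nan_to_num((vals - np.nanmean(vals)) / np.nanstd(vals))
            beta_int, beta_ctrl = betas
            eta += np.where(is_int, beta_int, beta_ctrl) * col
        prob = np.empty(n)
        for arm_mask, rate in ((is_int, 1.0 - rate_int), (~is_int, 1.0 - rate_ctrl)):
            if not arm_mask.any():
                continue
            sub = eta[arm_mask]
            if np.allclose(sub, 0.0):
                prob[arm_mask] = rate
                continue
            b0 = optimize.brentq(
                lambda b: special.expit(b + sub).mean() - rate, -25.0, 25.0
            )
            prob[arm_mask] = special.expit(b0 + sub)
    else:
        prob = target

    retained = rng.random(n) < prob
    retained_ids = set(base["participant_id"][retained])

    def _filter(frame: Optional[pd.DataFrame]) -> Optional[pd.DataFrame]:
        if frame is None:
            return None
        keep = (frame["wave"] == "baseline") | frame["participant_id"].isin(retained_ids)
        return frame[keep].reset_index(drop=True)

    participants = _filter(data.participants).copy()
    participants["retained"] = participants["participant_id"].isin(retained_ids)
    return TrialDataset(
        participants=participants,
        scores=_filter(data.scores),
        items=_filter(data.items),
    )


def simulate_trial(params: CohortParams, items: bool = True) -> TrialDataset:
    """Generate a cohort and apply its dropout model in one call."""
    return apply_dropout(generate_cohort(params, items=items), params)
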