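"""Questionnaire scoring for the four treatment behaviors.

Each behavior is scored from item-level responses exactly as in the trial
protocol:

* **Physical activity** (SQUASH-style): per activity category the
  respondent reports days/week and average minutes/day.  Activities below
  the moderate-intensity threshold (MET < 3, two categories in the default
  table) are excluded; the score is the cumulative number of weekly
  minutes over the remaining activities.
* **Unhealthy snack intake** (FFQ): weekly portion frequencies per snack
  are translated to kilocalories via a kcal-per-portion table and summed.
* **Oral-medication adherence**: 18 binary items, sum score 0-18, higher
  is better.
* **Insulin adherence**: 9-item adaptation of the same scale, sum 0-9.

The MET and kcal tables are configuration data, not code; the defaults
below are documented stand-ins with plausible values (the per-activity MET
compendium values and the national nutrient database are not bundled) and
should be replaced by a locally validated table for real data.  Every run
should log the table actually used.
"""

from __future__ import annotations

from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ScoringError

#: Default MET value per SQUASH activity category.  Two categories fall
#: below the moderate-intensity threshold of 3 MET and are therefore
#: excluded from the physical-activity score, preserving the instrument's
#: exclusion pathway.
DEFAULT_MET_TABLE: dict[str, float] = {
    "walking": 3.0,
    "cycling": 4.0,
    "gardening": 4.3,
    "odd_jobs": 5.0,
    "sports": 7.0,
    "heavy_housework": 3.5,
    "light_housework": 2.3,   # < 3 MET, excluded
    "standing_work": 2.0,     # < 3 MET, excluded
}

#: Default kilocalories per portion for the unhealthy-snack FFQ.
DEFAULT_KCAL_TABLE: dict[str, float] = {
    "chocolate": 220.0,
    "crisps": 170.0,
    "biscuits": 130.0,
    "cake": 310.0,
    "candy": 90.0,
    "salted_nuts": 190.0,
    "ice_cream": 180.0,
    "savoury_pastry": 270.0,
}

#: MET threshold for "at least moderate" activity; comparison is inclusive
#: (an activity of exactly 3 MET qualifies).
MET_THRESHOLD: float = 3.0

#: Missing-item tolerance for the adherence sum scores: up to this many
#: missing items are scored as non-adherent (and the record flagged);
#: more missing items yield a missing score.
MAX_MISSING_OHA = 2
MAX_MISSING_INSULIN = 1


class ActivityEntry(NamedTuple):
    """One SQUASH activity line: category, days/week, minutes/day."""

    activity_id: str
    days_per_week: int
    daily_duration: float  # minutes


class FfqEntry(NamedTuple):
    """One FFQ line: snack category and weekly portion frequency."""

    snack_id: str
    weekly_frequency: float


def _check_activity(entry: ActivityEntry) -> None:
    if not (0 <= entry.days_per_week <= 7):
        raise ScoringError(
            f"days_per_week must be in [0, 7], got {entry.days_per_week!r} "
            f"for activity {entry.activity_id!r}"
        )
    if not np.isfinite(entry.daily_duration) or entry.daily_duration < 0:
        raise ScoringError(
            f"daily_duration must be finite and >= 0, got "
            f"{entry.daily_duration!r} for activity {entry.activity_id!r}"
        )


def hours_minutes_to_minutes(hours: float, minutes: float) -> float:
    """Normalize an hours+minutes duration entry to minutes."""
    return 60.0 * hours + minutes


def score_squash(
    entries: Iterable[ActivityEntry],
    met: Mapping[str, float] = DEFAULT_MET_TABLE,
    threshold: float = MET_THRESHOLD,
) -> float:
    """Weekly minutes of at-least-moderate physical activity.

    Sums ``days_per_week * daily_duration`` over all entries whose activity
    has MET >= ``threshold``; lower-intensity activities are excluded.

    Raises
    ------
    ScoringError
        If an activity id is absent from the MET table or an entry is
        out of range.
    """
    total = 0.0
    for entry in entries:
        entry = ActivityEntry(*entry)
        _check_activity(entry)
        try:
            met_value = met[entry.activity_id]
        except KeyError:
            raise ScoringError(
                f"unknown activity id {entry.activity_id!r}: not in MET table"
            ) from None
        if met_value >= threshold:
            total += entry.days_per_week * entry.daily_duration
    return total


def score_ffq(
    entries: Iterable[FfqEntry],
    kcal: Mapping[str, float] = DEFAULT_KCAL_TABLE,
) -> float:
    """Weekly kilocalories from unhealthy snacks.

    Sums ``weekly_frequency * kcal_per_portion`` over all entries.
    """
    total = 0.0
    for entry in entries:
        entry = FfqEntry(*entry)
        if not np.isfinite(entry.weekly_frequency) or entry.weekly_frequency < 0:
            raise ScoringError(
                f"weekly_frequency must be finite and >= 0, got "
                f"{entry.weekly_frequency!r} for snack {entry.snack_id!r}"
            )
        try:
            kcal_value = kcal[entry.snack_id]
        except KeyError:
            raise ScoringError(
                f"unknown snack id {entry.snack_id!r}: not in kcal table"
            ) from None
        total += entry.weekly_frequency * kcal_value
    return total


def _score_binary_sum(
    responses: Sequence, n_items: int, max_missing: int, label: str
) -> tuple[Optional[int], bool]:
    responses = list(responses)
    if len(responses) != n_items:
        raise ScoringError(
            f"{label} requires exactly {n_items} item responses, "
            f"got {len(responses)}"
        )
    arr = np.asarray(responses, dtype=float)
    n_missing = int(np.isnan(arr).sum())
    valid = arr[~np.isnan(arr)]
    if not np.isin(valid, (0.0, 1.0)).all():
        raise ScoringError(f"{label} responses must be binary (0/1) or missing")
    if n_missing > max_missing:
        return None, True
    # missing items are conservatively scored as non-adherent
    return int(np.nansum(arr)), n_missing > 0


def score_promas(responses: Sequence) -> tuple[Optional[int], bool]:
    """Oral-medication adherence sum score (0-18).

    ``responses`` holds 18 binary indicators (1 = adherent), with ``nan``
    for missing items.  Up to 2 missing items are scored as non-adherent
    and the record flagged; with more the score is ``None``.

    Returns ``(score, flagged)``.
    """
    return _score_binary_sum(responses, 18, MAX_MISSING_OHA, "oral-adherence scale")


def score_promas_insulin(responses: Sequence) -> tuple[Optional[int], bool]:
    """Insulin adherence sum score (0-9); 9-item twin of :func:`score_promas`
    tolerating at most 1 missing item."""
    return _score_binary_sum(
        responses, 9, MAX_MISSING_INSULIN, "insulin-adherence scale"
    )


# ---------------------------------------------------------------------------
# vectorized scoring of a long-form items table
# ---------------------------------------------------------------------------

def score_items_frame(
    items: pd.DataFrame,
    met: Mapping[str, float] = DEFAULT_MET_TABLE,
    kcal: Mapping[str, float] = DEFAULT_KCAL_TABLE,
    threshold: float = MET_THRESHOLD,
) -> pd.DataFrame:
    """Score a long-form items table into one row per participant x wave.

    ``items`` columns: ``participant_id, wave, instrument, item_id, value``.
    Instruments: ``squash`` (item_id ``<activity>.days`` /
    ``<activity>.min_per_day``), ``ffq`` (item_id = snack id, value =
    portions/week), ``oha`` and ``insulin`` (item_id ``itemNN``, value 0/1
    or missing).

    Returns a frame with columns ``participant_id, wave, pa_min,
    snack_kcal, oha, insulin, oha_flag, insulin_flag``; behaviors whose
    instrument is absent for a participant-wave are ``NaN``.
    """
    required = {"participant_id", "wave", "instrument", "item_id", "value"}
    missing_cols = required - set(items.columns)
    if missing_cols:
        raise ScoringError(f"items table lacks columns: {sorted(missing_cols)}")

    keys = ["participant_id", "wave"]
    pieces: list[pd.DataFrame] = []

    squash = items[items["instrument"] == "squash"]
    if len(squash):
        parts = squash["item_id"].str.rsplit(".", n=1, expand=True)
        squash = squash.assign(activity=parts[0], field=parts[1])
        unknown = set(squash["activity"]) - set(met)
        if unknown:
            raise ScoringError(f"unknown activity id(s) {sorted(unknown)!r}: not in MET table")
        wide = squash.pivot_table(
            index=keys + ["activity"], columns="field", values="value",
            aggfunc="first",
        ).reset_index()
        for col in ("days", "min_per_day"):
            if col not in wide:
                wide[col] = np.nan
        wide["met"] = wide["activity"].map(met)
        qualifying = wide["met"] >= threshold
        wide["minutes"] = np.where(
            qualifying, wide["days"].fillna(0) * wide["min_per_day"].fillna(0), 0.0
        )
        pa = wide.groupby(keys)["minutes"].sum().rename("pa_min")
        pieces.append(pa.to_frame())

    ffq = items[items["instrument"] == "ffq"]
    if len(ffq):
        unknown = set(ffq["item_id"]) - set(kcal)
        if unknown:
            raise ScoringError(f"unknown snack id(s) {sorted(unknown)!r}: not in kcal table")
        ffq = ffq.assign(kcal=ffq["item_id"].map(kcal) * ffq["value"].fillna(0))
        pieces.append(ffq.groupby(keys)["kcal"].sum().rename("snack_kcal").to_frame())

    for instrument, n_items, max_missing in (
        ("oha", 18, MAX_MISSING_OHA),
        ("insulin", 9, MAX_MISSING_INSULIN),
    ):
        sub = items[items["instrument"] == instrument]
        if not len(sub):
            continue
        grp = sub.groupby(keys)["value"]
        counts = grp.size()
        bad = counts[counts != n_items]
        if len(bad):
            raise ScoringError(
                f"{instrument} instrument must have exactly {n_items} items; "
                f"offending keys: {list(bad.index[:5])}"
            )
        n_missing = grp.apply(lambda v: int(v.isna().sum()))
        score = grp.sum(min_count=0)
        score[n_missing > max_missing] = np.nan
        flag = n_missing > 0
        pieces.append(
            pd.DataFrame({instrument: score, f"{instrument}_flag": flag})
        )

    if not pieces:
        return pd.DataFrame(
            columns=["participant_id", "wave", "pa_min", "snack_kcal",
                     "oha", "insulin", "oha_flag", "insulin_flag"]
        )
    out = pd.concat(pieces, axis=1).reset_index()
    for col in ("pa_min", "snack_kcal", "oha", "insulin"):
        if col not in out:
            out[col] = np.nan
    for col in ("oha_flag", "insulin_flag"):
        if col not in out:
            out[col] = False
        else:
            out[col] = out[col].map(lambda v: bool(v) if pd.notna(v) else False)
    return out[
        ["participant_id", "wave", "pa_min", "snack_kcal", "oha", "insulin",
         "oha_flag", "insulin_flag"]
    ]
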