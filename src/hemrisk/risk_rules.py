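"""Three-tier obstetric-hemorrhage risk classification (AWHONN-style rules).

A delivery admission is scored against a fixed list of risk items split into
a medium-risk column and a high-risk column:

* no item triggered                      -> ``low``
* exactly one medium item, no high item  -> ``medium``
* any high item, or two or more medium
  items (the escalation rule)            -> ``high``

The one conditional item is low hematocrit (< 30%), which counts as a high
item only when at least one other risk item — medium or high — is present.

Two entry points are provided: :func:`classify` for a single validated
:class:`RiskFactorProfile`, and :func:`classify_frame` for a whole cohort as
a :class:`pandas.DataFrame` (vectorized; tested for agreement with the
per-record path).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from .thresholds import DEFAULT_THRESHOLDS, Thresholds

LOW = "low"
MEDIUM = "medium"
HIGH = "high"
LEVELS = (LOW, MEDIUM, HIGH)
LEVEL_RANK = {LOW: 0, MEDIUM: 1, HIGH: 2}

#: Medium-column item identifiers, in evaluation order (stable vocabulary).
MEDIUM_ITEMS = (
    "labor_induction",
    "grand_multiparity",          # > 4 prior vaginal births
    "prior_cesarean_or_uterine_incision",
    "large_uterine_fibroids",
    "single_prior_pph",           # history of exactly one prior PPH
    "chorioamnionitis",
    "fetal_demise",
    "morbid_obesity",             # BMI > 35
    "macrosomia",                 # estimated fetal weight > 4 kg
    "family_history_pph",
    "polyhydramnios",
    "multiple_gestation",         # non-singleton pregnancy
)

#: High-column item identifiers, in evaluation order.
HIGH_ITEMS = (
    "active_bleeding",            # more than bloody show
    "suspected_accreta_or_percreta",
    "previa_low_lying",
    "known_coagulopathy",         # known bleeding disorder or coagulopathy
    "recurrent_prior_pph",        # two or more prior PPH
    "thrombocytopenia",           # platelets < 100k/uL
    "hct_low_with_risk_factors",  # hematocrit < 30 AND any other item
)


class RiskFactorProfile(BaseModel):
    """One delivery's admission risk-factor assessment.

    Booleans default to False and nullable numerics to None; a missing
    numeric never triggers its item. ``known_bleeding_disorder`` and
    ``known_coagulopathy`` are treated as synonyms (either triggers the
    high-risk coagulopathy item).
    """

    prior_uterine_incision_or_cesarean: bool = False
    prior_vaginal_births: int = Field(default=0, ge=0)
    known_bleeding_disorder: bool = False
    prior_pph_count: int = Field(default=0, ge=0)
    multiple_gestation: bool = False
    labor_induction: bool = False
    large_uterine_fibroids: bool = False
    chorioamnionitis: bool = False
    fetal_demise: bool = False
    bmi: Optional[float] = Field(default=None, gt=0)
    estimated_fetal_weight: Optional[float] = Field(default=None, gt=0)
    family_history_pph_first_degree: bool = False
    polyhydramnios: bool = False
    active_bleeding_more_than_show: bool = False
    suspected_accreta_or_percreta: bool = False
    placenta_previa_or_low_lying: bool = False
    known_coagulopathy: bool = False
    hematocrit: Optional[float] = Field(default=None, gt=0, le=60)
    platelets: Optional[float] = Field(default=None, ge=0)

    @field_validator("prior_vaginal_births", "prior_pph_count")
    @classmethod
    def _int_counts(cls, v: int) -> int:
        if v != int(v):
            raise ValueError("counts must be integers")
        return int(v)


#: Profile field names in canonical (CSV) order.
PROFILE_FIELDS = tuple(RiskFactorProfile.model_fields)


@dataclass(frozen=True)
class RiskCategory:
    """Classification result: level plus the items that produced it."""

    level: str
    triggered_medium_items: tuple[str, ...] = ()
    triggered_high_items: tuple[str, ...] = ()
    escalated_from_medium: bool = False

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}")


def medium_risk_items(
    profile: RiskFactorProfile, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> list[str]:
    """Return the triggered medium-column items, in vocabulary order."""
    t = thresholds
    checks = {
        "labor_induction": profile.labor_induction,
        "grand_multiparity": profile.prior_vaginal_births
        > t.grand_multiparity_births,
        "prior_cesarean_or_uterine_incision":
            profile.prior_uterine_incision_or_cesarean,
        "large_uterine_fibroids": profile.large_uterine_fibroids,
        "single_prior_pph": profile.prior_pph_count == 1,
        "chorioamnionitis": profile.chorioamnionitis,
        "fetal_demise": profile.fetal_demise,
        "morbid_obesity": profile.bmi is not None
        and profile.bmi > t.bmi_morbid_obesity,
        "macrosomia": profile.estimated_fetal_weight is not None
        and profile.estimated_fetal_weight > t.fetal_weight_kg,
        "family_history_pph": profile.family_history_pph_first_degree,
        "polyhydramnios": profile.polyhydramnios,
        "multiple_gestation": profile.multiple_gestation,
    }
    return [item for item in MEDIUM_ITEMS if checks[item]]


def high_risk_items(
    profile: RiskFactorProfile, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> list[str]:
    """Return the triggered high-column items, in vocabulary order.

    Low hematocrit is conditional: it triggers only when at least one other
    item (medium or unconditional high) is triggered.
    """
    t = thresholds
    checks = {
        "active_bleeding": profile.active_bleeding_more_than_show,
        "suspected_accreta_or_percreta": profile.suspected_accreta_or_percreta,
        "previa_low_lying": profile.placenta_previa_or_low_lying,
        "known_coagulopathy": profile.known_coagulopathy
        or profile.known_bleeding_disorder,
        "recurrent_prior_pph": profile.prior_pph_count >= 2,
        "thrombocytopenia": profile.platelets is not None
        and profile.platelets < t.platelets_per_ul,
    }
    items = [item for item in HIGH_ITEMS if checks.get(item, False)]
    hct_low = (
        profile.hematocrit is not None
        and profile.hematocrit < t.hematocrit_pct
    )
    if hct_low and (items or medium_risk_items(profile, thresholds)):
        items.append("hct_low_with_risk_factors")
    return items


def classify(
    profile: RiskFactorProfile, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> RiskCategory:
    """Classify one delivery as low, medium, or high hemorrhage risk.

    Pure and deterministic. High-column items dominate; otherwise two or
    more medium items escalate to high, exactly one medium item yields
    medium, and no items yield low.
    """
    medium = tuple(medium_risk_items(profile, thresholds))
    high = tuple(high_risk_items(profile, thresholds))
    if high:
        level, escalated = HIGH, False
    elif len(medium) >= 2:
        level, escalated = HIGH, True
    elif len(medium) == 1:
        level, escalated = MEDIUM, False
    else:
        level, escalated = LOW, False
    return RiskCategory(
        level=level,
        triggered_medium_items=medium,
        triggered_high_items=high,
        escalated_from_medium=escalated,
    )


# ---------------------------------------------------------------------------
# Vectorized cohort path
# ---------------------------------------------------------------------------

def _bool_col(df: pd.DataFrame, name: str) -> pd.Series:
    col = df[name]
    if col.dtype == bool:
        return col
    return pd.to_numeric(col, errors="coerce").fillna(0).astype(bool)


def _num_gt(df: pd.DataFrame, name: str, cut: float) -> pd.Series:
    return pd.to_numeric(df[name], errors="coerce").gt(cut).fillna(False)


def _num_lt(df: pd.DataFrame, name: str, cut: float) -> pd.Series:
    return pd.to_numeric(df[name], errors="coerce").lt(cut).fillna(False)


def classify_frame(
    df: pd.DataFrame, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> pd.DataFrame:
    """Classify every row of a cohort frame.

    Parameters
    ----------
    df : DataFrame with the :data:`PROFILE_FIELDS` columns (booleans may be
        0/1 or bool; missing numerics as NaN).

    Returns
    -------
    DataFrame indexed like ``df`` with columns ``level``,
    ``n_medium_items``, ``n_high_items``, ``escalated_from_medium``.
    """
    t = thresholds
    counts = pd.to_numeric(df["prior_vaginal_births"], errors="coerce")
    pph = pd.to_numeric(df["prior_pph_count"], errors="coerce")
    medium = [
        _bool_col(df, "labor_induction"),
        counts.gt(t.grand_multiparity_births).fillna(False),
        _bool_col(df, "prior_uterine_incision_or_cesarean"),
        _bool_col(df, "large_uterine_fibroids"),
        pph.eq(1).fillna(False),
        _bool_col(df, "chorioamnionitis"),
        _bool_col(df, "fetal_demise"),
        _num_gt(df, "bmi", t.bmi_morbid_obesity),
        _num_gt(df, "estimated_fetal_weight", t.fetal_weight_kg),
        _bool_col(df, "family_history_pph_first_degree"),
        _bool_col(df, "polyhydramnios"),
        _bool_col(df, "multiple_gestation"),
    ]
    high = [
        _bool_col(df, "active_bleeding_more_than_show"),
        _bool_col(df, "suspected_accreta_or_percreta"),
        _bool_col(df, "placenta_previa_or_low_lying"),
        _bool_col(df, "known_coagulopathy")
        | _bool_col(df, "known_bleeding_disorder"),
        pph.ge(2).fillna(False),
        _num_lt(df, "platelets", t.platelets_per_ul),
    ]
    n_medium = np.sum([m.to_numpy() for m in medium], axis=0)
    n_high_uncond = np.sum([h.to_numpy() for h in high], axis=0)
    hct_low = _num_lt(df, "hematocrit", t.hematocrit_pct).to_numpy()
    hct_trig = hct_low & ((n_medium + n_high_uncond) > 0)
    n_high = n_high_uncond + hct_trig

    level = np.full(len(df), LOW, dtype=object)
    level[n_medium == 1] = MEDIUM
    level[(n_high > 0) | (n_medium >= 2)] = HIGH
    escalated = (n_high == 0) & (n_medium >= 2)
    return pd.DataFrame(
        {
            "level": level,
            "n_medium_items": n_medium,
            "n_high_items": n_high,
            "escalated_from_medium": escalated,
        },
        index=df.index,
    )
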