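"""Composite hemorrhage-related morbidity from delivery outcome fields.

The composite is the union of four overlapping component indicators:

* ``hemorrhage`` — estimated blood loss >= 1000 mL (inclusive, gravimetric);
* ``transfusion`` — any packed red blood cells (>= 1 unit);
* ``icu`` — ICU admission;
* ``additional_complication`` — hysterectomy or dilation and curettage.

Components overlap freely, so per-component cohort counts are not additive
to the composite count; the composite count is bounded below by the largest
single component count and above by the component sum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd
from pydantic import BaseModel, Field

from .thresholds import DEFAULT_THRESHOLDS, Thresholds

#: Component identifiers in reporting order.
COMPONENTS = ("hemorrhage", "transfusion", "icu", "additional_complication")

#: Outcome field names in canonical (CSV) order.
OUTCOME_FIELDS = (
    "ebl_ml",
    "prbc_units",
    "icu_admission",
    "hysterectomy",
    "dilation_and_curettage",
)


class DeliveryOutcome(BaseModel):
    """Recorded delivery outcomes for one patient.

    ``ebl_ml`` may be missing; a missing EBL contributes no hemorrhage
    component (callers log field-level missingness at ingest).
    """

    ebl_ml: Optional[float] = Field(default=None, ge=0)
    prbc_units: int = Field(default=0, ge=0)
    icu_admission: bool = False
    hysterectomy: bool = False
    dilation_and_curettage: bool = False


@dataclass(frozen=True)
class CompositeResult:
    composite: bool
    components: frozenset[str]

    def __post_init__(self) -> None:
        if self.composite != bool(self.components):
            raise ValueError("composite must equal non-emptiness of components")


def composite_morbidity(
    outcome: DeliveryOutcome, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> CompositeResult:
    """Derive the composite morbidity indicator and its component set."""
    comps = set()
    if (
        outcome.ebl_ml is not None
        and outcome.ebl_ml >= thresholds.ebl_hemorrhage_ml
    ):
        comps.add("hemorrhage")
    if outcome.prbc_units >= 1:
        comps.add("transfusion")
    if outcome.icu_admission:
        comps.add("icu")
    if outcome.hysterectomy or outcome.dilation_and_curettage:
        comps.add("additional_complication")
    return CompositeResult(composite=bool(comps), components=frozenset(comps))


def composite_frame(
    df: pd.DataFrame, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> pd.DataFrame:
    """Vectorized composite scoring for a cohort frame.

    Returns a frame with one boolean column per component plus ``composite``.
    """
    ebl = pd.to_numeric(df["ebl_ml"], errors="coerce")
    units = pd.to_numeric(df["prbc_units"], errors="coerce").fillna(0)

    def _flag(name: str) -> pd.Series:
        col = df[name]
        if col.dtype == bool:
            return col
        return pd.to_numeric(col, errors="coerce").fillna(0).astype(bool)

    out = pd.DataFrame(index=df.index)
    out["hemorrhage"] = ebl.ge(thresholds.ebl_hemorrhage_ml).fillna(False)
    out["transfusion"] = units.ge(1)
    out["icu"] = _flag("icu_admission")
    out["additional_complication"] = _flag("hysterectomy") | _flag(
        "dilation_and_curettage"
    )
    out["composite"] = out[list(COMPONENTS)].any(axis=1)
    return out
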