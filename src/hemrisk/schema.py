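"""Cohort CSV column dictionary.

One row per delivery; header row required; booleans encoded 0/1; missing
numerics as empty cells. Column names match the
:class:`~hemrisk.risk_rules.RiskFactorProfile` and
:class:`~hemrisk.outcomes.DeliveryOutcome` field names exactly. The
dictionary is exportable as JSON (``hemrisk schema``) for downstream tools.
"""

from __future__ import annotations

import json
from pathlib import Path

from .outcomes import OUTCOME_FIELDS
from .risk_rules import PROFILE_FIELDS

_BOOL = {"type": "boolean", "encoding": "0/1", "required": False}


def _count(desc: str) -> dict:
    return {"type": "count", "unit": "", "required": False, "description": desc}


COLUMN_DICTIONARY: dict[str, dict] = {
    # --- risk-factor assessment fields ---
    "prior_uterine_incision_or_cesarean": {
        **_BOOL, "description": "Prior cesarean birth or other uterine incision"},
    "prior_vaginal_births": _count("Number of prior vaginal births"),
    "known_bleeding_disorder": {
        **_BOOL, "description": "Known bleeding disorder (synonym of coagulopathy)"},
    "prior_pph_count": _count("Number of prior postpartum hemorrhages"),
    "multiple_gestation": {**_BOOL, "description": "Non-singleton pregnancy"},
    "labor_induction": {**_BOOL, "description": "Induction of labor"},
    "large_uterine_fibroids": {**_BOOL, "description": "Large uterine fibroids"},
    "chorioamnionitis": {**_BOOL, "description": "Chorioamnionitis"},
    "fetal_demise": {**_BOOL, "description": "Fetal demise"},
    "bmi": {"type": "float", "unit": "kg/m^2", "required": False,
            "description": "Delivery body-mass index (morbid obesity if > 35)"},
    "estimated_fetal_weight": {"type": "float", "unit": "kg", "required": False,
                               "description": "Estimated fetal weight (macrosomia if > 4)"},
    "family_history_pph_first_degree": {
        **_BOOL, "description": "First-degree relative with postpartum hemorrhage"},
    "polyhydramnios": {**_BOOL, "description": "Polyhydramnios"},
    "active_bleeding_more_than_show": {
        **_BOOL, "description": "Active bleeding beyond bloody show"},
    "suspected_accreta_or_percreta": {
        **_BOOL, "description": "Suspected placenta accreta or percreta"},
    "placenta_previa_or_low_lying": {
        **_BOOL, "description": "Placenta previa or low-lying placenta"},
    "known_coagulopathy": {**_BOOL, "description": "Known coagulopathy"},
    "hematocrit": {"type": "float", "unit": "%", "required": False,
                   "description": "Hematocrit (conditional risk item if < 30)"},
    "platelets": {"type": "float", "unit": "/uL", "required": False,
                  "description": "Platelet count (thrombocytopenia if < 100,000)"},
    # --- outcome fields ---
    "ebl_ml": {"type": "float", "unit": "mL", "required": False,
               "description": "Estimated blood loss (hemorrhage if >= 1000)"},
    "prbc_units": _count("Packed red-blood-cell units transfused"),
    "icu_admission": {**_BOOL, "description": "ICU admission"},
    "hysterectomy": {**_BOOL, "description": "Peripartum hysterectomy"},
    "dilation_and_curettage": {**_BOOL, "description": "Dilation and curettage"},
}

ASSESSMENT_COLUMNS = PROFILE_FIELDS
OUTCOME_COLUMNS = OUTCOME_FIELDS
REQUIRED_COLUMNS = tuple(COLUMN_DICTIONARY)


def write_column_dictionary(path: str | Path) -> None:
    """Dump the column dictionary as JSON."""
    Path(path).write_text(json.dumps(COLUMN_DICTIONARY, indent=2) + "\n")
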