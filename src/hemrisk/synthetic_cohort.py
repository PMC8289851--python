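"""Seed-reproducible synthetic delivery cohorts.

Generates per-delivery records — a risk-factor profile, an assigned risk
level, and delivery outcomes — whose group sizes and outcome rates are
calibrated to a published multicenter cohort of 56,903 deliveries screened
with the three-tier hemorrhage risk tool (14,803 low / 26,163 medium /
15,937 high; composite morbidity 330 / 2,084 / 1,898; obstetric hemorrhage
304 / 1,986 / 1,822; transfusion 26 / 109 / 123; ICU 13 / 45 / 41;
hysterectomy or D&C 0 / 2 / 23).

Outcome model per risk level
----------------------------
Hemorrhage (EBL >= 1000 mL) is a Bernoulli draw. The remaining components
are drawn conditionally on hemorrhage status:

* given hemorrhage, transfusion / ICU / additional complication are
  independent Bernoullis;
* given no hemorrhage, at most one of the three occurs (mutually
  exclusive), so the composite union probability is available in closed
  form: ``p_composite = p_hem + (1 - p_hem) * sum(nonhem component probs)``.

:func:`default_spec` solves the conditional probabilities so that every
published marginal count and the composite union are matched in expectation
exactly; :meth:`CohortSpec.expected_counts` returns those analytic values.

Profiles are generated so the rule classifier recovers the assigned level
exactly (no triggering item for low; exactly one medium item for medium;
either a high item or two medium items for high). An optional
misclassification rate flips the *recorded* level away from the rule-implied
one, emulating scoring errors seen in practice; at the default rate of 0 the
round trip is exact.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import SpecValidationError
from .outcomes import COMPONENTS
from .risk_rules import (
    HIGH,
    LEVELS,
    LOW,
    MEDIUM,
    MEDIUM_ITEMS,
    PROFILE_FIELDS,
    RiskFactorProfile,
)

#: Published calibration: group sizes and per-group outcome counts.
CALIBRATION_GROUP_SIZES: dict[str, int] = {LOW: 14_803, MEDIUM: 26_163, HIGH: 15_937}
CALIBRATION_COUNTS: dict[str, dict[str, int]] = {
    "composite": {LOW: 330, MEDIUM: 2_084, HIGH: 1_898},
    "hemorrhage": {LOW: 304, MEDIUM: 1_986, HIGH: 1_822},
    "transfusion": {LOW: 26, MEDIUM: 109, HIGH: 123},
    "icu": {LOW: 13, MEDIUM: 45, HIGH: 41},
    "additional_complication": {LOW: 0, MEDIUM: 2, HIGH: 23},
}

_OVERLAP_COMPONENTS = ("transfusion", "icu", "additional_complication")

#: Sampling weights for which single medium item a medium-risk profile
#: carries (roughly: inductions and prior cesareans dominate in practice).
MEDIUM_ITEM_WEIGHTS: dict[str, float] = {
    "labor_induction": 0.35,
    "prior_cesarean_or_uterine_incision": 0.20,
    "morbid_obesity": 0.15,
    "macrosomia": 0.06,
    "chorioamnionitis": 0.05,
    "grand_multiparity": 0.04,
    "single_prior_pph": 0.04,
    "multiple_gestation": 0.04,
    "polyhydramnios": 0.03,
    "family_history_pph": 0.02,
    "large_uterine_fibroids": 0.015,
    "fetal_demise": 0.005,
}

#: Weights for which high item a directly-high profile carries. The
#: conditional low-hematocrit item is included; when drawn, one medium item
#: is added so the conditional rule fires.
HIGH_ITEM_WEIGHTS: dict[str, float] = {
    "thrombocytopenia": 0.26,
    "recurrent_prior_pph": 0.25,
    "previa_low_lying": 0.22,
    "hct_low_with_risk_factors": 0.10,
    "known_coagulopathy": 0.08,
    "active_bleeding": 0.05,
    "suspected_accreta_or_percreta": 0.04,
}

#: Probability a high-risk profile carries a direct high item rather than
#: escalating from two medium items.
DIRECT_HIGH_FRACTION = 0.6

_MISSING_FRACTION = 0.05  # nullable numerics left unrecorded at this rate


class ComponentModel(BaseModel):
    """Per-level outcome probabilities (see module docstring for the model)."""

    model_config = ConfigDict(frozen=True)

    hemorrhage: float = Field(ge=0, le=1)
    #: P(component | no hemorrhage); mutually exclusive, so the sum must be <= 1.
    nonhem: dict[str, float]
    #: P(component | hemorrhage); independent Bernoullis.
    given_hem: dict[str, float]

    @model_validator(mode="after")
    def _check(self) -> "ComponentModel":
        for m in (self.nonhem, self.given_hem):
            if set(m) != set(_OVERLAP_COMPONENTS):
                raise ValueError(f"component maps must have keys {_OVERLAP_COMPONENTS}")
            if any(not 0 <= v <= 1 for v in m.values()):
                raise ValueError("component probabilities must be in [0, 1]")
        if sum(self.nonhem.values()) > 1 + 1e-12:
            raise ValueError("non-hemorrhage component probabilities exceed 1")
        return self

    @property
    def union_probability(self) -> float:
        """Closed-form P(composite) implied by the model."""
        return self.hemorrhage + (1 - self.hemorrhage) * sum(self.nonhem.values())


class CohortSpec(BaseModel):
    """Generator parameters for one synthetic cohort."""

    model_config = ConfigDict(frozen=True)

    group_sizes: dict[str, int]
    composite_prob: dict[str, float]
    component_model: dict[str, ComponentModel]
    misclassification_rate: float = Field(default=0.0, ge=0, le=1)
    seed: int = 0

    @model_validator(mode="after")
    def _validate(self) -> "CohortSpec":
        problems = []
        for m in (self.group_sizes, self.composite_prob, self.component_model):
            if set(m) != set(LEVELS):
                problems.append(f"mappings must be keyed by {LEVELS}, got {sorted(m)}")
        if not problems:
            for g, n in self.group_sizes.items():
                if n < 0:
                    problems.append(f"group size for {g} is negative")
            for g, p in self.composite_prob.items():
                if not 0 <= p <= 1:
                    problems.append(f"composite probability for {g} not in [0, 1]")
                implied = self.component_model[g].union_probability
                if abs(implied - p) > 1e-9:
                    problems.append(
                        f"{g}: component model implies union {implied:.6g} "
                        f"but composite_prob is {p:.6g}"
                    )
        if problems:
            raise SpecValidationError("; ".join(problems))
        return self

    def expected_counts(self) -> dict[str, dict[str, float]]:
        """Analytic expected per-level counts for the composite and components."""
        out: dict[str, dict[str, float]] = {
            k: {} for k in ("composite",) + COMPONENTS
        }
        for g in LEVELS:
            n = self.group_sizes[g]
            cm = self.component_model[g]
            out["composite"][g] = n * cm.union_probability
            out["hemorrhage"][g] = n * cm.hemorrhage
            for comp in _OVERLAP_COMPONENTS:
                out[comp][g] = n * (
                    cm.hemorrhage * cm.given_hem[comp]
                    + (1 - cm.hemorrhage) * cm.nonhem[comp]
                )
        return out


def _solve_component_model(
    n: int, counts: Mapping[str, int]
) -> ComponentModel:
    """Solve conditional component probabilities from marginal counts.

    The non-hemorrhage composite excess ``c - h`` is allocated across the
    three overlap components proportionally to their marginal counts; the
    remainder of each marginal is placed on hemorrhage-positive records.
    """
    h = counts["hemorrhage"]
    c = counts["composite"]
    excess = c - h
    if excess < 0:
        raise SpecValidationError("composite count below hemorrhage count")
    marg = {comp: counts[comp] for comp in _OVERLAP_COMPONENTS}
    total_marg = sum(marg.values())
    nonhem_counts = {
        comp: (excess * m / total_marg if total_marg else 0.0)
        for comp, m in marg.items()
    }
    nonhem = {
        comp: (cnt / (n - h) if n > h else 0.0)
        for comp, cnt in nonhem_counts.items()
    }
    given_hem = {
        comp: ((marg[comp] - nonhem_counts[comp]) / h if h else 0.0)
        for comp in _OVERLAP_COMPONENTS
    }
    return ComponentModel(hemorrhage=h / n if n else 0.0, nonhem=nonhem, given_hem=given_hem)


def default_spec(seed: int = 0, misclassification_rate: float = 0.0) -> CohortSpec:
    """The cohort spec calibrated to the published group sizes and rates."""
    sizes = dict(CALIBRATION_GROUP_SIZES)
    model = {}
    composite_prob = {}
    for g in LEVELS:
        counts = {k: CALIBRATION_COUNTS[k][g] for k in CALIBRATION_COUNTS}
        model[g] = _solve_component_model(sizes[g], counts)
        composite_prob[g] = counts["composite"] / sizes[g]
    return CohortSpec(
        group_sizes=sizes,
        composite_prob=composite_prob,
        component_model=model,
        misclassification_rate=misclassification_rate,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Profile generation
# ---------------------------------------------------------------------------

def _base_profiles(n: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Non-triggering baseline for every profile field."""
    cols: dict[str, np.ndarray] = {}
    for f in PROFILE_FIELDS:
        cols[f] = np.zeros(n, dtype=object)
    for f in (
        "prior_uterine_incision_or_cesarean", "known_bleeding_disorder",
        "multiple_gestation", "labor_induction", "large_uterine_fibroids",
        "chorioamnionitis", "fetal_demise", "family_history_pph_first_degree",
        "polyhydramnios", "active_bleeding_more_than_show",
        "suspected_accreta_or_percreta", "placenta_previa_or_low_lying",
        "known_coagulopathy",
    ):
        cols[f] = np.zeros(n, dtype=bool)
    cols["prior_vaginal_births"] = rng.integers(0, 5, size=n)
    cols["prior_pph_count"] = np.zeros(n, dtype=np.int64)
    cols["bmi"] = np.clip(rng.normal(29.0, 4.0, size=n), 17.0, 35.0).round(1)
    cols["estimated_fetal_weight"] = np.clip(
        rng.normal(3.3, 0.45, size=n), 1.5, 4.0
    ).round(2)
    cols["hematocrit"] = np.clip(rng.normal(34.0, 2.5, size=n), 30.0, 45.0).round(1)
    cols["platelets"] = np.clip(
        rng.normal(230_000, 60_000, size=n), 100_000, 450_000
    ).round(-3)
    for f in ("bmi", "estimated_fetal_weight", "hematocrit", "platelets"):
        miss = rng.random(n) < _MISSING_FRACTION
        vals = cols[f].astype(float)
        vals[miss] = np.nan
        cols[f] = vals
    return cols


def _apply_medium_item(
    cols: dict[str, np.ndarray], item: str, idx: np.ndarray, rng: np.random.Generator
) -> None:
    n = len(idx)
    if n == 0:
        return
    if item == "labor_induction":
        cols["labor_induction"][idx] = True
    elif item == "grand_multiparity":
        cols["prior_vaginal_births"][idx] = rng.integers(5, 9, size=n)
    elif item == "prior_cesarean_or_uterine_incision":
        cols["prior_uterine_incision_or_cesarean"][idx] = True
    elif item == "large_uterine_fibroids":
        cols["large_uterine_fibroids"][idx] = True
    elif item == "single_prior_pph":
        cols["prior_pph_count"][idx] = 1
    elif item == "chorioamnionitis":
        cols["chorioamnionitis"][idx] = True
    elif item == "fetal_demise":
        cols["fetal_demise"][idx] = True
    elif item == "morbid_obesity":
        cols["bmi"][idx] = (35.0 + rng.uniform(0.5, 12.0, size=n)).round(1)
    elif item == "macrosomia":
        cols["estimated_fetal_weight"][idx] = (
            4.0 + rng.uniform(0.05, 0.9, size=n)
        ).round(2)
    elif item == "family_history_pph":
        cols["family_history_pph_first_degree"][idx] = True
    elif item == "polyhydramnios":
        cols["polyhydramnios"][idx] = True
    elif item == "multiple_gestation":
        cols["multiple_gestation"][idx] = True
    else:  # pragma: no cover - guarded by the weight tables
        raise ValueError(f"unknown medium item {item!r}")


def _apply_high_item(
    cols: dict[str, np.ndarray], item: str, idx: np.ndarray, rng: np.random.Generator
) -> None:
    n = len(idx)
    if n == 0:
        return
    if item == "active_bleeding":
        cols["active_bleeding_more_than_show"][idx] = True
    elif item == "suspected_accreta_or_percreta":
        cols["suspected_accreta_or_percreta"][idx] = True
    elif item == "previa_low_lying":
        cols["placenta_previa_or_low_lying"][idx] = True
    elif item == "known_coagulopathy":
        cols["known_coagulopathy"][idx] = True
    elif item == "recurrent_prior_pph":
        cols["prior_pph_count"][idx] = rng.integers(2, 4, size=n)
    elif item == "thrombocytopenia":
        cols["platelets"][idx] = (rng.uniform(40_000, 95_000, size=n)).round(-3)
    elif item == "hct_low_with_risk_factors":
        cols["hematocrit"][idx] = rng.uniform(22.0, 29.5, size=n).round(1)
        # conditional item: pair with one medium item so the rule fires
        partners = rng.choice(
            list(MEDIUM_ITEM_WEIGHTS), size=n, p=_weights(MEDIUM_ITEM_WEIGHTS)
        )
        for partner in np.unique(partners):
            _apply_medium_item(cols, partner, idx[partners == partner], rng)
    else:  # pragma: no cover
        raise ValueError(f"unknown high item {item!r}")


def _weights(table: Mapping[str, float]) -> np.ndarray:
    w = np.array(list(table.values()), dtype=float)
    return w / w.sum()


def generate_profiles(
    level: str, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Generate ``n`` profiles whose rule-implied level is ``level``."""
    if level not in LEVELS:
        raise ValueError(f"unknown level {level!r}")
    cols = _base_profiles(n, rng)
    all_idx = np.arange(n)
    if level == MEDIUM:
        items = rng.choice(
            list(MEDIUM_ITEM_WEIGHTS), size=n, p=_weights(MEDIUM_ITEM_WEIGHTS)
        )
        for item in np.unique(items):
            _apply_medium_item(cols, item, all_idx[items == item], rng)
    elif level == HIGH:
        direct = rng.random(n) < DIRECT_HIGH_FRACTION
        items = rng.choice(
            list(HIGH_ITEM_WEIGHTS), size=n, p=_weights(HIGH_ITEM_WEIGHTS)
        )
        for item in np.unique(items):
            _apply_high_item(cols, item, all_idx[direct & (items == item)], rng)
        # escalation branch: two distinct medium items (Gumbel top-2 trick)
        esc_idx = all_idx[~direct]
        if len(esc_idx):
            names = list(MEDIUM_ITEM_WEIGHTS)
            logw = np.log(_weights(MEDIUM_ITEM_WEIGHTS))
            gumbel = rng.gumbel(size=(len(esc_idx), len(names)))
            top2 = np.argsort(logw[None, :] + gumbel, axis=1)[:, -2:]
            for j, item in enumerate(names):
                for k in (0, 1):
                    sel = esc_idx[top2[:, k] == j]
                    _apply_medium_item(cols, item, sel, rng)
    return pd.DataFrame({f: cols[f] for f in PROFILE_FIELDS})


def generate_profile(level: str, rng: np.random.Generator) -> RiskFactorProfile:
    """Single-record convenience wrapper around :func:`generate_profiles`."""
    row = generate_profiles(level, 1, rng).iloc[0]
    data = {
        k: (None if isinstance(v, float) and math.isnan(v) else v)
        for k, v in row.items()
    }
    for k in ("prior_vaginal_births", "prior_pph_count"):
        data[k] = int(data[k])
    return RiskFactorProfile(**data)


# ---------------------------------------------------------------------------
# Outcome generation and cohort assembly
# ---------------------------------------------------------------------------

# EBL magnitude distributions: log-normal bodies on either side of the
# 1000 mL hemorrhage threshold. Shapes are cosmetic — any distribution
# supported on the correct side of the threshold gives identical composite
# and component rates.
_EBL_NONHEM = dict(mean=math.log(300.0), sigma=0.55, cap=999.0)
_EBL_HEM = dict(mean=math.log(350.0), sigma=0.8, floor=1000.0)


def _generate_outcomes(
    cm: ComponentModel, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    hem = rng.random(n) < cm.hemorrhage
    ebl = np.empty(n)
    n_hem = int(hem.sum())
    ebl[hem] = _EBL_HEM["floor"] + np.round(
        rng.lognormal(_EBL_HEM["mean"], _EBL_HEM["sigma"], size=n_hem)
    )
    ebl[~hem] = np.minimum(
        np.round(rng.lognormal(_EBL_NONHEM["mean"], _EBL_NONHEM["sigma"], size=n - n_hem)),
        _EBL_NONHEM["cap"],
    )
    transfusion = np.zeros(n, dtype=bool)
    icu = np.zeros(n, dtype=bool)
    additional = np.zeros(n, dtype=bool)
    # given hemorrhage: independent Bernoullis
    for comp, arr in (("transfusion", transfusion), ("icu", icu),
                      ("additional_complication", additional)):
        arr[hem] = rng.random(n_hem) < cm.given_hem[comp]
    # given no hemorrhage: at most one component (categorical draw)
    u = rng.random(n - n_hem)
    p_t = cm.nonhem["transfusion"]
    p_i = cm.nonhem["icu"]
    p_a = cm.nonhem["additional_complication"]
    transfusion[~hem] = u < p_t
    icu[~hem] = (u >= p_t) & (u < p_t + p_i)
    additional[~hem] = (u >= p_t + p_i) & (u < p_t + p_i + p_a)

    units = np.zeros(n, dtype=np.int64)
    units[transfusion] = 1 + rng.poisson(0.7, size=int(transfusion.sum()))
    # split additional complications between hysterectomy and D&C
    hyst = np.zeros(n, dtype=bool)
    dnc = np.zeros(n, dtype=bool)
    which = rng.random(n) < 0.3
    hyst[additional & which] = True
    dnc[additional & ~which] = True
    return pd.DataFrame(
        {
            "ebl_ml": ebl,
            "prbc_units": units,
            "icu_admission": icu,
            "hysterectomy": hyst,
            "dilation_and_curettage": dnc,
        }
    )


def generate(spec: CohortSpec) -> pd.DataFrame:
    """Generate a full synthetic cohort frame.

    Returns a DataFrame with the profile columns, the outcome columns, and a
    ``recorded_level`` column (the level documented for the delivery, which
    differs from the rule-implied level with probability
    ``spec.misclassification_rate``). Rows are grouped by rule-implied level
    in low / medium / high order; output is fully determined by the spec,
    including its seed.
    """
    root = np.random.SeedSequence(spec.seed)
    # fixed stage layout so adding stages later does not perturb earlier draws
    streams = {
        (g, stage): np.random.default_rng(child)
        for (g, stage), child in zip(
            [(g, s) for g in LEVELS for s in ("profile", "outcome", "label")],
            root.spawn(3 * len(LEVELS)),
        )
    }
    frames = []
    for g in LEVELS:
        n = spec.group_sizes[g]
        profiles = generate_profiles(g, n, streams[(g, "profile")])
        outcomes = _generate_outcomes(
            spec.component_model[g], n, streams[(g, "outcome")]
        )
        recorded = np.full(n, g, dtype=object)
        r = spec.misclassification_rate
        if r > 0:
            rng = streams[(g, "label")]
            flip = rng.random(n) < r
            others = [lv for lv in LEVELS if lv != g]
            choice = rng.integers(0, 2, size=n)
            recorded[flip] = np.where(
                choice[flip] == 0, others[0], others[1]
            )
        block = pd.concat([profiles, outcomes], axis=1)
        block["recorded_level"] = recorded
        frames.append(block)
    cohort = pd.concat(frames, ignore_index=True)
    return cohort


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    """Write a cohort frame in the ingest CSV schema (booleans as 0/1)."""
    out = cohort.copy()
    for col in out.columns:
        if out[col].dtype == bool:
            out[col] = out[col].astype(int)
    out.to_csv(path, index=False)


def roundtrip_agreement(cohort: pd.DataFrame) -> float:
    """Fraction of records whose rule-implied level equals ``recorded_level``."""
    from .risk_rules import classify_frame

    implied = classify_frame(cohort)["level"].to_numpy()
    return float((implied == cohort["recorded_level"].to_numpy()).mean())
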