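"""Independent brute-force oracles for cross-checking the implementation.

These deliberately avoid the package's rule tables: each works directly off
raw field values with its own flat logic, so agreement with the package is a
genuine dual-route check.
"""

from __future__ import annotations


def brute_force_level(fields: dict) -> str:
    """Count triggered items from raw field values; apply the two rules.

    Independent re-derivation of the three-tier classification: any
    unconditional high item -> high; low hematocrit counts as high only
    alongside another item; two or more medium items -> high; one -> medium.
    """
    g = fields.get
    n_medium = sum(
        [
            bool(g("labor_induction")),
            (g("prior_vaginal_births") or 0) > 4,
            bool(g("prior_uterine_incision_or_cesarean")),
            bool(g("large_uterine_fibroids")),
            (g("prior_pph_count") or 0) == 1,
            bool(g("chorioamnionitis")),
            bool(g("fetal_demise")),
            g("bmi") is not None and g("bmi") > 35,
            g("estimated_fetal_weight") is not None
            and g("estimated_fetal_weight") > 4,
            bool(g("family_history_pph_first_degree")),
            bool(g("polyhydramnios")),
            bool(g("multiple_gestation")),
        ]
    )
    n_high = sum(
        [
            bool(g("active_bleeding_more_than_show")),
            bool(g("suspected_accreta_or_percreta")),
            bool(g("placenta_previa_or_low_lying")),
            bool(g("known_coagulopathy")) or bool(g("known_bleeding_disorder")),
            (g("prior_pph_count") or 0) >= 2,
            g("platelets") is not None and g("platelets") < 100_000,
        ]
    )
    if (
        g("hematocrit") is not None
        and g("hematocrit") < 30
        and (n_medium + n_high) > 0
    ):
        n_high += 1
    if n_high > 0 or n_medium >= 2:
        return "high"
    if n_medium == 1:
        return "medium"
    return "low"


def brute_force_table(records: list[tuple[str, bool]], positive: set[str]):
    """Accumulate the 2x2 contrast cell counts one record at a time."""
    tp = fp = fn = tn = 0
    for level, event in records:
        if level in positive:
            if event:
                tp += 1
            else:
                fp += 1
        elif level == "low":
            if event:
                fn += 1
            else:
                tn += 1
    return tp, fp, fn, tn
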