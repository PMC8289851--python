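import numpy as np
import pytest

from hemrisk.diagnostics import ContingencyTable2x2
from hemrisk.risk_rules import PROFILE_FIELDS

# Published per-group totals used as count-level inputs throughout the suite.
GROUP_SIZES = {"low": 14_803, "medium": 26_163, "high": 15_937}
OUTCOME_COUNTS = {
    "composite": {"low": 330, "medium": 2_084, "high": 1_898},
    "hemorrhage": {"low": 304, "medium": 1_986, "high": 1_822},
    "transfusion": {"low": 26, "medium": 109, "high": 123},
    "icu": {"low": 13, "medium": 45, "high": 41},
    "additional_complication": {"low": 0, "medium": 2, "high": 23},
}

#: The combined medium+high vs low 2x2 table implied by the totals above.
COMBINED_TABLE = ContingencyTable2x2(tp=3_982, fp=38_118, fn=330, tn=14_473)


@pytest.fixture
def combined_table():
    return COMBINED_TABLE


def random_profile_fields(rng: np.random.Generator) -> dict:
    """A random raw profile dict spanning both sides of every threshold."""
    fields: dict = {}
    bool_fields = [
        f for f in PROFILE_FIELDS
        if f not in (
            "prior_vaginal_births", "prior_pph_count", "bmi",
            "estimated_fetal_weight", "hematocrit", "platelets",
        )
    ]
    for f in bool_fields:
        fields[f] = bool(rng.random() < 0.15)
    fields["prior_vaginal_births"] = int(rng.integers(0, 8))
    fields["prior_pph_count"] = int(rng.integers(0, 4))
    fields["bmi"] = None if rng.random() < 0.3 else float(rng.uniform(18, 50))
    fields["estimated_fetal_weight"] = (
        None if rng.random() < 0.3 else float(rng.uniform(2.0, 5.0))
    )
    fields["hematocrit"] = None if rng.random() < 0.3 else float(rng.uniform(22, 45))
    fields["platelets"] = (
        None if rng.random() < 0.3 else float(rng.uniform(50_000, 400_000))
    )
    return fields
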