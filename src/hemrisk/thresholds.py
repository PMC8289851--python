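"""Clinical thresholds used throughout the package.

Every cut-point that turns a numeric field into a risk item or an outcome
component lives here, with the published values as immutable defaults.
All inequalities are strict in the printed direction except the hemorrhage
EBL threshold, which is inclusive (EBL >= 1000 mL counts as hemorrhage).
"""

from dataclasses import dataclass


@dataclass(frozen=True)
class Thresholds:
    """Cut-points for risk-item triggers and outcome components.

    Attributes
    ----------
    ebl_hemorrhage_ml : float
        Estimated blood loss at or above which a delivery counts as an
        obstetric hemorrhage (gravimetric method). Inclusive.
    bmi_morbid_obesity : float
        BMI above which "morbid obesity" triggers (strict >), kg/m^2.
    fetal_weight_kg : float
        Estimated fetal weight above which macrosomia triggers (strict >).
    platelets_per_ul : float
        Platelet count below which thrombocytopenia triggers (strict <).
    hematocrit_pct : float
        Hematocrit below which the conditional anemia item triggers
        (strict <; only counts when another risk item is present).
    grand_multiparity_births : int
        Prior vaginal births above which grand multiparity triggers
        (strict >; exactly this many does not trigger).
    alpha : float
        Default two-sided significance level for confidence intervals.
    """

    ebl_hemorrhage_ml: float = 1000.0
    bmi_morbid_obesity: float = 35.0
    fetal_weight_kg: float = 4.0
    platelets_per_ul: float = 100_000.0
    hematocrit_pct: float = 30.0
    grand_multiparity_births: int = 4
    alpha: float = 0.05


DEFAULT_THRESHOLDS = Thresholds()
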