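# Methods

## The screening model

`hemrisk` analyses a three-tier, rule-based hemorrhage risk assessment of
delivery admissions as a screening test for composite hemorrhage-related
maternal morbidity. The classification is purely deterministic:

* **high** — any high-column item is present, or two or more medium-column
  items co-occur (the escalation rule);
* **medium** — exactly one medium item and no high item;
* **low** — no item at all.

Rule conventions where the checklist's prose leaves room:

* High items are unconditional and dominate: a patient with placenta previa
  plus two medium items is high *by the previa*, not by escalation (the
  `escalated_from_medium` flag is only set when no high item fired).
* "Hematocrit < 30 **and other risk factors**" is the single conditional
  item: low hematocrit counts as a high item only when at least one other
  item (medium or high) is triggered. On its own it leaves the patient low
  risk. This preserves monotonicity: adding any item never lowers the level.
* "No known bleeding disorder" (a low-column entry) and "known coagulopathy"
  (a high-column entry) are treated as one boolean pair; either field
  triggers the same high item, since no operational distinction exists
  between them.
* Non-singleton pregnancy is counted as a medium item: singleton status is a
  low-column requirement, and a medium weight is the only placement that
  lets it break low-eligibility without jumping straight to high.
* All numeric cut-points are strict in their printed direction
  (BMI > 35, EFW > 4 kg, platelets < 100,000/µL, hematocrit < 30,
  prior vaginal births > 4); a missing numeric never triggers its item.
* A record with *every* assessment field missing cannot be scored and is
  excluded at ingest; partial missingness is only logged.

## Composite morbidity

The outcome is the union of four overlapping indicators: obstetric
hemorrhage (EBL ≥ 1000 mL by the gravimetric method — inclusive), any pRBC
transfusion (≥ 1 unit, any timing), ICU admission, and a hemorrhage-related
procedure (hysterectomy or dilation and curettage). Because components
overlap, cohort reports show both raw per-component counts and the union;
per-component counts are not additive to the composite.

## Diagnostics

For each contrast (medium vs low, high vs low, medium+high vs low) the
elevated group(s) are test-positive and the low group is the referent;
records in the omitted third group are dropped from that table, not pooled.
From the 2×2 counts: sensitivity TP/(TP+FN), specificity TN/(FP+TN),
PPV TP/(TP+FP), NPV TN/(FN+TN), and the cross-product diagnostic odds ratio
with a Woolf (log-normal) confidence interval using
z₀.₉₇₅ = 1.959964. We deliberately report an odds ratio, not a risk ratio:
the two are sometimes conflated in clinical reporting, and for these data
the published point estimates are cross-product odds ratios (the combined
contrast's risk ratio would be ≈ 4.24, its odds ratio 4.58). Similarly, the
combined-contrast PPV is reported at full precision (0.0946 ≈ 9%); a
published display rounding of 0.10 is not matched.

Numerical choices: statistics are computed at full precision and rounded
only for display (2 dp for diagnostics, 1 dp for percentages); when any cell
is zero the Haldane–Anscombe correction adds 0.5 to all four cells before
the odds ratio and interval are computed and the output is flagged; a zero
denominator raises an error naming the statistic; exact conditional
intervals are not implemented — Woolf reproduces the published intervals
and is standard for tables of this size.

## Synthetic cohort generator

The generator emulates the published 56,903-delivery multicenter cohort at
the level the printed tables permit: group sizes (14,803 / 26,163 / 15,937),
per-group hemorrhage probabilities (304/14803, 1986/26163, 1822/15937), and
per-group marginal counts for transfusion (26/109/123), ICU (13/45/41), and
additional complications (0/2/23), with composite unions of 330/2084/1898.

**Overlap model.** Joint component counts are not published, so the
generator parameterizes overlap as: hemorrhage is Bernoulli; given
hemorrhage, the other three components are independent Bernoullis; given no
hemorrhage, at most one of the three occurs (mutually exclusive). The
non-hemorrhage composite excess (composite − hemorrhage) is allocated across
components proportionally to their marginal counts, and the
hemorrhage-conditional probabilities absorb the remainder. Under this
model every printed marginal and the composite union are matched in
expectation *exactly* (`CohortSpec.expected_counts()` returns the analytic
values; the suite asserts equality with the calibration counts). The solved
conditionals are documented constants of the generator, not claims about the
real cohort's joint distribution.

**Profiles.** Each record's risk-factor profile is generated to round-trip
through the classifier: low profiles trigger nothing; medium profiles carry
exactly one medium item drawn from a documented weight table (inductions and
prior cesareans weighted heaviest, matching their dominance among risk
factors in practice); high profiles carry a direct high item with
probability 0.6 or two distinct medium items otherwise (weighted sampling
without replacement via the Gumbel-top-k trick); the conditional
low-hematocrit item is always paired with one medium item so the rule fires.
Baseline numerics are drawn from plausible clipped-normal bodies that cannot
cross their thresholds, with 5% of nullable labs left unrecorded.

**EBL magnitudes.** Blood loss is log-normal on either side of the 1000 mL
threshold (median ≈ 300 mL capped at 999 for non-hemorrhage; 1000 mL plus a
log-normal tail for hemorrhage). The shapes are cosmetic: any distribution
supported on the correct side of the threshold leaves every rate and
diagnostic unchanged.

**Misclassification.** An optional rate flips the *recorded* level away from
the rule-implied one (uniformly to one of the other two levels), emulating
scoring errors observed in real deployments; the default is 0, at which the
classifier recovers every assigned level exactly (asserted over full
cohorts). The pipeline re-derives levels from the rules by default and uses
the recorded column only behind `--use-recorded-level`.

**Seeding.** One integer master seed is split with `numpy.random.
SeedSequence.spawn` into per-level, per-stage streams (profile / outcome /
label) in a fixed layout, so identical spec + seed gives byte-identical CSV
output and adding a stage later would not perturb earlier draws.

**What the generator does not emulate.** Covariate correlations, hospital
clustering (the real cohort spans 19 sites), transfusion timing, and any
joint structure beyond the overlap model above. Tests passing on synthetic
cohorts therefore validate the pipeline's arithmetic and calibration, not
the tool's clinical performance on new data.

## Problem sizes

Count-level reproductions of the published tables are exact and effectively
instantaneous. Sampled tests use cohorts from ~1,400 to the full 56,903
records (generation is vectorized; a full cohort generates in well under a
second). The acceptance script averages the combined-contrast diagnostic
odds ratio over 20 full-scale cohorts; with per-replicate log-OR standard
error ≈ 0.058, the mean is expected within a few percent of the calibrated
value 4.58.

## Known limitations

* The rule set is timing-agnostic: re-assessment at pre-birth or postpartum
  uses identical logic, so administration timing is workflow, not
  computation.
* No imputation of missing risk factors; missingness is logged only.
* Between-group covariate hypothesis testing and multilevel (site) modeling
  are out of scope.
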