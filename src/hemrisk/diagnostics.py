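"""Screening-test diagnostics for risk-group contrasts.

Each contrast treats membership in one or more elevated risk groups as the
screening "test positive" and composite morbidity (or a named component) as
the reference outcome, yielding a 2x2 table:

====================  ==============  ==============
                      outcome +       outcome -
test positive         TP              FP
test negative (low)   FN              TN
====================  ==============  ==============

From it: sensitivity TP/(TP+FN), specificity TN/(FP+TN), PPV TP/(TP+FP),
NPV TN/(FN+TN), and the diagnostic odds ratio dOR = (TP*TN)/(FP*FN) with a
Woolf (log-normal) confidence interval,
``exp(log dOR ± z * sqrt(1/TP + 1/FP + 1/FN + 1/TN))``.
If any cell is zero, the Haldane–Anscombe correction adds 0.5 to all four
cells before the odds ratio and interval are computed, and the result is
flagged. The three standard contrasts are medium vs low, high vs low, and
medium+high combined vs low; records outside a contrast's groups are
excluded from its table, not pooled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyContrastError, UndefinedStatisticError
from .outcomes import COMPONENTS
from .risk_rules import HIGH, LEVELS, LOW, MEDIUM

#: The three standard contrasts, in reporting order.
STANDARD_CONTRASTS = (
    ("medium_vs_low", (MEDIUM,)),
    ("high_vs_low", (HIGH,)),
    ("medium_high_vs_low", (MEDIUM, HIGH)),
)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Screening 2x2 table: counts of (test, outcome) combinations."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        cells = (self.tp, self.fp, self.fn, self.tn)
        if any(c < 0 for c in cells):
            raise ValueError("2x2 cell counts must be non-negative")
        if sum(cells) == 0:
            raise EmptyContrastError("all four cells of the 2x2 table are zero")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def scaled(self, k: int) -> "ContingencyTable2x2":
        return ContingencyTable2x2(self.tp * k, self.fp * k, self.fn * k, self.tn * k)


@dataclass(frozen=True)
class ComparisonSpec:
    """Which risk levels count as test-positive, against the low referent."""

    positive_levels: tuple[str, ...]
    outcome: str = "composite"

    def __post_init__(self) -> None:
        if not self.positive_levels:
            raise ValueError("positive_levels must be non-empty")
        bad = set(self.positive_levels) - {MEDIUM, HIGH}
        if bad:
            raise ValueError(f"positive_levels must be within {{medium, high}}, got {bad}")
        if self.outcome != "composite" and self.outcome not in COMPONENTS:
            raise ValueError(f"unknown outcome {self.outcome!r}")


@dataclass(frozen=True)
class DiagnosticSummary:
    """Full-precision diagnostics for one contrast."""

    contrast: str
    table: ContingencyTable2x2
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    dor: float
    ci_low: float
    ci_high: float
    alpha: float
    correction_applied: bool


def sensitivity(t: ContingencyTable2x2) -> float:
    if t.tp + t.fn == 0:
        raise UndefinedStatisticError("sensitivity")
    return t.tp / (t.tp + t.fn)


def specificity(t: ContingencyTable2x2) -> float:
    if t.fp + t.tn == 0:
        raise UndefinedStatisticError("specificity")
    return t.tn / (t.fp + t.tn)


def ppv(t: ContingencyTable2x2) -> float:
    if t.tp + t.fp == 0:
        raise UndefinedStatisticError("ppv")
    return t.tp / (t.tp + t.fp)


def npv(t: ContingencyTable2x2) -> float:
    if t.fn + t.tn == 0:
        raise UndefinedStatisticError("npv")
    return t.tn / (t.fn + t.tn)


def _corrected_cells(t: ContingencyTable2x2) -> tuple[float, float, float, float, bool]:
    cells = (t.tp, t.fp, t.fn, t.tn)
    if any(c == 0 for c in cells):
        return tuple(c + 0.5 for c in cells) + (True,)  # type: ignore[return-value]
    return tuple(float(c) for c in cells) + (False,)  # type: ignore[return-value]


def diagnostic_or(t: ContingencyTable2x2) -> tuple[float, bool]:
    """Cross-product odds ratio, Haldane–Anscombe corrected on zero cells.

    Returns ``(dor, correction_applied)``.
    """
    a, b, c, d, corrected = _corrected_cells(t)
    return (a * d) / (b * c), corrected


def woolf_ci(
    t: ContingencyTable2x2, alpha: float = 0.05
) -> tuple[float, float]:
    """Woolf (log-normal) confidence interval for the diagnostic odds ratio.

    The half-width on the log scale is ``z_{1-alpha/2} *
    sqrt(1/TP + 1/FP + 1/FN + 1/TN)`` (corrected cells if any cell is zero).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    a, b, c, d, _ = _corrected_cells(t)
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(1 - alpha / 2)
    return math.exp(log_or - z * se), math.exp(log_or + z * se)


def summarize(
    t: ContingencyTable2x2, contrast: str = "", alpha: float = 0.05
) -> DiagnosticSummary:
    """All diagnostics for one table, at full precision."""
    dor, corrected = diagnostic_or(t)
    lo, hi = woolf_ci(t, alpha)
    return DiagnosticSummary(
        contrast=contrast,
        table=t,
        sensitivity=sensitivity(t),
        specificity=specificity(t),
        ppv=ppv(t),
        npv=npv(t),
        dor=dor,
        ci_low=lo,
        ci_high=hi,
        alpha=alpha,
        correction_applied=corrected,
    )


def build_table(
    levels: Sequence[str],
    outcome_positive: Sequence[bool],
    spec: ComparisonSpec,
) -> ContingencyTable2x2:
    """Accumulate a contrast's 2x2 table from per-record (level, outcome).

    Records at levels outside ``spec.positive_levels`` and the low referent
    are excluded entirely.
    """
    lv = np.asarray(levels, dtype=object)
    out = np.asarray(outcome_positive, dtype=bool)
    if lv.shape != out.shape:
        raise ValueError("levels and outcomes must have equal length")
    pos = np.isin(lv, spec.positive_levels)
    ref = lv == LOW
    if not (pos.any() or ref.any()):
        raise EmptyContrastError(
            f"no records in groups {spec.positive_levels + (LOW,)}"
        )
    return ContingencyTable2x2(
        tp=int((pos & out).sum()),
        fp=int((pos & ~out).sum()),
        fn=int((ref & out).sum()),
        tn=int((ref & ~out).sum()),
    )


def tables_from_group_counts(
    group_sizes: Mapping[str, int], event_counts: Mapping[str, int]
) -> dict[str, ContingencyTable2x2]:
    """Build all three standard contrast tables from per-group totals.

    Parameters
    ----------
    group_sizes, event_counts : mappings keyed by risk level giving the
        number of deliveries and of outcome-positive deliveries per group.
    """
    tables = {}
    for name, positive in STANDARD_CONTRASTS:
        tp = sum(event_counts[g] for g in positive)
        n_pos = sum(group_sizes[g] for g in positive)
        fn = event_counts[LOW]
        tables[name] = ContingencyTable2x2(
            tp=tp, fp=n_pos - tp, fn=fn, tn=group_sizes[LOW] - fn
        )
    return tables


@dataclass(frozen=True)
class EvaluationReport:
    """Per-group incidence plus the three standard contrast summaries."""

    incidence: pd.DataFrame
    contrasts: dict[str, DiagnosticSummary]
    alpha: float

    def diagnostics_frame(self, decimals: int = 2) -> pd.DataFrame:
        """Tabulate the contrast summaries, rounded for display."""
        rows = []
        for name, s in self.contrasts.items():
            rows.append(
                {
                    "contrast": name,
                    "tp": s.table.tp,
                    "fp": s.table.fp,
                    "fn": s.table.fn,
                    "tn": s.table.tn,
                    "sensitivity": round(s.sensitivity, decimals),
                    "specificity": round(s.specificity, decimals),
                    "ppv": round(s.ppv, decimals),
                    "npv": round(s.npv, decimals),
                    "dor": round(s.dor, decimals),
                    "ci_low": round(s.ci_low, decimals),
                    "ci_high": round(s.ci_high, decimals),
                    "correction_applied": s.correction_applied,
                }
            )
        return pd.DataFrame(rows)


def _incidence_table(
    levels: np.ndarray, flags: pd.DataFrame, group_sizes: Mapping[str, int]
) -> pd.DataFrame:
    rows = []
    for outcome in ("composite",) + COMPONENTS:
        row: dict[str, object] = {"outcome": outcome}
        for g in LEVELS:
            n = group_sizes[g]
            count = int(flags.loc[levels == g, outcome].sum())
            row[f"{g}_count"] = count
            row[f"{g}_pct"] = round(100 * count / n, 1) if n else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def evaluate(
    levels: Sequence[str],
    flags: pd.DataFrame,
    alpha: float = 0.05,
) -> EvaluationReport:
    """Run the full diagnostics stage on a classified, scored cohort.

    Parameters
    ----------
    levels : per-record risk level labels.
    flags : frame from :func:`hemrisk.outcomes.composite_frame` — boolean
        ``composite`` plus one column per component.
    alpha : two-sided significance level for the Woolf intervals.

    Returns the per-group incidence table (counts and percentages at 1 dp)
    and the three standard contrast summaries on the composite outcome.
    """
    lv = np.asarray(levels, dtype=object)
    if len(lv) != len(flags):
        raise ValueError("levels and flags must have equal length")
    unknown = set(np.unique(lv)) - set(LEVELS)
    if unknown:
        raise ValueError(f"unknown risk levels {unknown}")
    group_sizes = {g: int((lv == g).sum()) for g in LEVELS}
    flags = flags.reset_index(drop=True)
    incidence = _incidence_table(lv, flags, group_sizes)
    out = flags["composite"].to_numpy(dtype=bool)
    contrasts = {}
    for name, positive in STANDARD_CONTRASTS:
        spec = ComparisonSpec(positive_levels=positive)
        try:
            table = build_table(lv, out, spec)
            contrasts[name] = summarize(table, contrast=name, alpha=alpha)
        except UndefinedStatisticError as exc:
            raise UndefinedStatisticError(f"{name}: {exc.statistic}") from exc
        except EmptyContrastError as exc:
            raise EmptyContrastError(f"{name}: {exc}") from exc
    return EvaluationReport(incidence=incidence, contrasts=contrasts, alpha=alpha)


def evaluate_from_counts(
    group_sizes: Mapping[str, int],
    outcome_counts: Mapping[str, Mapping[str, int]],
    alpha: float = 0.05,
) -> EvaluationReport:
    """Diagnostics stage driven by per-group counts instead of records.

    ``outcome_counts`` maps each outcome name (``composite`` and the
    components) to per-level event counts. Contrast summaries are computed
    on the composite outcome.
    """
    rows = []
    for outcome, counts in outcome_counts.items():
        row: dict[str, object] = {"outcome": outcome}
        for g in LEVELS:
            n = group_sizes[g]
            row[f"{g}_count"] = counts[g]
            row[f"{g}_pct"] = round(100 * counts[g] / n, 1) if n else float("nan")
        rows.append(row)
    incidence = pd.DataFrame(rows)
    tables = tables_from_group_counts(group_sizes, outcome_counts["composite"])
    contrasts = {
        name: summarize(t, contrast=name, alpha=alpha)
        for name, t in tables.items()
    }
    return EvaluationReport(incidence=incidence, contrasts=contrasts, alpha=alpha)
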