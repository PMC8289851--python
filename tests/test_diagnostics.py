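"""Screening-diagnostics tests: 2x2 construction, statistics, Woolf CI."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import GROUP_SIZES, OUTCOME_COUNTS
from oracle import brute_force_table

from hemrisk.diagnostics import (
    ComparisonSpec,
    ContingencyTable2x2,
    build_table,
    diagnostic_or,
    evaluate,
    evaluate_from_counts,
    npv,
    ppv,
    sensitivity,
    specificity,
    summarize,
    tables_from_group_counts,
    woolf_ci,
)
from hemrisk.errors import EmptyContrastError, UndefinedStatisticError
from hemrisk.outcomes import COMPONENTS
import pandas as pd


class TestTableConstruction:
    def test_combined_contrast_from_group_counts(self, combined_table):
        tables = tables_from_group_counts(
            GROUP_SIZES, OUTCOME_COUNTS["composite"]
        )
        assert tables["medium_high_vs_low"] == combined_table

    def test_two_group_contrast_excludes_third_group(self):
        levels = ["low", "medium", "high", "high", "low"]
        events = [False, True, True, False, True]
        t = build_table(levels, events, ComparisonSpec(("medium",)))
        # the two high records must not contribute anywhere
        assert (t.tp, t.fp, t.fn, t.tn) == (1, 0, 1, 1)

    def test_degenerate_all_low_no_events(self):
        t = build_table(["low"] * 5, [False] * 5, ComparisonSpec(("medium", "high")))
        assert (t.tp, t.fp, t.fn, t.tn) == (0, 0, 0, 5)

    def test_agrees_with_per_record_brute_force(self):
        rng = np.random.default_rng(11)
        levels = rng.choice(["low", "medium", "high"], size=1_000)
        events = rng.random(1_000) < 0.1
        for positive in [("medium",), ("high",), ("medium", "high")]:
            t = build_table(levels, events, ComparisonSpec(positive))
            assert (t.tp, t.fp, t.fn, t.tn) == brute_force_table(
                list(zip(levels, events)), set(positive)
            )
            assert t.total == np.isin(levels, positive + ("low",)).sum()

    def test_empty_included_set_errors(self):
        with pytest.raises(EmptyContrastError):
            build_table(["high"], [True], ComparisonSpec(("medium",)))
        # excluded level present but no included records either way
        with pytest.raises(EmptyContrastError):
            ContingencyTable2x2(0, 0, 0, 0)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 0, 0, 5)


class TestStatistics:
    def test_published_combined_contrast_values(self, combined_table):
        t = combined_table
        assert round(sensitivity(t), 2) == 0.92
        assert round(specificity(t), 2) == 0.28
        assert round(npv(t), 2) == 0.98
        assert round(ppv(t), 4) == 0.0946

    def test_perfect_classifier(self):
        t = ContingencyTable2x2(tp=8, fp=0, fn=0, tn=12)
        assert sensitivity(t) == specificity(t) == ppv(t) == npv(t) == 1.0

    def test_zero_denominator_names_the_statistic(self):
        t = ContingencyTable2x2(tp=0, fp=3, fn=0, tn=4)
        with pytest.raises(UndefinedStatisticError, match="sensitivity"):
            sensitivity(t)


class TestDiagnosticOddsRatio:
    def test_published_value(self, combined_table):
        dor, corrected = diagnostic_or(combined_table)
        assert round(dor, 2) == 4.58
        assert not corrected

    def test_no_association_identity(self):
        dor, _ = diagnostic_or(ContingencyTable2x2(10, 10, 10, 10))
        assert dor == 1.0

    def test_haldane_anscombe_on_zero_cell(self):
        dor, corrected = diagnostic_or(ContingencyTable2x2(5, 0, 3, 7))
        assert corrected
        assert dor == pytest.approx((5.5 * 7.5) / (0.5 * 3.5))

    @settings(max_examples=200, derandomize=True)
    @given(
        tp=st.integers(1, 500), fp=st.integers(1, 500),
        fn=st.integers(1, 500), tn=st.integers(1, 500),
        k=st.integers(2, 9),
    )
    def test_invariance_under_cell_scaling(self, tp, fp, fn, tn, k):
        t = ContingencyTable2x2(tp, fp, fn, tn)
        assert diagnostic_or(t.scaled(k))[0] == pytest.approx(
            diagnostic_or(t)[0], rel=1e-12
        )

    @settings(max_examples=200, derandomize=True)
    @given(
        tp=st.integers(1, 500), fp=st.integers(1, 500),
        fn=st.integers(1, 500), tn=st.integers(1, 500),
    )
    def test_dor_equals_sens_spec_identity(self, tp, fp, fn, tn):
        t = ContingencyTable2x2(tp, fp, fn, tn)
        se, sp = sensitivity(t), specificity(t)
        dor, _ = diagnostic_or(t)
        assert dor == pytest.approx(
            (se / (1 - se)) / ((1 - sp) / sp), rel=1e-9
        )

    def test_identity_holds_at_published_counts(self, combined_table):
        se = sensitivity(combined_table)
        sp = specificity(combined_table)
        implied = (se / (1 - se)) / ((1 - sp) / sp)
        assert round(implied, 2) == 4.58

    @settings(max_examples=200, derandomize=True)
    @given(
        tp=st.integers(1, 500), fp=st.integers(1, 500),
        fn=st.integers(1, 500), tn=st.integers(1, 500),
    )
    def test_bayes_ppv_npv_consistency(self, tp, fp, fn, tn):
        t = ContingencyTable2x2(tp, fp, fn, tn)
        se, sp = sensitivity(t), specificity(t)
        pi = (tp + fn) / t.total
        assert ppv(t) == pytest.approx(
            se * pi / (se * pi + (1 - sp) * (1 - pi)), abs=1e-12
        )
        assert npv(t) == pytest.approx(
            sp * (1 - pi) / (sp * (1 - pi) + (1 - se) * pi), abs=1e-12
        )


class TestWoolfCI:
    def test_published_combined_interval(self, combined_table):
        lo, hi = woolf_ci(combined_table, alpha=0.05)
        assert (round(lo, 2), round(hi, 2)) == (4.09, 5.13)

    def test_published_high_vs_low_interval(self):
        t = ContingencyTable2x2(tp=1898, fp=14_039, fn=330, tn=14_473)
        lo, hi = woolf_ci(t, alpha=0.05)
        assert (round(lo, 2), round(hi, 2)) == (5.26, 6.68)

    def test_scaling_cells_narrows_interval_around_same_estimate(self):
        t = ContingencyTable2x2(20, 30, 10, 40)
        big = t.scaled(100)
        lo, hi = woolf_ci(t)
        lo_b, hi_b = woolf_ci(big)
        assert diagnostic_or(big)[0] == pytest.approx(diagnostic_or(t)[0])
        assert lo < lo_b and hi_b < hi

    def test_coverage_of_fixed_true_odds_ratio(self):
        """95% Woolf interval covers a known OR in ~95% of simulated tables."""
        rng = np.random.default_rng(0)
        n1 = n0 = 200
        p1, p0 = 0.5, 0.25
        true_or = (p1 / (1 - p1)) / (p0 / (1 - p0))
        reps, covered = 500, 0
        for _ in range(reps):
            tp = int(rng.binomial(n1, p1))
            fn = int(rng.binomial(n0, p0))
            t = ContingencyTable2x2(tp, n1 - tp, fn, n0 - fn)
            lo, hi = woolf_ci(t, alpha=0.05)
            covered += lo <= true_or <= hi
        assert 0.925 <= covered / reps <= 0.975

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            woolf_ci(ContingencyTable2x2(1, 1, 1, 1), alpha=1.5)


class TestEvaluate:
    def test_from_counts_reproduces_all_published_diagnostics(self):
        report = evaluate_from_counts(GROUP_SIZES, OUTCOME_COUNTS, alpha=0.05)
        expected = {
            "medium_vs_low": (0.86, 0.38, 0.08, 0.98, 3.80, 3.37, 4.27),
            "high_vs_low": (0.85, 0.51, 0.12, 0.98, 5.93, 5.26, 6.68),
            "medium_high_vs_low": (0.92, 0.28, 0.09, 0.98, 4.58, 4.09, 5.13),
        }
        for name, (se, sp, pv, nv, dor, lo, hi) in expected.items():
            s = report.contrasts[name]
            assert round(s.sensitivity, 2) == se
            assert round(s.specificity, 2) == sp
            assert round(s.ppv, 2) == pv
            assert round(s.npv, 2) == nv
            assert round(s.dor, 2) == dor
            assert (round(s.ci_low, 2), round(s.ci_high, 2)) == (lo, hi)
            assert not s.correction_applied

    def test_incidence_percentages_match_published_rates(self):
        report = evaluate_from_counts(GROUP_SIZES, OUTCOME_COUNTS)
        inc = report.incidence.set_index("outcome")
        assert [
            inc.loc["composite", f"{g}_pct"] for g in ("low", "medium", "high")
        ] == [2.2, 8.0, 11.9]
        assert [
            inc.loc["hemorrhage", f"{g}_pct"] for g in ("low", "medium", "high")
        ] == [2.1, 7.6, 11.4]

    def test_null_association_gives_unit_odds_ratios(self):
        rng = np.random.default_rng(3)
        n = 30_000
        levels = rng.choice(["low", "medium", "high"], size=n)
        flags = pd.DataFrame(
            {c: np.zeros(n, dtype=bool) for c in COMPONENTS}
        )
        flags["hemorrhage"] = rng.random(n) < 0.08  # same rate in every group
        flags["composite"] = flags[list(COMPONENTS)].any(axis=1)
        report = evaluate(levels, flags)
        for s in report.contrasts.values():
            assert math.log(s.dor) == pytest.approx(0.0, abs=0.25)
            assert s.ci_low < 1 < s.ci_high

    def test_record_level_evaluate_matches_count_level(self):
        rng = np.random.default_rng(17)
        n = 5_000
        levels = rng.choice(["low", "medium", "high"], size=n, p=[0.3, 0.4, 0.3])
        flags = pd.DataFrame({c: np.zeros(n, dtype=bool) for c in COMPONENTS})
        rate = {"low": 0.02, "medium": 0.08, "high": 0.12}
        for g, r in rate.items():
            mask = levels == g
            flags.loc[mask, "hemorrhage"] = rng.random(mask.sum()) < r
        flags["composite"] = flags[list(COMPONENTS)].any(axis=1)
        report = evaluate(levels, flags)
        sizes = {g: int((levels == g).sum()) for g in rate}
        counts = {
            "composite": {
                g: int(flags.loc[levels == g, "composite"].sum()) for g in rate
            }
        }
        counts.update(
            {
                c: {g: int(flags.loc[levels == g, c].sum()) for g in rate}
                for c in COMPONENTS
            }
        )
        by_counts = evaluate_from_counts(sizes, counts)
        for name in report.contrasts:
            assert report.contrasts[name].dor == pytest.approx(
                by_counts.contrasts[name].dor
            )

    def test_contrast_errors_are_named(self):
        with pytest.raises(EmptyContrastError, match="medium_vs_low"):
            evaluate(
                ["high", "high"],
                pd.DataFrame(
                    {c: [False, False] for c in COMPONENTS}
                    | {"composite": [False, False]}
                ),
            )
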