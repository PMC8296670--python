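"""Registry construction, statistical primitives and verdict evaluation."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from octostrat.config import RuleConstants
from octostrat.hypotheses import (
    CategoricalStat,
    ContinuousStat,
    PrintedP,
    SummaryStats,
    aggregate,
    build_registry,
    direction_check,
    effect_band_check,
    evaluate_rq1,
    evaluate_rq2,
    evaluate_rq3,
    pairwise_chi_square,
    pairwise_t_test,
    responder_band_check,
)
from octostrat.stratify import ProportionTable


class TestRegistry:
    def test_sixty_three_hypotheses(self, registry):
        assert len(registry) == 63
        by_rq = {"RQ1": 0, "RQ2": 0, "RQ3": 0}
        for spec in registry:
            by_rq[spec.research_question] += 1
        assert by_rq == {"RQ1": 15, "RQ2": 30, "RQ3": 18}

    def test_ids_unique(self, registry):
        ids = [s.id for s in registry]
        assert len(set(ids)) == 63

    def test_band_mapping_by_subgroup(self, registry):
        bands = {
            (s.subject, s.measure): s.band
            for s in registry
            if s.research_question == "RQ3"
        }
        assert bands[("low", "effect_size")] == "large"
        assert bands[("obesity", "effect_size")] == "medium"
        assert bands[("high", "effect_size")] == "small"
        assert bands[("low", "mic_rate")] == "majority"
        assert bands[("obesity", "mic_rate")] == "half"
        assert bands[("high", "mic_rate")] == "minority"


class TestRQ1:
    def test_published_counts_give_12_of_15(self, proportion_table, registry):
        verdicts = evaluate_rq1(proportion_table, registry)
        assert len(verdicts) == 15
        accepted = [v.hypothesis_id for v in verdicts if v.accepted]
        refuted = [v.hypothesis_id for v in verdicts if v.accepted is False]
        assert len(accepted) == 12
        assert sorted(refuted) == [
            "rq1_high_CBT",
            "rq1_high_VIDEX",
            "rq1_obesity_VIDEX",
        ]

    def test_marginal_deviations_computed_unrounded(self, proportion_table):
        dev = proportion_table.deviations
        # 16/222 vs 213/1211 just exceeds the band; 52/177 far outside
        assert dev.loc["CBT", "high"] == pytest.approx(-10.38, abs=0.01)
        assert dev.loc["VIDEX", "obesity"] == pytest.approx(-18.27, abs=0.01)

    def test_invariant_to_uniform_cohort_scaling(self, proportion_table, registry):
        scaled = ProportionTable.from_counts(proportion_table.counts * 7)
        a = [v.accepted for v in evaluate_rq1(proportion_table, registry)]
        b = [v.accepted for v in evaluate_rq1(scaled, registry)]
        assert a == b

    def test_empty_cohort_undefined(self, registry):
        counts = pd.DataFrame(
            {"low": [0, 10], "high": [0, 5], "obesity": [0, 5]},
            index=["AMS_OA", "STABILO"],
        )
        verdicts = evaluate_rq1(ProportionTable.from_counts(counts), registry)
        ams = [v for v in verdicts if "AMS_OA" in v.hypothesis_id]
        assert all(v.accepted is None for v in ams)


class TestStatisticalPrimitives:
    def test_age_low_vs_high_strongly_significant(self):
        p = pairwise_t_test(65.2, 8.4, 421, 62.3, 8.6, 213)
        assert p < 0.001

    def test_identical_groups_give_p_one(self):
        assert pairwise_t_test(5.0, 1.0, 30, 5.0, 1.0, 30) == pytest.approx(1.0)

    def test_summary_path_equals_raw_vector_path(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            a = rng.normal(0, 1, rng.integers(3, 40))
            b = rng.normal(0.3, 1.2, rng.integers(3, 40))
            p_summary = pairwise_t_test(
                a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b)
            )
            p_raw = sps.ttest_ind(a, b, equal_var=True).pvalue
            assert p_summary == pytest.approx(p_raw, rel=1e-9)

    def test_gender_counts_strongly_significant(self):
        assert pairwise_chi_square([[310, 111], [88, 125]]) < 0.001

    def test_proportional_table_gives_p_one(self):
        assert pairwise_chi_square([[10, 20, 30], [20, 40, 60]]) == pytest.approx(1.0)

    def test_chi_square_matches_hand_computed_pearson(self):
        table = np.array([[12, 30], [25, 14]], dtype=float)
        # brute-force Pearson statistic from expected counts
        row, col, n = table.sum(1), table.sum(0), table.sum()
        expected = np.outer(row, col) / n
        x2 = ((table - expected) ** 2 / expected).sum()
        p_hand = sps.chi2.sf(x2, df=1)
        assert pairwise_chi_square(table) == pytest.approx(p_hand, rel=1e-12)

    def test_degenerate_tables_rejected(self):
        with pytest.raises(ValueError):
            pairwise_chi_square([[0, 0], [1, 2]])
        with pytest.raises(ValueError):
            pairwise_t_test(1.0, 0.0, 10, 2.0, 1.0, 10)
        with pytest.raises(ValueError):
            pairwise_t_test(1.0, 1.0, 1, 2.0, 1.0, 10)


class TestDirectionCheck:
    def test_continuous_means(self):
        a, b = ContinuousStat(65.2, 8.4, 421), ContinuousStat(62.3, 8.6, 213)
        assert direction_check("age", a, b, "greater")
        assert not direction_check("age", a, b, "less")

    def test_equal_means_have_no_direction(self):
        a = ContinuousStat(5.0, 1.0, 10)
        assert not direction_check("age", a, a, "greater")
        assert not direction_check("age", a, a, "less")

    def test_ordinal_kl_mean_score(self):
        # radiographic severity lower in the high-strength subgroup than
        # the low-strength subgroup despite a significant difference
        high = CategoricalStat({"0/1": 72, "2": 64, "3": 48, "4": 42})
        low = CategoricalStat({"0/1": 95, "2": 131, "3": 92, "4": 83})
        assert not direction_check("kl", high, low, "greater")
        assert direction_check("kl", high, low, "less")

    def test_binary_positive_class(self):
        high = CategoricalStat({"female": 88, "male": 125})
        low = CategoricalStat({"female": 310, "male": 111})
        assert direction_check("sex", high, low, "greater")  # more males


class TestPrintedP:
    def test_parse_and_significance(self):
        lt = PrintedP.parse("<0.001")
        assert lt.is_upper_bound and lt.significant(0.05)
        exact = PrintedP.parse("0.55")
        assert not exact.significant(0.05)
        assert PrintedP.parse("0.03").significant(0.05)


class TestRQ2:
    def test_published_summaries_give_26_of_30(self, table4_summary, registry):
        verdicts = evaluate_rq2(table4_summary, registry=registry)
        assert len(verdicts) == 30
        refuted = sorted(v.hypothesis_id for v in verdicts if v.accepted is False)
        assert refuted == [
            "rq2_12_high_age_vs_obesity",
            "rq2_13_high_kl_vs_low",
            "rq2_14_high_kl_vs_obesity",
            "rq2_28_obesity_pain_vs_low",
        ]
        assert sum(v.accepted is True for v in verdicts) == 26

    def test_opposite_direction_flagged(self, table4_summary, registry):
        verdicts = {v.hypothesis_id: v for v in evaluate_rq2(table4_summary, registry=registry)}
        assert "opposite direction" in verdicts["rq2_13_high_kl_vs_low"].observed

    def test_shared_cells_inherit_one_evaluation(self, table4_summary, registry):
        verdicts = {v.hypothesis_id: v for v in evaluate_rq2(table4_summary, registry=registry)}
        # the two contradictory low<->obesity strength hypotheses share
        # one cell and therefore one verdict
        first = verdicts["rq2_04_low_strength_vs_obesity"]
        second = verdicts["rq2_26_obesity_strength_vs_low"]
        assert "shared cell" in second.note
        assert first.hypothesis_id in second.note
        assert second.accepted is True and first.accepted is True

    def test_alpha_limits(self, table4_summary, registry):
        # with alpha -> 1 every correctly-directed hypothesis is accepted
        lax = RuleConstants(alpha=1.0)
        verdicts = evaluate_rq2(table4_summary, registry=registry, rules=lax)
        accepted = sum(v.accepted is True for v in verdicts)
        assert accepted == 28  # all but the two opposite-direction K/L cells
        # with alpha -> 0 nothing is
        strict = RuleConstants(alpha=1e-12)
        verdicts = evaluate_rq2(table4_summary, registry=registry, rules=strict)
        assert sum(v.accepted is True for v in verdicts) == 0

    def test_missing_variable_is_undefined(self, table4_summary, registry):
        stripped = SummaryStats(
            stats={k: v for k, v in table4_summary.stats.items() if k != "surgery"},
            printed_p=table4_summary.printed_p,
        )
        verdicts = {v.hypothesis_id: v for v in evaluate_rq2(stripped, registry=registry)}
        assert verdicts["rq2_05_high_surgery_vs_low"].accepted is None


class TestBands:
    @pytest.mark.parametrize(
        "values,kind,expected",
        [
            ([1.05], "large", True),
            ([0.60], "large", True),  # inclusive lower edge
            ([0.59], "large", False),
            ([1.10], "medium", False),
            ([0.27, 0.60], "medium", True),  # dual instrument, one passes
            ([0.30], "medium", True),
            ([0.70], "medium", True),
            ([0.82], "small", False),
            ([0.40], "small", True),
            ([-0.10], "small", True),  # unbounded below
        ],
    )
    def test_effect_bands(self, values, kind, expected):
        assert effect_band_check(values, kind) is expected

    def test_effect_values_compared_at_two_decimals(self):
        assert effect_band_check([0.596], "large") is True  # rounds to 0.60

    @pytest.mark.parametrize(
        "rates,kind,expected",
        [
            ([70], "majority", True),
            ([67], "majority", False),  # strict
            ([72], "half", False),
            ([67], "half", True),  # inclusive
            ([33], "half", True),
            ([7, 9], "minority", True),
            ([66], "minority", False),
            ([32.6], "minority", False),  # rounds to 33, strict
        ],
    )
    def test_responder_bands(self, rates, kind, expected):
        assert responder_band_check(rates, kind) is expected


class TestRQ3:
    def test_published_effects_give_8_of_18(self, table5_effects, registry):
        verdicts = evaluate_rq3(table5_effects, registry)
        assert len(verdicts) == 18
        assert sum(v.accepted is True for v in verdicts) == 8

    def test_low_strength_subgroup_alone_5_of_6(self, table5_effects, registry):
        verdicts = [
            v
            for v in evaluate_rq3(table5_effects, registry)
            if v.hypothesis_id.startswith("rq3_low")
        ]
        assert len(verdicts) == 6
        assert sum(v.accepted for v in verdicts) == 5
        # only the strength responder-rate hypothesis fails (49%/31%)
        failing = [v for v in verdicts if not v.accepted]
        assert failing[0].hypothesis_id == "rq3_low_strength_mic"

    def test_all_zero_effects(self, registry):
        df = pd.DataFrame(
            [
                {"subgroup": s, "outcome": o, "instrument": "", "effect_size": 0.0,
                 "mic_rate": 0.0}
                for s in ("low", "obesity", "high")
                for o in ("pain", "function", "strength")
            ]
        )
        verdicts = evaluate_rq3(df, registry)
        by_sub = lambda s: [v.accepted for v in verdicts if f"_{s}_" in v.hypothesis_id]
        assert sum(by_sub("low")) == 0
        assert sum(by_sub("obesity")) == 0
        assert sum(by_sub("high")) == 6  # small bands and minority all pass

    def test_missing_outcome_is_undefined(self, table5_effects, registry):
        partial = table5_effects[table5_effects["outcome"] != "strength"]
        verdicts = evaluate_rq3(partial, registry)
        undefined = [v for v in verdicts if v.accepted is None]
        assert len(undefined) == 6


class TestAggregate:
    def _mk(self, rq, i, accepted):
        from octostrat.hypotheses import Verdict

        return Verdict(f"{rq}_{i}", rq, "", "", accepted)

    def _full(self, acc1, acc2, acc3):
        vs = [self._mk("RQ1", i, i < acc1) for i in range(15)]
        vs += [self._mk("RQ2", i, i < acc2) for i in range(30)]
        vs += [self._mk("RQ3", i, i < acc3) for i in range(18)]
        return vs

    def test_published_verdict_counts_give_73_percent(self):
        out = aggregate(self._full(12, 26, 8))
        assert out["overall"] == {"accepted": 46, "total": 63, "percent": 73}

    def test_extremes(self):
        assert aggregate(self._full(15, 30, 18))["overall"]["percent"] == 100
        assert aggregate(self._full(0, 0, 0))["overall"]["percent"] == 0

    def test_wrong_count_rejected(self):
        with pytest.raises(ValueError, match="63"):
            aggregate(self._full(12, 26, 8)[:-1])

    def test_conservation_on_fixture_run(
        self, proportion_table, table4_summary, table5_effects, registry
    ):
        verdicts = (
            evaluate_rq1(proportion_table, registry)
            + evaluate_rq2(table4_summary, registry=registry)
            + evaluate_rq3(table5_effects, registry)
        )
        acc = sum(v.accepted is True for v in verdicts)
        ref = sum(v.accepted is False for v in verdicts)
        und = sum(v.accepted is None for v in verdicts)
        assert acc + ref + und == 63


class TestSummaryVsRawEquivalence:
    def test_from_records_matches_direct_tests(self, small_synthetic):
        """t and chi-square p-values computed from summary statistics
        equal those computed from the raw per-patient vectors."""
        from octostrat.stratify import stratify_cohorts

        _, records, _ = small_synthetic
        labels, _ = stratify_cohorts(records)
        summary = SummaryStats.from_records(records, labels)

        # continuous: age, low vs high
        a = summary.get("age", "low")
        b = summary.get("age", "high")
        p_summary = pairwise_t_test(a.mean, a.sd, a.n, b.mean, b.sd, b.n)
        ages_low = [r.age for r in records if labels[r.patient_id] == "low"]
        ages_high = [r.age for r in records if labels[r.patient_id] == "high"]
        p_raw = sps.ttest_ind(ages_low, ages_high, equal_var=True).pvalue
        assert p_summary == pytest.approx(p_raw, rel=1e-9)

        # categorical: sex, low vs high
        ca, cb = summary.get("sex", "low"), summary.get("sex", "high")
        table = [
            [ca.counts["female"], ca.counts["male"]],
            [cb.counts["female"], cb.counts["male"]],
        ]
        p_sum = pairwise_chi_square(table)
        p_scipy = sps.chi2_contingency(np.array(table), correction=False).pvalue
        assert p_sum == pytest.approx(p_scipy, rel=1e-12)
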