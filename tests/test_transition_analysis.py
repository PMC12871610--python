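import math

import numpy as np
import pandas as pd
import pytest

from bivalink import (
    ExpressionTable,
    UniverseMismatchError,
    call_bivalent,
    classify_transition,
    count_timeline,
    intersect_with_list,
    summarize_group_expression,
)


def calls_from_sets(stage, universe, bivalent):
    values = pd.Series({g: (10.0 if g in bivalent else 0.1) for g in universe})
    return call_bivalent(values, values, theta=1.0, stage=stage)


UNIVERSE = list("abcdefgh")


class TestClassifyTransition:
    def test_hand_set_algebra(self):
        part = classify_transition(
            calls_from_sets("A", UNIVERSE, {"a", "b", "c"}),
            calls_from_sets("B", UNIVERSE, {"b", "c", "d"}),
        )
        assert part.a_specific == {"a"}
        assert part.shared == {"b", "c"}
        assert part.b_specific == {"d"}
        assert part.fractions["shared_of_B"] == pytest.approx(2 / 3)

    def test_identical_sets_all_shared(self):
        part = classify_transition(
            calls_from_sets("A", UNIVERSE, {"a", "b"}),
            calls_from_sets("B", UNIVERSE, {"a", "b"}),
        )
        assert part.shared == {"a", "b"} and not part.a_specific and not part.b_specific

    def test_disjoint_sets_share_nothing(self):
        part = classify_transition(
            calls_from_sets("A", UNIVERSE, {"a"}),
            calls_from_sets("B", UNIVERSE, {"b"}),
        )
        assert part.shared == frozenset()

    def test_partition_covers_union_once(self):
        part = classify_transition(
            calls_from_sets("A", UNIVERSE, {"a", "b", "c"}),
            calls_from_sets("B", UNIVERSE, {"c", "d"}),
        )
        groups = [part.a_specific, part.shared, part.b_specific]
        union = set().union(*groups)
        assert union == {"a", "b", "c", "d"}
        assert sum(len(g) for g in groups) == len(union)

    def test_mirror_symmetry(self):
        a = calls_from_sets("A", UNIVERSE, {"a", "b", "c"})
        b = calls_from_sets("B", UNIVERSE, {"b", "d"})
        ab, ba = classify_transition(a, b), classify_transition(b, a)
        assert ab.a_specific == ba.b_specific
        assert ab.b_specific == ba.a_specific
        assert ab.shared == ba.shared

    def test_universe_mismatch_lists_offenders(self):
        with pytest.raises(UniverseMismatchError, match="zz"):
            classify_transition(
                calls_from_sets("A", UNIVERSE, {"a"}),
                calls_from_sets("B", UNIVERSE + ["zz"], {"a"}),
            )


class TestCountTimeline:
    def test_published_style_fold_change(self):
        df = count_timeline([("E3.5_ICM", 364), ("E4.5_ICM", 1457)])
        assert df["n_bivalent"].tolist() == [364, 1457]
        assert df["fold_change_vs_prev"].iloc[1] == pytest.approx(1457 / 364)

    def test_single_stage_has_no_fold_change(self):
        df = count_timeline([("only", 5)])
        assert len(df) == 1 and math.isnan(df["fold_change_vs_prev"].iloc[0])

    def test_zero_count_stage_yields_nan_not_inf(self):
        df = count_timeline([("a", 0), ("b", 10)])
        assert math.isnan(df["fold_change_vs_prev"].iloc[1])

    def test_accepts_call_sets(self):
        calls = calls_from_sets("A", UNIVERSE, {"a", "b"})
        df = count_timeline([calls])
        assert df["n_bivalent"].iloc[0] == 2


class TestGroupExpression:
    @staticmethod
    def expr(values: dict) -> ExpressionTable:
        return ExpressionTable(pd.DataFrame(values))

    def test_constant_group_has_zero_iqr(self):
        e = self.expr({"s1": pd.Series({"a": 2.0, "b": 2.0, "c": 2.0})})
        summary = summarize_group_expression({"grp": ["a", "b", "c"]}, e, stage="s1")
        row = summary.table.loc["grp"]
        assert row["median"] == 2.0 and row["q3"] - row["q1"] == 0.0

    def test_contrast_closed_form(self):
        a = pd.Series({"a": 1.0, "b": 4.0, "c": 0.5})
        e = self.expr({"A": a, "B": 2.0 * a})
        summary = summarize_group_expression(
            {"grp": ["a", "b", "c"]}, e, contrast=("A", "B"), pseudocount=0.0
        )
        assert summary.kind == "log2fc"
        assert summary.table.loc["grp", "median"] == pytest.approx(1.0)

    def test_empty_group_summarized_as_n_zero(self):
        e = self.expr({"s1": pd.Series({"a": 1.0})})
        summary = summarize_group_expression({"none": []}, e, stage="s1")
        assert summary.table.loc["none", "n"] == 0
        assert math.isnan(summary.table.loc["none", "median"])

    def test_low_coverage_group_rejected(self):
        e = self.expr({"s1": pd.Series({"a": 1.0})})
        with pytest.raises(ValueError, match="covers only"):
            summarize_group_expression({"grp": ["a", "x", "y"]}, e, stage="s1")

    def test_planted_bivalent_genes_are_lowly_expressed(self, two_wave_dataset):
        truth = two_wave_dataset.truth
        biv = truth.bivalent_genes("S4")
        active = truth.genes_of_class("S4", "k4_only")
        summary = summarize_group_expression(
            {"bivalent": biv, "active": active}, two_wave_dataset.expression, stage="S4"
        )
        assert summary.median("bivalent") < summary.median("active")


class TestIntersectWithList:
    def test_sublist_fully_overlaps(self):
        calls = calls_from_sets("A", UNIVERSE, {"a", "b", "c"})
        inter = intersect_with_list(calls, ["a", "b"])
        assert inter.counts == {"in_both": 2, "bivalent_only": 1, "list_only": 0}

    def test_disjoint_list(self):
        calls = calls_from_sets("A", UNIVERSE, {"a"})
        inter = intersect_with_list(calls, ["g", "h"])
        assert inter.counts["in_both"] == 0

    def test_empty_list_warns_and_counts_zero(self, caplog):
        calls = calls_from_sets("A", UNIVERSE, {"a"})
        with caplog.at_level("WARNING"):
            inter = intersect_with_list(calls, [])
        assert inter.counts["in_both"] == 0 and "empty" in caplog.text

    @pytest.mark.parametrize("seed", range(5))
    def test_counts_match_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        universe = [f"g{i}" for i in range(30)]
        biv = {g for g in universe if rng.random() < 0.4}
        listed = [g for g in universe if rng.random() < 0.3]
        inter = intersect_with_list(calls_from_sets("A", universe, biv), listed)
        in_both = sum(1 for g in listed for h in biv if g == h)
        assert inter.counts["in_both"] == in_both
        assert inter.counts["bivalent_only"] == len(biv) - in_both
        assert inter.counts["list_only"] == len(set(listed)) - in_both
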