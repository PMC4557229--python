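"""Confusion variants, PPV/TPR/MCC, arcs, percentages, summaries."""

import random

import pytest

from extpair.basepair_annotation import ALL_FAMILIES
from extpair.errors import EvaluationError
from extpair.evaluation import (
    ConfusionCounts,
    EvalPair,
    Variant,
    arc_categories,
    confusion,
    evaluate,
    evaluate_counts,
    match_pairs,
    mcc,
    percent_correct,
    ppv,
    round_half_up,
    summarize,
    tpr,
)
from extpair.formats import parse_dotbracket

from conftest import random_secondary_structure


def _pairs(keys, canonical=False, lw=None, multiplet=()):
    return [EvalPair(i=i, j=j, canonical=canonical, lw=lw,
                     in_multiplet=(i, j) in multiplet)
            for i, j in keys]


class TestMatching:
    def test_identical_sets_fully_matched(self):
        pairs = _pairs([(1, 9), (2, 8)])
        assert len(match_pairs(pairs, pairs)) == 2

    def test_disjoint_sets_unmatched(self):
        assert match_pairs(_pairs([(1, 9)]), _pairs([(3, 7)])) == []

    def test_index_must_be_identical(self):
        assert match_pairs(_pairs([(2, 9)]), _pairs([(2, 10)])) == []

    def test_multiplet_members_excluded(self):
        pred = _pairs([(1, 9), (2, 8)], multiplet={(1, 9)})
        ref = _pairs([(1, 9), (2, 8)])
        assert len(match_pairs(pred, ref)) == 1


class TestConfusion:
    def test_worked_example_variant_iii(self):
        """18 reference non-canonical, 3 predicted, 2 position-matched."""
        ref = _pairs([(k, k + 30) for k in range(1, 19)])
        pred = _pairs([(1, 31), (2, 32), (25, 28)])
        counts = confusion(pred, ref, Variant.III)
        assert (counts.tp, counts.fp, counts.fn) == (2, 1, 16)
        res = evaluate_counts(counts)
        assert round_half_up(res.ppv) == 0.67
        assert round_half_up(res.tpr) == 0.11
        assert round_half_up(res.mcc) == 0.27

    def test_variant_iv_classification_dependent(self):
        """4 matched, 3 LW-correct, no unmatched predictions, 9 in reference."""
        fams = ALL_FAMILIES
        ref = _pairs([(k, k + 20) for k in range(1, 10)], lw=fams[1])
        pred = (_pairs([(1, 21), (2, 22), (3, 23)], lw=fams[1])
                + _pairs([(4, 24)], lw=fams[2]))
        counts = confusion(pred, ref, Variant.IV)
        assert (counts.tp, counts.fp, counts.fn) == (3, 1, 5)
        res = evaluate_counts(counts)
        assert round_half_up(res.ppv) == 0.75
        assert round_half_up(res.tpr) == 0.38

    def test_equal_sets_zero_errors_all_variants(self):
        pairs = (_pairs([(1, 12), (2, 11)], canonical=True, lw=ALL_FAMILIES[0])
                 + _pairs([(4, 9)], lw=ALL_FAMILIES[5]))
        for variant in Variant:
            counts = confusion(pairs, pairs, variant)
            assert counts.fp == 0 and counts.fn == 0

    def test_variant_iv_without_lw_labels_raises(self):
        pairs = _pairs([(1, 9)])
        with pytest.raises(EvaluationError):
            confusion(pairs, pairs, Variant.IV)

    def test_variant_nesting_monotone(self):
        rng = random.Random(3)
        for _ in range(30):
            def rand_pairs():
                return [
                    EvalPair(i=i, j=i + rng.randint(3, 12),
                             canonical=rng.random() < 0.5,
                             lw=rng.choice(ALL_FAMILIES))
                    for i in rng.sample(range(1, 60), rng.randint(0, 10))
                ]
            pred, ref = rand_pairs(), rand_pairs()
            c1 = confusion(pred, ref, Variant.I)
            c3 = confusion(pred, ref, Variant.III)
            c4 = confusion(pred, ref, Variant.IV)
            assert c3.tp <= c1.tp
            assert c4.tp <= c3.tp


class TestScores:
    @pytest.mark.parametrize("counts,expected", [
        ((2, 1, 0), 0.67), ((0, 0, 0), 0.0), ((5, 0, 0), 1.0),
    ])
    def test_ppv(self, counts, expected):
        c = ConfusionCounts(*counts, variant=Variant.I)
        assert round_half_up(ppv(c)) == expected

    @pytest.mark.parametrize("counts,expected", [
        ((2, 0, 16), 0.11), ((0, 0, 0), 0.0), ((3, 0, 5), 0.38),
    ])
    def test_tpr(self, counts, expected):
        c = ConfusionCounts(*counts, variant=Variant.I)
        assert round_half_up(tpr(c)) == expected

    @pytest.mark.parametrize("p,t,expected", [
        (0.85, 0.61, 0.72), (1.0, 1.0, 1.0), (0.78, 0.39, 0.55),
    ])
    def test_mcc_sqrt_form(self, p, t, expected):
        assert round_half_up(mcc(p, t)) == expected

    def test_mcc_symmetric_and_monotone(self):
        grid = [0.0, 0.2, 0.5, 0.9, 1.0]
        for p in grid:
            for t in grid:
                assert mcc(p, t) == mcc(t, p)
                for d in (0.05, 0.1):
                    if p + d <= 1:
                        assert mcc(p + d, t) >= mcc(p, t)

    def test_undefined_flags_mirror_na_cells(self):
        res = evaluate_counts(ConfusionCounts(0, 0, 5, variant=Variant.III))
        assert res.ppv == 0.0 and res.ppv_undefined and not res.tpr_undefined


class TestSelfComparison:
    def test_self_evaluation_is_perfect(self):
        rng = random.Random(41)
        for _ in range(20):
            ss = random_secondary_structure(rng, lw_labels=list(ALL_FAMILIES))
            for variant in Variant:
                res = evaluate(ss, ss, variant)
                if res.counts.tp:
                    assert res.ppv == res.tpr == res.mcc == 1.0

    def test_length_mismatch_raises(self):
        a = parse_dotbracket(">a\nGGCC\n(..)\n")
        b = parse_dotbracket(">b\nGGCCA\n(..).\n")
        with pytest.raises(EvaluationError):
            evaluate(a, b, Variant.I)


class TestArcs:
    def test_categories_and_cross_check_with_variant_i(self):
        pred = _pairs([(1, 9), (3, 7), (4, 12)])
        ref = _pairs([(1, 9), (2, 8)])
        table = arc_categories(pred, ref)
        by_cat = table.groupby("category").size().to_dict()
        counts = confusion(pred, ref, Variant.I)
        assert by_cat.get("TP_upper", 0) == counts.tp
        assert by_cat.get("FN_upper", 0) == counts.fn
        assert by_cat.get("FP_lower", 0) == counts.fp

    def test_empty_prediction_all_fn(self):
        table = arc_categories([], _pairs([(1, 9), (2, 8)]))
        assert set(table["category"]) == {"FN_upper"}


class TestPercentAndSummary:
    @pytest.mark.parametrize("n_correct,n_ref,expected", [
        (171, 641, 26.68), (0, 641, 0.00), (268, 607, 44.15),
        (1, 800, 0.13),   # 0.125 rounds half-up to 0.13
    ])
    def test_percent_correct(self, n_correct, n_ref, expected):
        assert percent_correct(n_correct, n_ref) == expected

    def test_percent_correct_validation(self):
        with pytest.raises(EvaluationError):
            percent_correct(5, 0)
        with pytest.raises(EvaluationError):
            percent_correct(6, 5)

    def test_single_structure_summary(self):
        counts = ConfusionCounts(2, 0, 2, variant=Variant.III)
        summary = summarize([("short", counts)])
        row = summary.table.loc["short"]
        assert row["percent"] == 50.00
        assert row["n_reference_noncanonical"] == 4

    def test_subsets_aggregate_independently(self):
        records = [
            ("a", ConfusionCounts(2, 1, 2, variant=Variant.III)),
            ("a", ConfusionCounts(1, 0, 3, variant=Variant.III)),
            ("b", ConfusionCounts(5, 2, 0, variant=Variant.III)),
        ]
        table = summarize(records).table
        assert table.loc["a", "n_structures"] == 2
        assert table.loc["a", "n_correct"] == 3
        assert table.loc["a", "n_reference_noncanonical"] == 8
        assert table.loc["a", "percent"] == 37.50
        assert table.loc["a", "n_predicted_total"] == 4
        assert table.loc["b", "percent"] == 100.00

    def test_empty_input_raises(self):
        with pytest.raises(EvaluationError):
            summarize([])

    def test_wrong_variant_rejected(self):
        with pytest.raises(EvaluationError):
            summarize([("a", ConfusionCounts(1, 0, 0, variant=Variant.I))])
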