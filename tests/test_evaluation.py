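"""Precision-recall curve, PRAUC, MAP, and per-disease P/R/F metrics."""

import random

import numpy as np
import pytest

from phenorec.evaluation import (
    RankedResult,
    average_precision,
    disease_prf,
    mean_average_precision,
    pr_curve,
    ranked_result,
)
from phenorec.matching import DiseaseMatcher
from phenorec.types import DiseaseTerm


def result(qid, flags, scores=None):
    if scores is None:
        scores = [1.0 - 0.1 * i for i in range(len(flags))]
    ranking = tuple((f"D{i}", s) for i, s in enumerate(scores))
    return RankedResult(qid, ranking, tuple(flags))


def id_matcher(ids):
    vocab = {d: DiseaseTerm(d, f"name {d}") for d in ids}
    return DiseaseMatcher(vocab, "string")


# -- brute-force oracles ------------------------------------------------

def brute_prauc(results):
    pooled = []
    total_rel = 0
    for r in results:
        n = sum(r.relevant)
        total_rel += n if n else 1
        pooled += [(s, rel) for (_, s), rel in zip(r.ranking, r.relevant)]
    pts = []
    for t in sorted({s for s, _ in pooled}, reverse=True):
        sel = [rel for s, rel in pooled if s >= t]
        pts.append((sum(sel) / total_rel, sum(sel) / len(sel)))
    rs = [0.0] + [r for r, _ in pts]
    ps = [pts[0][1]] + [p for _, p in pts]
    return sum((rs[i] - rs[i - 1]) * (ps[i] + ps[i - 1]) / 2 for i in range(1, len(rs)))


def brute_map(results):
    aps = []
    for r in results:
        hits, precs = 0, []
        for rank, rel in enumerate(r.relevant, 1):
            if rel:
                hits += 1
                precs.append(hits / rank)
        aps.append(sum(precs) / len(precs) if precs else 0.0)
    return sum(aps) / len(aps)


def random_results(rng, max_queries=10, max_ranks=8):
    n_q = rng.randint(1, max_queries)
    out = []
    for q in range(n_q):
        n = rng.randint(1, max_ranks)
        scores = sorted((round(rng.random(), 3) for _ in range(n)), reverse=True)
        flags = [rng.random() < 0.4 for _ in range(n)]
        out.append(result(f"q{q}", flags, scores))
    return out


class TestPRCurve:
    def test_perfect_ranking_gives_prauc_one(self):
        results = [result(f"q{i}", [True, False, False]) for i in range(4)]
        _, prauc = pr_curve(results)
        assert prauc == pytest.approx(1.0)

    def test_single_query_relevant_last_hand_enumeration(self):
        points, prauc = pr_curve([result("q", [False, False, False, True])])
        assert points == [(0.0, 0.0), (0.0, 0.0), (0.0, 0.0), (1.0, 0.25)]
        assert prauc == pytest.approx(0.125)

    def test_prauc_invariant_to_duplicating_queries(self):
        rng = random.Random(8)
        for _ in range(20):
            results = random_results(rng)
            if not any(any(r.relevant) for r in results):
                continue
            _, a = pr_curve(results)
            doubled = results + [
                RankedResult(r.query_id + "_copy", r.ranking, r.relevant) for r in results
            ]
            _, b = pr_curve(doubled)
            assert b == pytest.approx(a, abs=1e-12)

    def test_zero_relevant_items_rejected(self):
        with pytest.raises(ValueError, match="no relevant item"):
            pr_curve([result("q", [False, False])])

    def test_unretrieved_truth_holds_recall_below_one(self):
        results = [result("q1", [True]), result("q2", [False])]
        points, _ = pr_curve(results)
        assert max(r for r, _ in points) == pytest.approx(0.5)

    def test_relevance_flag_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="align"):
            RankedResult("q", (("D1", 0.5),), (True, False))


class TestMAP:
    def test_rank_one_everywhere_gives_one(self):
        assert mean_average_precision([result(f"q{i}", [True, False]) for i in range(3)]) == 1.0

    def test_two_queries_ranks_one_and_two(self):
        results = [result("q1", [True, False]), result("q2", [False, True])]
        assert mean_average_precision(results) == pytest.approx((1.0 + 0.5) / 2)

    def test_query_with_nothing_relevant_contributes_zero(self):
        results = [result("q1", [True]), result("q2", [False])]
        assert mean_average_precision(results) == pytest.approx(0.5)
        assert average_precision(result("q2", [False, False])) == 0.0

    def test_empty_result_list_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            mean_average_precision([])


class TestOracleEquivalence:
    def test_map_and_prauc_match_brute_force_on_random_fixtures(self):
        rng = random.Random(31)
        checked = 0
        while checked < 100:
            results = random_results(rng)
            if not any(any(r.relevant) for r in results):
                continue
            checked += 1
            _, prauc = pr_curve(results)
            assert prauc == pytest.approx(brute_prauc(results), abs=1e-9)
            assert mean_average_precision(results) == pytest.approx(
                brute_map(results), abs=1e-9
            )

    def test_permuting_query_order_changes_nothing(self):
        rng = random.Random(13)
        results = random_results(rng, max_queries=8)
        while not any(any(r.relevant) for r in results):
            results = random_results(rng, max_queries=8)
        shuffled = list(results)
        rng.shuffle(shuffled)
        assert pr_curve(shuffled)[1] == pytest.approx(pr_curve(results)[1], abs=1e-12)
        assert mean_average_precision(shuffled) == pytest.approx(
            mean_average_precision(results), abs=1e-12
        )


class TestDiseasePRF:
    def test_all_correct_gives_unit_scores(self):
        preds = [(f"q{i}", "D1", "D1") for i in range(3)]
        preds += [(f"r{i}", "D2", "D2") for i in range(3)]
        scores, macro_f = disease_prf(preds, id_matcher(["D1", "D2"]), min_patients=3)
        assert all(s.precision == s.recall == s.f_measure == 1.0 for s in scores)
        assert macro_f == 1.0

    def test_hand_confusion_counts(self):
        # 3 patients of D1, predictions (D1, D1, D2); no other D1 predictions
        preds = [("q1", "D1", "D1"), ("q2", "D1", "D1"), ("q3", "D2", "D1")]
        preds += [(f"r{i}", "D2", "D2") for i in range(3)]
        scores, _ = disease_prf(preds, id_matcher(["D1", "D2"]), min_patients=3)
        d1 = next(s for s in scores if s.disease_id == "D1")
        assert d1.precision == 1.0
        assert d1.recall == pytest.approx(2 / 3)
        assert d1.f_measure == pytest.approx(0.8)
        assert d1.n_affected == 3

    def test_category_criterion_counts_same_category_as_tp(self):
        vocab = {
            "D1": DiseaseTerm("D1", "one", categories=frozenset({"cat"})),
            "D2": DiseaseTerm("D2", "two", categories=frozenset({"cat"})),
        }
        matcher = DiseaseMatcher(vocab, "category")
        preds = [(f"q{i}", "D2", "D1") for i in range(3)]
        scores, macro_f = disease_prf(preds, matcher, min_patients=3)
        assert macro_f == 1.0
        assert all(s.recall == 1.0 for s in scores)

    def test_none_prediction_counts_as_miss(self):
        preds = [("q1", None, "D1"), ("q2", "D1", "D1"), ("q3", "D1", "D1")]
        scores, _ = disease_prf(preds, id_matcher(["D1"]), min_patients=3)
        assert scores[0].recall == pytest.approx(2 / 3)

    def test_min_patients_excludes_rare_truths(self):
        preds = [("q1", "D1", "D1")] * 3 + [("q4", "D2", "D2")]
        scores, _ = disease_prf(preds, id_matcher(["D1", "D2"]), min_patients=3)
        assert [s.disease_id for s in scores] == ["D1"]

    def test_macro_f_bounded_by_max_disease_f(self):
        preds = [("a", "D1", "D1")] * 3 + [("b", "D2", "D1")] * 3 + [("c", "D2", "D2")] * 3
        scores, macro_f = disease_prf(preds, id_matcher(["D1", "D2"]), min_patients=3)
        assert 0.0 <= macro_f <= max(s.f_measure for s in scores) <= 1.0


class TestMonotoneRelaxation:
    """On a strictly nested fixture, relaxing the criterion never lowers
    MAP, PRAUC, or macro-F."""

    def _nested_matchers(self):
        # names unique; D1/D2 share a concept; D1/D2/D3 share a category
        vocab = {
            "D1": DiseaseTerm("D1", "one", concept_key="ck", categories=frozenset({"cat"})),
            "D2": DiseaseTerm("D2", "two", concept_key="ck", categories=frozenset({"cat"})),
            "D3": DiseaseTerm("D3", "three", concept_key="other", categories=frozenset({"cat"})),
        }
        return [DiseaseMatcher(vocab, c) for c in ("string", "concept", "category")]

    def test_metrics_non_decreasing_under_relaxation(self):
        ranking = [("D2", 0.9), ("D3", 0.5), ("D1", 0.2)]
        results_by_crit = [
            [ranked_result(f"q{i}", ranking, "D1", m) for i in range(3)]
            for m in self._nested_matchers()
        ]
        preds = [(f"q{i}", "D2", "D1") for i in range(3)]
        maps = [mean_average_precision(r) for r in results_by_crit]
        praucs = [pr_curve(r)[1] for r in results_by_crit]
        macro_fs = [disease_prf(preds, m, 3)[1] for m in self._nested_matchers()]
        for seq in (maps, praucs, macro_fs):
            assert seq == sorted(seq)
        assert maps[0] < maps[1]  # the relaxation genuinely changes the metric
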