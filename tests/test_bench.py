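"""Truth matching, metric identities, AUC and decile reporting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from conftest import make_call
from svmeta.bench import (
    MatchParams,
    MatchResult,
    compute_metrics,
    decile_report,
    match_to_truth,
    roc_auc,
)
from svmeta.types import SVType


class TestMatching:
    def test_identical_call_is_tp(self):
        truth = [make_call(id="t", caller="truth")]
        call = [make_call(id="c")]
        result = match_to_truth(call, truth)
        assert (result.tp, result.fp, result.fn) == (1, 0, 0)
        assert result.pairs == [("c", "t")]

    def test_size_ratio_below_threshold_is_fp(self):
        truth = [make_call(id="t", caller="truth", svlen=1000, end=1999)]
        call = [make_call(id="c", svtype=SVType.INS, end=1000, svlen=500)]
        # same position but INS vs DEL: not even a candidate
        assert match_to_truth(call, truth).tp == 0
        # same type, size ratio 0.5 < 0.7
        call = [make_call(id="c", pos=1000, end=1499, svlen=500)]
        result = match_to_truth(call, truth)
        assert (result.tp, result.fp, result.fn) == (0, 1, 1)

    def test_truth_with_no_nearby_call_counts_as_fn(self):
        truth = [
            make_call(id="t1", caller="truth"),
            make_call(id="t2", caller="truth", pos=500_000, end=500_999, svlen=1000),
        ]
        result = match_to_truth([make_call(id="c")], truth)
        assert (result.tp, result.fp, result.fn) == (1, 0, 1)

    def test_breakpoint_distance_bound_is_inclusive(self):
        truth = [make_call(id="t", caller="truth")]
        at_bound = [make_call(id="c", pos=1500, end=2499, svlen=1000)]
        assert match_to_truth(at_bound, truth, MatchParams(ref_dist=500)).tp == 1
        past = [make_call(id="c", pos=1501, end=2500, svlen=1000)]
        assert match_to_truth(past, truth, MatchParams(ref_dist=500)).tp == 0

    def test_assignment_is_one_to_one_and_distance_ranked(self):
        truth = [make_call(id="t", caller="truth")]
        near = make_call(id="near", pos=1010, end=2009, svlen=1000)
        far = make_call(id="far", pos=1400, end=2399, svlen=1000)
        result = match_to_truth([far, near], truth)
        assert result.pairs == [("near", "t")]
        assert (result.tp, result.fp, result.fn) == (1, 1, 0)

    def test_duplicate_truth_ids_rejected(self):
        truth = [make_call(id="t", caller="truth"), make_call(id="t", caller="truth")]
        with pytest.raises(ValueError, match="duplicated"):
            match_to_truth([], truth)

    def test_conservation_and_monotonicity(self):
        rng = np.random.default_rng(5)
        truth = [
            make_call(id=f"t{i}", caller="truth", pos=int(p), end=int(p) + 999, svlen=1000)
            for i, p in enumerate(rng.integers(1, 10_000_000, size=40))
        ]
        calls = [
            make_call(id=f"c{i}", pos=t.pos + int(rng.integers(-50, 50)),
                      end=t.end + int(rng.integers(-50, 50)), svlen=1000)
            for i, t in enumerate(truth[:25])
        ]
        result = match_to_truth(calls, truth)
        assert result.tp + result.fn == len(truth)
        assert result.tp + result.fp == len(calls)
        # adding an unmatched call increments fp only
        extra = calls + [make_call(id="lone", pos=9_999_000, end=9_999_999, svlen=1000)]
        r2 = match_to_truth(extra, truth)
        assert (r2.tp, r2.fn) == (result.tp, result.fn)
        assert r2.fp == result.fp + 1

    def test_greedy_matches_maximum_bipartite_on_small_fixtures(self):
        """With ties constructed away, greedy distance-ranked assignment
        achieves the maximum-matching TP count."""
        import networkx as nx

        rng = np.random.default_rng(11)
        for _ in range(20):
            n_t, n_c = rng.integers(3, 12), rng.integers(3, 12)
            truth = [
                make_call(id=f"t{i}", caller="truth", pos=int(p), end=int(p) + 999,
                          svlen=1000)
                for i, p in enumerate(np.sort(rng.integers(1, 40_000, size=n_t)))
            ]
            calls = [
                make_call(id=f"c{i}", pos=int(p), end=int(p) + 999, svlen=1000)
                for i, p in enumerate(np.sort(rng.integers(1, 40_000, size=n_c)))
            ]
            result = match_to_truth(calls, truth)
            graph = nx.Graph()
            for c in calls:
                for t in truth:
                    if abs(c.pos - t.pos) <= 500 and abs(c.end - t.end) <= 500:
                        graph.add_edge(("c", c.id), ("t", t.id))
            expected = len(nx.max_weight_matching(graph, maxcardinality=True))
            assert result.tp == expected


class TestMetricIdentities:
    @pytest.mark.parametrize(
        "tp, fp, fn, precision, recall, f1",
        [
            (3207, 967, 844, 0.77, 0.79, 0.78),   # union of deletion calls
            (2649, 97, 1402, 0.96, 0.65, 0.78),   # strongest single deletion caller
            (2, 7, 5211, 0.22, 0.00, 0.00),       # near-zero insertion caller
            (1800, 131, 3413, 0.93, 0.35, 0.50),  # insertion-only caller
        ],
    )
    def test_printed_counts_reproduce_printed_metrics(self, tp, fp, fn, precision, recall, f1):
        metrics = compute_metrics(MatchResult(tp=tp, fp=fp, fn=fn, pairs=[("c", "t")] * tp)).rounded()
        assert metrics.precision == precision
        assert metrics.recall == recall
        assert metrics.f1 == f1

    def test_degenerate_zero_counts_yield_zero_by_convention(self):
        metrics = compute_metrics(MatchResult(tp=0, fp=0, fn=0, pairs=[]))
        assert (metrics.precision, metrics.recall, metrics.f1) == (0.0, 0.0, 0.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            MatchResult(tp=0, fp=-1, fn=0, pairs=[])


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [True, True, False, False]) == 1.0

    def test_small_fixture_equals_pair_enumeration(self):
        # scores: pos 0.8, 0.4; neg 0.6, 0.4 -> pairs won: (0.8>0.6), (0.8>0.4),
        # (0.4<0.6 -> 0), (0.4==0.4 -> 1/2) = 2.5 / 4
        assert roc_auc([0.8, 0.4, 0.6, 0.4], [1, 1, 0, 0]) == pytest.approx(2.5 / 4)

    def test_matches_sklearn_on_random_scores(self):
        rng = np.random.default_rng(0)
        scores = rng.random(500)
        labels = rng.random(500) > 0.6
        assert roc_auc(scores, labels) == pytest.approx(roc_auc_score(labels, scores))

    def test_independent_scores_near_half(self):
        rng = np.random.default_rng(1)
        scores = rng.random(10_000)
        labels = rng.random(10_000) > 0.5
        assert roc_auc(scores, labels) == pytest.approx(0.5, abs=0.02)

    def test_single_class_is_signaled(self):
        with pytest.raises(ValueError, match="single class"):
            roc_auc([0.1, 0.9], [True, True])


class TestDecileReport:
    def test_all_in_first_bin(self):
        table = decile_report([0.05] * 4, [True, False, True, False])
        assert table.loc[0, "n_calls"] == 4
        assert table.loc[0, "fraction"] == 1.0
        assert table.loc[0, "tp_proportion"] == 0.5

    def test_probability_one_lands_in_top_closed_bin(self):
        table = decile_report([1.0], [True])
        assert table.loc[9, "n_calls"] == 1

    def test_bin_sizes_sum_to_n_and_fractions_to_one(self):
        rng = np.random.default_rng(2)
        probs = rng.random(1000)
        table = decile_report(probs, rng.random(1000) > 0.5)
        assert table["n_calls"].sum() == 1000
        assert table["fraction"].sum() == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=60)
    @given(
        st.lists(
            st.tuples(st.floats(min_value=0.0, max_value=1.0), st.booleans()),
            min_size=1,
            max_size=200,
        )
    )
    def test_deciles_partition_any_probability_vector(self, data):
        probs = [p for p, _ in data]
        labels = [l for _, l in data]
        table = decile_report(probs, labels)
        assert table["n_calls"].sum() == len(probs)
        assert table["fraction"].sum() == pytest.approx(1.0)
        occupied = table[table["n_calls"] > 0]
        assert ((occupied["tp_proportion"] >= 0) & (occupied["tp_proportion"] <= 1)).all()
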