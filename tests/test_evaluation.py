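"""Negative sampling, CV plans, classification rule and metrics."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from dlslink import (
    BipartiteGraph,
    GeneratorConfig,
    classify_top_ranked,
    compute_metrics,
    evaluate_method,
    make_cv_plan,
    random_bipartite,
    sample_negatives,
    score_method,
    sweep_combination,
)
from dlslink.evaluation import recovery_auc


# ---------------------------------------------------------------- negatives
class TestSampleNegatives:
    def test_zero_and_full(self, small_random):
        g = small_random
        assert sample_negatives(g, 0, seed=1).pairs == ()
        full = sample_negatives(g, g.n_candidate_pairs, seed=1)
        assert set(full.pairs) == set(g.candidate_pairs())
        assert full.drug_coverage == full.protein_coverage == 1.0

    def test_capacity_error(self, small_random):
        with pytest.raises(ValueError, match="cannot sample"):
            sample_negatives(small_random, small_random.n_candidate_pairs + 1, seed=1)

    def test_disjoint_from_edges_and_deterministic(self, medium_random):
        g = medium_random
        s1 = sample_negatives(g, g.n_edges, seed=9)
        s2 = sample_negatives(g, g.n_edges, seed=9)
        assert s1.pairs == s2.pairs
        assert len(set(s1.pairs)) == g.n_edges
        edge_set = set(g.edges())
        assert not (set(s1.pairs) & edge_set)

    def test_different_seeds_differ(self, medium_random):
        g = medium_random
        a = sample_negatives(g, 50, seed=1).pairs
        b = sample_negatives(g, 50, seed=2).pairs
        assert a != b


# ---------------------------------------------------------------- CV plan
class TestCVPlan:
    def test_even_blocks(self):
        g = BipartiteGraph.from_edges(
            [(f"d{k}", f"p{k}") for k in range(10)]
            + [(f"d{k}", f"p{(k + 1) % 10}") for k in range(10)]
        )
        plan = make_cv_plan(g, k=10, seed=0)
        assert [len(f.test_positives) for f in plan.folds] == [2] * 10
        assert [len(f.test_negatives) for f in plan.folds] == [2] * 10

    def test_folds_partition_positives(self, medium_random):
        plan = make_cv_plan(medium_random, k=10, seed=3)
        union = list(
            itertools.chain.from_iterable(f.test_positives for f in plan.folds)
        )
        assert len(union) == len(set(union)) == medium_random.n_edges
        assert set(union) == set(medium_random.edges())

    def test_balanced_counts_within_one(self, medium_random):
        plan = make_cv_plan(medium_random, k=7, seed=3)
        for f in plan.folds:
            assert abs(len(f.test_positives) - len(f.test_negatives)) <= 1

    def test_deterministic_per_seed(self, medium_random):
        p1 = make_cv_plan(medium_random, seed=5)
        p2 = make_cv_plan(medium_random, seed=5)
        assert p1 == p2

    def test_k_below_two_rejected(self, medium_random):
        with pytest.raises(ValueError, match="k must be"):
            make_cv_plan(medium_random, k=1)


# ---------------------------------------------------------------- classify
def _table(pairs, scores):
    return pd.DataFrame(
        {
            "drug": [d for d, _ in pairs],
            "protein": [p for _, p in pairs],
            "method": "test",
            "score": scores,
        }
    )


class TestClassifyTopRanked:
    def test_m_equals_all(self):
        t = _table([("d1", "p1"), ("d2", "p2")], [0.1, 0.9])
        out = classify_top_ranked(t, 2)
        assert out["predicted"].all()

    def test_perfect_scorer_perfect_accuracy(self):
        pairs = [("d1", "p1"), ("d2", "p2"), ("d3", "p3"), ("d4", "p4")]
        truth = [True, True, False, False]
        t = _table(pairs, [0.9, 0.8, 0.2, 0.1])
        out = classify_top_ranked(t, 2)
        truth_map = dict(zip(pairs, truth))
        labels = [
            truth_map[(d, p)] == pr
            for d, p, pr in zip(out["drug"], out["protein"], out["predicted"])
        ]
        assert all(labels)

    def test_m_too_large_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            classify_top_ranked(_table([("d", "p")], [1.0]), 2)

    def test_tie_break_is_lexicographic(self):
        t = _table([("d2", "p1"), ("d1", "p1"), ("d1", "p0")], [1.0, 1.0, 1.0])
        out = classify_top_ranked(t, 1)
        assert out.loc[0, ["drug", "protein"]].tolist() == ["d1", "p0"]
        assert out["predicted"].tolist() == [True, False, False]

    def test_balanced_identity_by_exhaustion(self):
        """With P = N and m = P, accuracy equals sensitivity for any scores:
        brute force over every labeling and score ordering of 4 pairs."""
        pairs = [("a", "w"), ("b", "x"), ("c", "y"), ("d", "z")]
        for truth in itertools.permutations([True, True, False, False]):
            for scores in itertools.permutations([4.0, 3.0, 2.0, 1.0]):
                out = classify_top_ranked(_table(pairs, list(scores)), 2)
                tmap = dict(zip(pairs, truth))
                tr = [tmap[(d, p)] for d, p in zip(out["drug"], out["protein"])]
                m = compute_metrics(out["predicted"], tr, out["score"])
                assert m["accuracy"] == pytest.approx(m["sensitivity"])


# ---------------------------------------------------------------- metrics
class TestComputeMetrics:
    def test_textbook_confusion(self):
        # TP=3 FP=1 FN=1 TN=3
        labels = [1, 1, 1, 1, 0, 0, 0, 0]
        truth = [1, 1, 1, 0, 1, 0, 0, 0]
        scores = [8, 7, 6, 5, 4, 3, 2, 1]
        m = compute_metrics(labels, truth, scores)
        for name in ("precision", "sensitivity", "f1", "accuracy"):
            assert m[name] == pytest.approx(0.75)

    def test_perfect_separation(self):
        truth = [1, 1, 0, 0]
        m = compute_metrics(truth, truth, [4, 3, 2, 1])
        assert m["auc"] == 1.0 and m["aupr"] == 1.0

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(12)
        n = 2000
        truth = np.r_[np.ones(n, bool), np.zeros(n, bool)]
        scores = rng.random(2 * n)
        m = compute_metrics(scores > 0.5, truth, scores)
        se = np.sqrt((2 * n + 1) / (12 * n * n))
        assert abs(m["auc"] - 0.5) < 3 * se

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="equal length"):
            compute_metrics([1], [1, 0], [0.5, 0.1])

    def test_empty_denominator_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="empty denominator"):
            m = compute_metrics([0, 0], [1, 1], [0.2, 0.1])
        assert m["precision"] == 0.0

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        truth = rng.random(200) < 0.5
        scores = rng.random(200)
        m1 = compute_metrics(truth, truth, scores)
        m2 = compute_metrics(truth, truth, np.exp(4 * scores) + 2)
        assert m1["auc"] == pytest.approx(m2["auc"])


# ---------------------------------------------------------------- evaluate
class TestEvaluateMethod:
    def test_deterministic(self, medium_random):
        r1 = evaluate_method(medium_random, "cn", k=5, seed=4, runs=2)
        r2 = evaluate_method(medium_random, "cn", k=5, seed=4, runs=2)
        pd.testing.assert_frame_equal(r1.per_fold, r2.per_fold)

    def test_unknown_method(self, medium_random):
        with pytest.raises(ValueError, match="unknown method"):
            evaluate_method(medium_random, "resource-allocation")

    def test_balanced_identity_on_every_fold(self, medium_random):
        rep = evaluate_method(medium_random, "dls", k=10, seed=2, runs=2)
        np.testing.assert_allclose(
            rep.per_fold["accuracy"], rep.per_fold["sensitivity"], atol=1e-12
        )

    def test_report_mean_within_fold_range(self, medium_random):
        rep = evaluate_method(medium_random, "pa", k=5, seed=1, runs=2)
        for name in ("auc", "accuracy"):
            col = rep.per_fold[name]
            assert col.min() - 1e-12 <= rep.mean[name] <= col.max() + 1e-12
            assert 0.0 <= rep.mean[name] <= 1.0

    def test_no_leakage_removed_vs_rebuilt(self, medium_random):
        """Scores are identical whether test edges are removed from the graph
        or the training graph is rebuilt from scratch without them."""
        g = medium_random
        plan = make_cv_plan(g, k=10, seed=8)
        fold = plan.folds[0]
        removed = g.remove_edges(fold.test_positives)
        rebuilt = BipartiteGraph.from_edges(
            [e for e in g.edges() if e not in set(fold.test_positives)],
            drugs=g.drugs,
            proteins=g.proteins,
        )
        pairs = list(fold.test_positives) + list(fold.test_negatives)
        for method in ("dls", "cn", "ja", "pa"):
            s1 = score_method(removed, method, pairs)["score"].to_numpy()
            s2 = score_method(rebuilt, method, pairs)["score"].to_numpy()
            assert (s1 == s2).all()

    def test_training_degrees_exclude_heldout(self, path_graph):
        """Removing a fold's positives changes the degrees the scorer sees."""
        g = path_graph.add_edges([("d1", "p2")])  # make (d1,p2) an edge
        g_train = g.remove_edges([("d1", "p2")])
        # with the edge removed, K_d1 is back to 1 and the score reflects it
        s = score_method(g_train, "dls", [("d1", "p2")])["score"].iat[0]
        assert s == pytest.approx(1.0 + 1.0 + 0.5)


# ---------------------------------------------------------------- sweep
class TestSweep:
    def test_grid_zero_equals_plain_cn(self, medium_random):
        base = evaluate_method(medium_random, "cn+dls", k=5, seed=6, runs=1, t=0.0)
        cn = evaluate_method(medium_random, "cn", k=5, seed=6, runs=1)
        assert base.mean["accuracy"] == pytest.approx(cn.mean["accuracy"])
        table = sweep_combination(medium_random, "dls", [0.0], k=5, seed=6, runs=1)
        assert table["accuracy"].iat[0] == pytest.approx(cn.mean["accuracy"])

    def test_output_rows_match_grid(self, medium_random):
        grid = [0.0, 5.0, 10.0]
        table = sweep_combination(medium_random, "ja", grid, k=5, seed=1, runs=1)
        assert len(table) == len(grid)
        assert table["coeff"].tolist() == grid
        assert "best_accuracy_coeff" in table.attrs

    def test_empty_grid_rejected(self, medium_random):
        with pytest.raises(ValueError, match="grid is empty"):
            sweep_combination(medium_random, "dls", [])


# ---------------------------------------------------------------- recovery
def test_dls_beats_pa_on_planted_structure(strong_planted):
    g, held = strong_planted
    dls = recovery_auc(g, held, "dls", seed=0)
    pa = recovery_auc(g, held, "pa", seed=0)
    assert dls > 0.8 > pa
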