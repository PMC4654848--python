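"""Bootstrap edge ranking and AUROC / AUPRC metrics."""

import itertools

import numpy as np
import pytest

from priorpc import (BenchmarkSpec, BootstrapConfig, GoldStandard,
                     RankedEdgeList, all_pairs, auprc, auroc, bootstrap_rank,
                     dsep_oracle, make_benchmark, pc_skeleton, restrict_nodes)


class TestBootstrapRank:
    def test_k1_is_indicator_of_single_skeleton(self, small_benchmark):
        data, gold, dag = small_benchmark
        oracle = dsep_oracle(dag)

        def algo(d):
            return pc_skeleton(oracle, d.variables)

        rk = bootstrap_rank(data, algo, BootstrapConfig(K=1, seed=0))
        assert {p for p, _ in rk.entries} == set(gold.true_edges)
        assert all(s == 1.0 for _, s in rk.entries)

    def test_frequency_counting_and_order(self):
        """An edge appearing in all K skeletons outranks one appearing
        in K-1; counting is by presence per resample."""
        data, _, _ = make_benchmark(BenchmarkSpec(n_nodes=5, n_edges=5,
                                                  n_samples=30, seed=1))
        calls = itertools.count()
        from priorpc import Skeleton

        def algo(d):
            k = next(calls)
            edges = {("A", "B")} if k > 0 else set()
            edges.add(("C", "D"))
            return Skeleton(("A", "B", "C", "D"), frozenset(edges))

        rk = bootstrap_rank(data, algo, BootstrapConfig(K=4, seed=0))
        scores = rk.scores()
        assert scores[("C", "D")] == 4.0
        assert scores[("A", "B")] == 3.0
        assert rk.entries[0][0] == ("C", "D")

    def test_deterministic_under_seed(self, small_benchmark):
        data, _, dag = small_benchmark
        oracle = dsep_oracle(dag)

        def algo(d):
            return pc_skeleton(oracle, d.variables)

        rk1 = bootstrap_rank(data, algo, BootstrapConfig(K=3, seed=42))
        rk2 = bootstrap_rank(data, algo, BootstrapConfig(K=3, seed=42))
        assert rk1.entries == rk2.entries

    def test_algorithm_failure_reports_resample_index(self, small_benchmark):
        data, _, _ = small_benchmark

        def algo(d):
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError, match="resample 0"):
            bootstrap_rank(data, algo, BootstrapConfig(K=2, seed=0))

    def test_oracle_algorithm_scores_every_true_edge_k(self, small_benchmark):
        """The d-separation-driven search is resample-independent, so
        every true edge reaches the maximal frequency K."""
        data, gold, dag = small_benchmark
        oracle = dsep_oracle(dag)

        def algo(d):
            return pc_skeleton(oracle, d.variables)

        K = 4
        rk = bootstrap_rank(data, algo, BootstrapConfig(K=K, seed=3))
        scores = rk.scores()
        assert all(scores[e] == K for e in gold.true_edges)


class TestRestrictNodes:
    def test_isolated_node_dropped(self):
        gold = GoldStandard(("A", "B", "C"), frozenset({("A", "B")}))
        assert restrict_nodes(gold) == {"A", "B"}

    def test_fully_connected_keeps_all(self):
        gold = GoldStandard(("A", "B", "C"),
                            frozenset({("A", "B"), ("B", "C")}))
        assert restrict_nodes(gold) == {"A", "B", "C"}

    def test_many_isolated_nodes(self):
        _, gold, _ = make_benchmark(BenchmarkSpec(n_nodes=30, n_edges=10,
                                                  n_samples=5, seed=2))
        connected = restrict_nodes(gold)
        isolated = set(gold.nodes) - connected
        assert connected and all(gold.degree(v) == 0 for v in isolated)

    def test_empty_gold_raises(self):
        gold = GoldStandard(("A", "B"), frozenset())
        with pytest.raises(ValueError, match="no edges"):
            restrict_nodes(gold)


def _brute_force_auroc(scores, labels):
    """P(random positive outranks random negative), ties = 1/2."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def _brute_force_auprc(scores, labels):
    """Independent step-summation over distinct thresholds."""
    order = sorted(range(len(scores)), key=lambda k: -scores[k])
    thresholds = sorted({scores[k] for k in order}, reverse=True)
    n_pos = sum(labels)
    area, prev_recall = 0.0, 0.0
    for t in thresholds:
        sel = [k for k in order if scores[k] >= t]
        tp = sum(labels[k] for k in sel)
        precision = tp / len(sel)
        recall = tp / n_pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


def _instance(rng, nodes=("A", "B", "C", "D", "E", "F", "G", "H")):
    pairs = all_pairs(nodes)
    n_pos = int(rng.integers(2, len(pairs) - 2))
    positives = {pairs[k] for k in rng.choice(len(pairs), n_pos, replace=False)}
    gold = GoldStandard(nodes, frozenset(positives))
    scores = {p: float(rng.integers(0, 6)) for p in pairs}
    ranking = RankedEdgeList.from_scores(scores)
    return ranking, gold, pairs, scores


class TestMetrics:
    def test_perfect_ranking_is_one(self):
        nodes = ("A", "B", "C")
        gold = GoldStandard(nodes, frozenset({("A", "B")}))
        rk = RankedEdgeList.from_scores({("A", "B"): 5, ("A", "C"): 1,
                                         ("B", "C"): 0})
        assert auroc(rk, gold, nodes) == 1.0
        assert auprc(rk, gold, nodes) == 1.0

    def test_constant_scores_give_half_auroc(self):
        nodes = ("A", "B", "C", "D")
        gold = GoldStandard(nodes, frozenset({("A", "B"), ("C", "D")}))
        rk = RankedEdgeList.from_scores({p: 1.0 for p in all_pairs(nodes)})
        assert auroc(rk, gold, nodes) == pytest.approx(0.5)

    def test_single_positive_ranked_last(self):
        nodes = ("A", "B", "C", "D")
        pairs = all_pairs(nodes)  # m = 6
        gold = GoldStandard(nodes, frozenset({pairs[-1]}))
        scores = {p: float(len(pairs) - k) for k, p in enumerate(pairs)}
        rk = RankedEdgeList.from_scores(scores)
        assert auprc(rk, gold, nodes) == pytest.approx(1 / len(pairs))

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(25):
            ranking, gold, pairs, scores = _instance(rng)
            labels = [p in gold.true_edges for p in pairs]
            values = [scores[p] for p in pairs]
            assert auroc(ranking, gold, gold.nodes) == pytest.approx(
                _brute_force_auroc(values, labels), abs=1e-12)
            assert auprc(ranking, gold, gold.nodes) == pytest.approx(
                _brute_force_auprc(values, labels), abs=1e-12)

    def test_matches_sklearn_cross_check(self, rng):
        from sklearn.metrics import average_precision_score, roc_auc_score

        for _ in range(10):
            ranking, gold, pairs, scores = _instance(rng)
            labels = np.array([p in gold.true_edges for p in pairs], dtype=int)
            values = np.array([scores[p] for p in pairs])
            assert auroc(ranking, gold, gold.nodes) == pytest.approx(
                roc_auc_score(labels, values), abs=1e-12)
            assert auprc(ranking, gold, gold.nodes) == pytest.approx(
                average_precision_score(labels, values), abs=1e-12)

    def test_auroc_invariant_to_monotone_transform(self, rng):
        ranking, gold, pairs, scores = _instance(rng)
        transformed = RankedEdgeList.from_scores(
            {p: np.exp(0.5 * s) for p, s in scores.items()})
        assert auroc(ranking, gold, gold.nodes) == pytest.approx(
            auroc(transformed, gold, gold.nodes), abs=1e-12)

    def test_auprc_of_uninformative_ranking_equals_prevalence(self, rng):
        """A single all-tied threshold has precision = prevalence and
        recall 1, so the step area is exactly the prevalence."""
        nodes = ("A", "B", "C", "D", "E")
        pairs = all_pairs(nodes)
        positives = {pairs[k] for k in rng.choice(len(pairs), 4, replace=False)}
        gold = GoldStandard(nodes, frozenset(positives))
        rk = RankedEdgeList.from_scores({p: 1.0 for p in pairs})
        assert auprc(rk, gold, nodes) == pytest.approx(len(positives) / len(pairs))

    def test_unranked_pairs_form_bottom_tie(self):
        nodes = ("A", "B", "C")
        gold = GoldStandard(nodes, frozenset({("A", "B")}))
        rk = RankedEdgeList.from_scores({("A", "B"): 2.0})
        # unranked (A,C), (B,C) score 0 -> positive strictly on top
        assert auroc(rk, gold, nodes) == 1.0

    def test_isolated_gold_nodes_never_evaluated(self):
        nodes = ("A", "B", "C", "Z")
        gold = GoldStandard(nodes, frozenset({("A", "B"), ("B", "C")}))
        eval_nodes = restrict_nodes(gold)
        assert "Z" not in eval_nodes
        rk = RankedEdgeList.from_scores({("A", "Z"): 9.0, ("A", "B"): 2.0,
                                         ("B", "C"): 1.0})
        # the high-scoring pair touching Z must not affect the metric
        assert auroc(rk, gold, eval_nodes) == 1.0
        assert auroc(rk, gold, gold.nodes) < 1.0  # unrestricted: Z pair hurts

    def test_undefined_metrics_raise(self):
        nodes = ("A", "B", "C")
        all_gold = GoldStandard(nodes, frozenset(all_pairs(nodes)))
        none_gold = GoldStandard(nodes, frozenset())
        rk = RankedEdgeList.from_scores({("A", "B"): 1.0})
        with pytest.raises(ValueError, match="AUROC"):
            auroc(rk, all_gold, nodes)
        with pytest.raises(ValueError, match="AUPRC"):
            auprc(rk, none_gold, nodes)

    def test_restriction_to_explicit_pair_subset(self):
        nodes = ("A", "B", "C", "D")
        gold = GoldStandard(nodes, frozenset({("A", "B"), ("C", "D")}))
        rk = RankedEdgeList.from_scores({("A", "B"): 3.0, ("A", "C"): 2.0,
                                         ("C", "D"): 1.0})
        sub = [("A", "B"), ("A", "C")]
        assert auroc(rk, gold, nodes, pairs=sub) == 1.0
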