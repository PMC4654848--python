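"""Skeleton phase of the PC algorithm, plus the PC-lite baseline.

The search starts from a complete (or otherwise seeded) undirected graph
and removes an edge X_i - X_j as soon as a conditioning set Y drawn from
the current adjacency of X_i renders the pair conditionally independent.
Adjacency updates are immediate (classic PC, not PC-stable): with
imperfect sample tests the output therefore depends on the variable
ordering order(V), a property the prior-guided variant deliberately
exploits.  With perfect CI answers the output is the true skeleton for
every ordering.

PC-lite replaces the zero-order pass with a hard cut: only the n_keep
pairs of highest marginal |correlation| enter the graph, and CI testing
proceeds from order 1.
"""

from __future__ import annotations

import itertools
import warnings
from typing import Iterable, Mapping, Sequence

from .ci_engine import CICallable, CITestConfig, correlation_matrix
from .io_model import ExpressionDataset, Pair, Skeleton, all_pairs, canon_pair

__all__ = ["WorkingGraph", "pc_skeleton", "pc_lite", "rank_pairs_by_correlation"]


class WorkingGraph:
    """Mutable undirected adjacency with a record of separation sets.

    Adjacency is kept symmetric at all times; a removed edge never
    re-enters.
    """

    def __init__(self, nodes: Sequence[str], edges: Iterable[Pair]):
        self.nodes = tuple(nodes)
        self.adj: dict[str, set[str]] = {v: set() for v in self.nodes}
        for a, b in edges:
            self.adj[a].add(b)
            self.adj[b].add(a)
        self.sep_sets: dict[Pair, frozenset[str]] = {}

    def has_edge(self, a: str, b: str) -> bool:
        return b in self.adj[a]

    def remove_edge(self, a: str, b: str, sep: Iterable[str]) -> None:
        self.adj[a].discard(b)
        self.adj[b].discard(a)
        self.sep_sets[canon_pair(a, b)] = frozenset(sep)

    def edges(self) -> frozenset[Pair]:
        return frozenset(
            canon_pair(a, b) for a in self.nodes for b in self.adj[a] if a < b
        )

    def to_skeleton(self) -> Skeleton:
        return Skeleton(self.nodes, self.edges())


def _test_pair_at_order(graph: WorkingGraph, ci: CICallable, x: str, y: str,
                        order: int, rank: Mapping[str, int],
                        diagnostics: dict | None) -> bool:
    """Try to remove edge x-y with conditioning sets of size ``order``
    drawn from adj(x) \\ {y}; returns True if the edge was removed.

    Candidate sets are enumerated in lexicographic order of the variable
    ordering (combinations of the rank-sorted neighbour list).
    """
    neighbours = sorted(graph.adj[x] - {y}, key=rank.__getitem__)
    if len(neighbours) < order:
        return False
    fast_scan = getattr(ci, "first_separating_subset", None)
    if fast_scan is not None:
        before = ci.tests_per_order.get(order, 0)
        sep = fast_scan(x, y, neighbours, order)
        if diagnostics is not None:
            key = ("tests", order)
            diagnostics[key] = (diagnostics.get(key, 0)
                                + ci.tests_per_order.get(order, 0) - before)
        if sep is not None:
            graph.remove_edge(x, y, sep)
            return True
        return False
    for Y in itertools.combinations(neighbours, order):
        if diagnostics is not None:
            key = ("tests", order)
            diagnostics[key] = diagnostics.get(key, 0) + 1
        if ci(x, y, Y):
            graph.remove_edge(x, y, Y)
            return True
    return False


def pc_skeleton(ci: CICallable, variables: Sequence[str],
                ordering: Sequence[str] | None = None,
                config: CITestConfig | None = None,
                initial_edges: Iterable[Pair] | None = None,
                start_order: int = 0,
                diagnostics: dict | None = None) -> Skeleton:
    """Estimate the skeleton by iterative CI testing.

    Parameters
    ----------
    ci
        CI callable ``ci(i, j, Y) -> bool`` (True = independent): either
        a sample-based tester or a d-separation oracle.
    variables
        Node identifiers.
    ordering
        Processing order over the variables (order(V)); defaults to the
        lexicographical ordering.  Governs both the pair scan and the
        enumeration of conditioning sets.
    initial_edges, start_order
        Seed graph and first order tested; the defaults (complete graph,
        order 0) give the classic algorithm.
    diagnostics
        Optional dict populated with ("tests", order) counters.
    """
    config = config or CITestConfig()
    variables = tuple(variables)
    if ordering is None:
        ordering = sorted(variables)
    if sorted(ordering) != sorted(variables):
        raise ValueError("ordering must be a permutation of the variables")
    rank = {v: k for k, v in enumerate(ordering)}

    if initial_edges is None:
        initial_edges = all_pairs(variables)
    graph = WorkingGraph(variables, initial_edges)

    for order in range(start_order, config.max_order + 1):
        ordered = sorted(variables, key=rank.__getitem__)
        any_testable = any(
            len(graph.adj[x] - {y}) >= order
            for x in ordered for y in graph.adj[x]
        )
        if not any_testable:
            break
        for x in ordered:
            for y in sorted(graph.adj[x], key=rank.__getitem__):
                if not graph.has_edge(x, y):  # removed earlier in this sweep
                    continue
                _test_pair_at_order(graph, ci, x, y, order, rank, diagnostics)
    return graph.to_skeleton()


def rank_pairs_by_correlation(data: ExpressionDataset) -> list[Pair]:
    """All pairs sorted by marginal |correlation| descending, ties
    broken lexicographically by canonical pair."""
    stats = correlation_matrix(data)
    idx = {v: k for k, v in enumerate(data.variables)}
    pairs = all_pairs(data.variables)
    return sorted(pairs, key=lambda p: (-stats.C[idx[p[0]], idx[p[1]]], p))


def pc_lite(data: ExpressionDataset, n_keep: int,
            ordering: Sequence[str] | None = None,
            config: CITestConfig | None = None,
            ci: CICallable | None = None,
            diagnostics: dict | None = None) -> Skeleton:
    """PC seeded with the top-``n_keep`` marginal-correlation pairs.

    Zero-order tests are skipped entirely; CI testing runs over orders
    1..max_order on the seeded graph only.  ``ci`` defaults to the
    sample-based Gaussian tester on ``data``.
    """
    if n_keep < 1:
        raise ValueError("n_keep must be >= 1")
    ranked = rank_pairs_by_correlation(data)
    if n_keep > len(ranked):
        warnings.warn(
            f"n_keep={n_keep} exceeds the {len(ranked)} available pairs; keeping all"
        )
        n_keep = len(ranked)
    if ci is None:
        from .ci_engine import make_ci_tester

        ci = make_ci_tester(data, config)
    return pc_skeleton(ci, data.variables, ordering=ordering, config=config,
                       initial_edges=ranked[:n_keep], start_order=1,
                       diagnostics=diagnostics)
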