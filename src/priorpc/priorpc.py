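"""Prior-guided skeleton search: confidence scores, edge discarding and
the 3-tier CI-test schedule.

Each candidate edge X_i - X_j receives a confidence score

    s_ij = alpha * b_ij + (1 - alpha) * d_ij,

mixing the prior belief b_ij with a data score d_ij.  The data score is
a CLR-style background correction of the absolute correlation matrix C:
the product of the two normalised deviations of C_ij from the
correlation background of gene i and of gene j,

    e_ij = |(C_ij - mu_i) / sigma_i| * |(C_ij - mu_j) / sigma_j|
    d_ij = e_ij / sqrt(e_ii * e_jj)
         = |(C_ij - mu_i) / (1 - mu_i)| * |(C_ij - mu_j) / (1 - mu_j)|,

where mu_i, sigma_i summarise |cor(X_i, .)| over all other genes and
C_ii = 1.  d_ij is used for ranking only and is deliberately not
clipped to [0, 1].

The search then (a) keeps only the n_keep highest-confidence edges
(replacing all zero-order CI tests; n_keep is about three times the
expected edge count), (b) splits them into weak / average / strong
thirds by confidence, and (c) runs CI tests of order 1..max_order tier
by tier — weak candidates first, strong last — over one shared working
graph, so that unlikely edges are removed before they can corrupt the
neighbourhoods used to test likely ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .ci_engine import (CICallable, CITestConfig, CorrelationStats,
                        correlation_matrix, make_ci_tester)
from .io_model import ExpressionDataset, Pair, PriorMatrix, Skeleton, canon_pair
from .pc_skeleton import WorkingGraph, _test_pair_at_order

__all__ = [
    "ConfidenceScores",
    "TierAssignment",
    "data_score",
    "confidence_scores",
    "discard_worst",
    "assign_tiers",
    "priorpc_skeleton",
    "default_n_keep",
]


@dataclass(frozen=True)
class ConfidenceScores:
    """Per-pair scores: raw data score e, normalised data score d, and —
    once a prior has been mixed in — the confidence s with its weight
    alpha.  All matrices are symmetric; diagonals are unset (NaN)."""

    variables: tuple[str, ...]
    e: np.ndarray
    d: np.ndarray
    s: np.ndarray | None = None
    alpha: float | None = None

    def pair_score(self, a: str, b: str, which: str = "s") -> float:
        m = getattr(self, which)
        if m is None:
            raise ValueError(f"score matrix {which!r} not computed")
        i, j = self.variables.index(a), self.variables.index(b)
        return float(m[i, j])

    def score_map(self, which: str = "s") -> dict[Pair, float]:
        m = getattr(self, which)
        if m is None:
            raise ValueError(f"score matrix {which!r} not computed")
        out: dict[Pair, float] = {}
        for i in range(len(self.variables)):
            for j in range(i + 1, len(self.variables)):
                out[canon_pair(self.variables[i], self.variables[j])] = float(m[i, j])
        return out


@dataclass(frozen=True)
class TierAssignment:
    """Retained edges split into strong / average / weak candidates.

    Tiers are disjoint, cover exactly the retained set, and their sizes
    differ by at most one (remainder edges go to the earlier tiers).
    ``strong`` holds the highest confidence scores.
    """

    strong: tuple[Pair, ...]
    average: tuple[Pair, ...]
    weak: tuple[Pair, ...]

    def __post_init__(self) -> None:
        groups = (self.strong, self.average, self.weak)
        sizes = [len(g) for g in groups]
        if max(sizes) - min(sizes) > 1:
            raise ValueError("tier sizes must differ by at most 1")
        flat = [e for g in groups for e in g]
        if len(set(flat)) != len(flat):
            raise ValueError("tiers must be disjoint")

    @property
    def all_edges(self) -> frozenset[Pair]:
        return frozenset(self.strong) | frozenset(self.average) | frozenset(self.weak)


def data_score(stats: CorrelationStats) -> ConfidenceScores:
    """CLR-like data scores e_ij (raw) and d_ij (normalised) from the
    absolute correlation matrix.

    A gene with a constant correlation profile (sigma_i = 0) gets all
    its e scores set to 0 with a warning; a gene with mu_i = 1 makes
    the d normalisation degenerate and raises.
    """
    C, mu, sigma = stats.C, stats.mu, stats.sigma
    p = C.shape[0]
    degenerate = np.flatnonzero(np.isclose(mu, 1.0))
    if degenerate.size:
        names = ", ".join(stats.variables[k] for k in degenerate)
        raise ValueError(
            f"degenerate correlation profile (mu_i = 1) for gene(s): {names}"
        )
    sigma_safe = sigma.copy()
    flat = np.flatnonzero(sigma == 0.0)
    if flat.size:
        names = ", ".join(stats.variables[k] for k in flat)
        warnings.warn(
            f"constant correlation profile (sigma_i = 0) for gene(s) {names}; "
            "their e scores are set to 0"
        )
        sigma_safe[flat] = np.inf
    zi = np.abs((C - mu[:, None]) / sigma_safe[:, None])   # row-wise z
    e = zi * zi.T
    di = np.abs((C - mu[:, None]) / (1.0 - mu[:, None]))
    d = di * di.T
    np.fill_diagonal(e, np.nan)
    np.fill_diagonal(d, np.nan)
    return ConfidenceScores(stats.variables, e, d)


def confidence_scores(B: PriorMatrix, scores: ConfidenceScores,
                      alpha: float) -> ConfidenceScores:
    """Mix prior beliefs and data scores: s = alpha*B + (1-alpha)*d."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    if tuple(B.variables) != tuple(scores.variables):
        raise ValueError("prior matrix and data scores use different variables")
    s = alpha * B.beliefs + (1.0 - alpha) * scores.d
    np.fill_diagonal(s, np.nan)
    return ConfidenceScores(scores.variables, scores.e, scores.d, s, alpha)


def _ranked_pairs(scores: Mapping[Pair, float]) -> list[Pair]:
    return sorted(scores, key=lambda p: (-scores[p], p))


def discard_worst(scores: ConfidenceScores, n_keep: int) -> list[Pair]:
    """Retain the n_keep pairs of highest confidence (ties broken
    lexicographically); everything else is permanently excluded.

    This step replaces the zero-order CI tests of the classic search.
    Returns the retained pairs in decreasing confidence order.
    """
    if n_keep < 3:
        raise ValueError("n_keep must be >= 3 so that all tiers are non-empty")
    smap = scores.score_map("s")
    ranked = _ranked_pairs(smap)
    if n_keep > len(ranked):
        warnings.warn(
            f"n_keep={n_keep} exceeds the {len(ranked)} available pairs; keeping all"
        )
        n_keep = len(ranked)
    return ranked[:n_keep]


def assign_tiers(retained: Sequence[Pair],
                 scores: ConfidenceScores) -> TierAssignment:
    """Split the retained edges into thirds by confidence score.

    Top third = strong candidates, bottom third = weak; when the count
    is not divisible by 3 the remainder goes to the earlier-listed
    tiers (strong, then average), so sizes differ by at most 1.
    """
    if not retained:
        raise ValueError("retained edge set is empty")
    smap = scores.score_map("s")
    ranked = sorted(retained, key=lambda p: (-smap[p], p))
    n = len(ranked)
    base, rem = divmod(n, 3)
    n_strong = base + (1 if rem >= 1 else 0)
    n_average = base + (1 if rem >= 2 else 0)
    strong = tuple(ranked[:n_strong])
    average = tuple(ranked[n_strong:n_strong + n_average])
    weak = tuple(ranked[n_strong + n_average:])
    return TierAssignment(strong, average, weak)


def default_n_keep(expected_edges: int) -> int:
    """The retained-edge budget N_E = 3 x |E| for an expected edge count."""
    if expected_edges < 1:
        raise ValueError("expected edge count must be >= 1")
    return int(round(3 * expected_edges))


def priorpc_skeleton(data: ExpressionDataset, B: PriorMatrix, alpha: float,
                     n_keep: int,
                     ordering: Sequence[str] | None = None,
                     config: CITestConfig | None = None,
                     ci: CICallable | None = None,
                     diagnostics: dict | None = None) -> Skeleton:
    """Full prior-guided skeleton estimate.

    Pipeline: data score -> confidence score -> discard all but the
    n_keep best edges -> tier split -> tiered CI phase.  The CI phase
    runs orders 1..max_order for the weak tier first, then average,
    then strong, over a single shared working graph: conditioning sets
    come from the *current* adjacency, which spans all tiers, and an
    edge removed in an early tier is gone for good.

    Within a tier, edges are processed in increasing confidence order
    (least-believed first, ties lexicographic).  ``ci`` defaults to the
    sample-based Gaussian tester; ``ordering`` (default lexicographic)
    governs conditioning-set enumeration.
    """
    config = config or CITestConfig()
    stats = correlation_matrix(data)
    scored = confidence_scores(B, data_score(stats), alpha)
    retained = discard_worst(scored, n_keep)
    tiers = assign_tiers(retained, scored)

    if ci is None:
        ci = make_ci_tester(data, config)
    if ordering is None:
        ordering = sorted(data.variables)
    if sorted(ordering) != sorted(data.variables):
        raise ValueError("ordering must be a permutation of the variables")
    rank = {v: k for k, v in enumerate(ordering)}
    smap = scored.score_map("s")

    graph = WorkingGraph(data.variables, retained)
    if diagnostics is not None:
        diagnostics["n_retained"] = len(retained)
        diagnostics["tier_sizes"] = {
            "strong": len(tiers.strong),
            "average": len(tiers.average),
            "weak": len(tiers.weak),
        }

    for tier_name, tier_edges in (("weak", tiers.weak),
                                  ("average", tiers.average),
                                  ("strong", tiers.strong)):
        for order in range(1, config.max_order + 1):
            # least-believed surviving edges first
            survivors = sorted(
                (e for e in tier_edges if graph.has_edge(*e)),
                key=lambda p: (smap[p], p),
            )
            if not survivors:
                break
            for a, b in survivors:
                for x, y in ((a, b), (b, a)):
                    if not graph.has_edge(x, y):
                        break
                    if _test_pair_at_order(graph, ci, x, y, order, rank,
                                           diagnostics):
                        break
    return graph.to_skeleton()
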