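"""Conditional-independence machinery for Gaussian skeleton learning.

Under the multivariate-Gaussian assumption a conditional independence
(X_i indep X_j | Y) is equivalent to a zero partial correlation
cor(X_i, X_j | Y).  The decision rule used throughout is

    |z(r)| * sqrt(n - |Y| - 3) <= t        ->  independent,

where z is Fisher's z-transform and t > 0 the decision threshold
(t = 0.1 by default; ``threshold_from_significance`` converts a
two-sided significance level beta into t = Phi^-1(1 - beta/2)).

A d-separation oracle over a known DAG provides *perfect* CI answers
with the same calling convention, for exact testing of the search
procedures.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import networkx as nx
import numpy as np
from scipy import stats as sps

from .io_model import ExpressionDataset

__all__ = [
    "CorrelationStats",
    "CITestConfig",
    "TrueDag",
    "correlation_matrix",
    "partial_correlation",
    "fisher_z",
    "ci_statistic",
    "is_independent",
    "threshold_from_significance",
    "GaussianCITester",
    "make_ci_tester",
    "dsep_oracle",
]

#: CI callables answer ci(i, j, Y) -> bool (True = independent), where
#: i, j are variable names and Y an iterable of variable names.
CICallable = Callable[[str, str, Iterable[str]], bool]

# correlations at least this close to +/-1 are treated as dependent
# without transforming, to avoid infinities in Fisher's z
_SATURATION = 1.0 - 1e-12


@dataclass(frozen=True)
class CITestConfig:
    """Parameters of the sample CI test.

    t
        Decision threshold on |z|*sqrt(n-|Y|-3); 0.1 unless overridden.
    max_order
        Largest conditioning-set size attempted by the search (5).
    shrinkage
        If True, partial correlations are computed from a Ledoit-Wolf
        shrunk covariance estimated once per dataset, instead of the
        plain sample covariance.
    """

    t: float = 0.1
    max_order: int = 5
    shrinkage: bool = False

    def __post_init__(self) -> None:
        if self.t <= 0:
            raise ValueError("threshold t must be > 0")
        if self.max_order < 0:
            raise ValueError("max_order must be >= 0")


def threshold_from_significance(beta: float) -> float:
    """t = Phi^-1(1 - beta/2) for a two-sided test at level beta."""
    if not 0.0 < beta < 1.0:
        raise ValueError("significance level must lie in (0, 1)")
    return float(sps.norm.ppf(1.0 - beta / 2.0))


@dataclass(frozen=True)
class CorrelationStats:
    """Absolute correlation matrix with per-gene background statistics.

    ``mu[i]`` and ``sigma[i]`` are the mean and (population) standard
    deviation of the |correlations| between gene i and all *other*
    genes — the diagonal is excluded, so each is computed over exactly
    |V| - 1 values.
    """

    variables: tuple[str, ...]
    C: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray


@dataclass(frozen=True)
class TrueDag:
    """A known directed acyclic graph: generator output and oracle input."""

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", tuple(self.nodes))
        object.__setattr__(self, "edges", tuple((a, b) for a, b in self.edges))
        g = self.to_networkx()
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("graph contains a directed cycle")

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def skeleton_edges(self) -> frozenset[tuple[str, str]]:
        from .io_model import canon_pair

        return frozenset(canon_pair(a, b) for a, b in self.edges)


# ---------------------------------------------------------------------------
# Correlation statistics
# ---------------------------------------------------------------------------


def correlation_matrix(data: ExpressionDataset) -> CorrelationStats:
    """Absolute Pearson correlation matrix with row background mu_i, sigma_i.

    Raises if any gene has zero variance (its correlations are undefined).
    """
    if data.n < 3:
        raise ValueError("need at least 3 samples to estimate correlations")
    sd = data.matrix.std(axis=1)
    dead = np.flatnonzero(sd == 0.0)
    if dead.size:
        names = ", ".join(data.variables[k] for k in dead)
        raise ValueError(f"zero-variance gene(s): {names}")
    C = np.abs(np.corrcoef(data.matrix))
    np.fill_diagonal(C, 1.0)
    p = C.shape[0]
    off = C[~np.eye(p, dtype=bool)].reshape(p, p - 1)
    mu = off.mean(axis=1)
    sigma = off.std(axis=1)
    return CorrelationStats(data.variables, C, mu, sigma)


# ---------------------------------------------------------------------------
# Partial correlation and the CI decision
# ---------------------------------------------------------------------------


def fisher_z(r: float) -> float:
    """Fisher's z-transform, (1/2) log((1+r)/(1-r)); odd in r."""
    if abs(r) >= 1.0:
        raise ValueError(f"|r| must be < 1, got {r}")
    return math.atanh(r)


def ci_statistic(r: float, n: int, k: int) -> float:
    """|z(r)| * sqrt(n - k - 3) for a conditioning set of size k."""
    dof = n - k - 3
    if dof < 1:
        raise ValueError(f"insufficient samples for order {k}: n - k - 3 = {dof} < 1")
    return abs(fisher_z(r)) * math.sqrt(dof)


class GaussianCITester:
    """Sample-based CI tester over one dataset.

    Precomputes the covariance matrix once; each query inverts the
    covariance submatrix over {i, j} union Y.  Instances are callable
    with the common CI signature and count queries per order in
    ``tests_per_order`` (diagnostic; reset with ``reset_counts``).
    """

    def __init__(self, data: ExpressionDataset, config: CITestConfig | None = None):
        self.data = data
        self.config = config or CITestConfig()
        self._index = {v: k for k, v in enumerate(data.variables)}
        if self.config.shrinkage:
            from sklearn.covariance import LedoitWolf

            lw = LedoitWolf().fit(data.matrix.T)
            self._cov = lw.covariance_
        else:
            self._cov = np.cov(data.matrix)
        self.tests_per_order: dict[int, int] = {}

    def reset_counts(self) -> None:
        self.tests_per_order = {}

    def partial_correlation(self, i: str, j: str, Y: Iterable[str]) -> float:
        """cor(X_i, X_j | Y) via inversion of the covariance submatrix."""
        yi = [self._index[v] for v in Y]
        a, b = self._index[i], self._index[j]
        if a == b:
            raise ValueError("i and j must differ")
        if a in yi or b in yi:
            raise ValueError("conditioning set must exclude i and j")
        if self.data.n - len(yi) - 3 < 1:
            raise ValueError(
                f"insufficient samples for order {len(yi)}: "
                f"n - |Y| - 3 = {self.data.n - len(yi) - 3} < 1"
            )
        idx = [a, b, *yi]
        sub = self._cov[np.ix_(idx, idx)]
        if not yi:  # order 0 reduces exactly to Pearson correlation
            denom = sub[0, 0] * sub[1, 1]
            if denom <= 0:
                raise ValueError("zero-variance variable in correlation")
            r = sub[0, 1] / math.sqrt(denom)
            return float(min(1.0, max(-1.0, r)))
        try:
            prec = np.linalg.inv(sub)
        except np.linalg.LinAlgError:
            raise ValueError(
                "singular covariance submatrix; consider shrinkage "
                "(CITestConfig(shrinkage=True))"
            ) from None
        denom = prec[0, 0] * prec[1, 1]
        if denom <= 0:
            raise ValueError(
                "covariance submatrix not positive definite; consider shrinkage "
                "(CITestConfig(shrinkage=True))"
            )
        r = -prec[0, 1] / math.sqrt(denom)
        return float(min(1.0, max(-1.0, r)))

    def first_separating_subset(self, x: str, y: str,
                                neighbours: Sequence[str],
                                order: int) -> tuple[str, ...] | None:
        """First conditioning set of size ``order`` (in lexicographic
        enumeration order over ``neighbours``) that renders x and y
        independent, or None.

        Semantically identical to calling the tester on each subset in
        turn, but evaluates the partial correlations in vectorised
        chunks; ``tests_per_order`` is advanced by the number of
        subsets a sequential scan would have examined.
        """
        import itertools

        k = order
        if self.data.n - k - 3 < 1:
            warnings.warn(
                f"order-{k} tests skipped (n={self.data.n} too small); "
                "pair treated as dependent"
            )
            return None
        a, b = self._index[x], self._index[y]
        nbr_idx = [self._index[v] for v in neighbours]
        factor = math.sqrt(self.data.n - k - 3)
        combos = itertools.combinations(range(len(neighbours)), k)
        chunk_size = 128
        examined = 0
        while True:
            chunk = list(itertools.islice(combos, chunk_size))
            if not chunk:
                break
            idx = np.empty((len(chunk), k + 2), dtype=np.intp)
            idx[:, 0] = a
            idx[:, 1] = b
            for r, combo in enumerate(chunk):
                idx[r, 2:] = [nbr_idx[c] for c in combo]
            sub = self._cov[idx[:, :, None], idx[:, None, :]]
            try:
                prec = np.linalg.inv(sub)
                denom = prec[:, 0, 0] * prec[:, 1, 1]
                with np.errstate(invalid="ignore", divide="ignore"):
                    r_vals = np.where(denom > 0,
                                      -prec[:, 0, 1] / np.sqrt(denom), 1.0)
            except np.linalg.LinAlgError:
                # rare singular submatrix: fall back to one-by-one
                r_vals = np.empty(len(chunk))
                for r, combo in enumerate(chunk):
                    try:
                        r_vals[r] = self.partial_correlation(
                            x, y, [neighbours[c] for c in combo])
                    except ValueError:
                        r_vals[r] = 1.0  # treat as dependent
            r_vals = np.clip(r_vals, -1.0, 1.0)
            with np.errstate(divide="ignore"):
                stat = np.abs(np.arctanh(r_vals)) * factor
            independent = (np.abs(r_vals) < _SATURATION) & (stat <= self.config.t)
            hits = np.flatnonzero(independent)
            if hits.size:
                examined += int(hits[0]) + 1
                self.tests_per_order[k] = (
                    self.tests_per_order.get(k, 0) + examined)
                combo = chunk[int(hits[0])]
                return tuple(neighbours[c] for c in combo)
            examined += len(chunk)
        self.tests_per_order[k] = self.tests_per_order.get(k, 0) + examined
        return None

    def __call__(self, i: str, j: str, Y: Iterable[str]) -> bool:
        Y = tuple(Y)
        k = len(Y)
        self.tests_per_order[k] = self.tests_per_order.get(k, 0) + 1
        if self.data.n - k - 3 < 1:
            warnings.warn(
                f"order-{k} test skipped (n={self.data.n} too small); "
                "pair treated as dependent"
            )
            return False
        r = self.partial_correlation(i, j, Y)
        if abs(r) >= _SATURATION:
            return False  # saturated correlation: clearly dependent
        return ci_statistic(r, self.data.n, k) <= self.config.t


def make_ci_tester(data: ExpressionDataset,
                   config: CITestConfig | None = None) -> GaussianCITester:
    """Build the sample-based CI callable for a dataset."""
    return GaussianCITester(data, config)


def partial_correlation(data: ExpressionDataset, i: str, j: str,
                        Y: Iterable[str]) -> float:
    """Sample partial correlation cor(X_i, X_j | Y); |Y| = 0 reduces to
    the plain Pearson correlation."""
    return GaussianCITester(data).partial_correlation(i, j, tuple(Y))


def is_independent(data: ExpressionDataset, i: str, j: str, Y: Iterable[str],
                   config: CITestConfig | None = None) -> bool:
    """Decide (X_i indep X_j | Y) from the data at threshold config.t."""
    return GaussianCITester(data, config)(i, j, tuple(Y))


# ---------------------------------------------------------------------------
# d-separation oracle
# ---------------------------------------------------------------------------


def dsep_oracle(dag: TrueDag) -> CICallable:
    """Perfect CI test: answers queries by d-separation in ``dag``.

    Returned callable has the common CI signature; queries are memoised
    so repeated sweeps over the same graph are cheap.
    """
    g = dag.to_networkx()
    nodes = set(dag.nodes)
    cache: dict[tuple[str, str, frozenset[str]], bool] = {}

    def ci(i: str, j: str, Y: Iterable[str]) -> bool:
        ys = frozenset(Y)
        if i not in nodes or j not in nodes or not ys <= nodes:
            unknown = ({i, j} | ys) - nodes
            raise ValueError(f"query variables not in DAG: {sorted(unknown)}")
        a, b = (i, j) if i < j else (j, i)
        key = (a, b, ys)
        if key not in cache:
            cache[key] = nx.is_d_separator(g, {a}, {b}, set(ys))
        return cache[key]

    return ci
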