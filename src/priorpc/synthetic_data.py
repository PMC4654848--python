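"""Synthetic benchmarks: random sparse DAGs and linear-Gaussian
steady-state expression data.

The generator emulates the scale of the DREAM4 in-silico 100-gene
benchmark — about 100 genes, 176 regulatory interactions and 100
steady-state samples — but draws data from a linear structural
equation model with Gaussian noise rather than a kinetic simulator:
each gene is a weighted sum of its regulators plus independent noise,
with structural weights bounded away from zero (|w| in [0.4, 1.0] by
default) so conditional-independence signal is detectable at n ~ 100.
All generation is a pure function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ci_engine import TrueDag
from .io_model import ExpressionDataset, GoldStandard

__all__ = ["BenchmarkSpec", "random_dag", "sample_linear_gaussian", "make_benchmark"]


@dataclass(frozen=True)
class BenchmarkSpec:
    """Size and signal parameters of one synthetic benchmark.

    Defaults mirror the DREAM4 100-gene scale: 100 nodes, 176 true
    interactions, 100 samples; weights are uniform on
    +/-[weight_lo, weight_hi]; noise_sd is the standard deviation of
    each gene's additive Gaussian noise (expression is in arbitrary
    units and not re-standardised — correlation is scale-invariant).
    """

    n_nodes: int = 100
    n_edges: int = 176
    n_samples: int = 100
    weight_lo: float = 0.4
    weight_hi: float = 1.0
    noise_sd: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("need at least 2 nodes")
        max_edges = self.n_nodes * (self.n_nodes - 1) // 2
        if not 0 <= self.n_edges <= max_edges:
            raise ValueError(
                f"n_edges={self.n_edges} infeasible for {self.n_nodes} nodes "
                f"(max {max_edges})"
            )
        if self.n_samples < 1:
            raise ValueError("need at least 1 sample")
        if not 0 < self.weight_lo <= self.weight_hi:
            raise ValueError("weight range must satisfy 0 < lo <= hi")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


def _node_names(n: int) -> tuple[str, ...]:
    width = len(str(n))
    return tuple(f"G{k + 1:0{width}d}" for k in range(n))


def random_dag(spec: BenchmarkSpec) -> TrueDag:
    """Uniform random topological order, then ``n_edges`` distinct
    forward pairs chosen uniformly; acyclic by construction."""
    rng = np.random.default_rng(spec.seed)
    names = _node_names(spec.n_nodes)
    order = rng.permutation(spec.n_nodes)
    pairs = [(i, j) for i in range(spec.n_nodes) for j in range(i + 1, spec.n_nodes)]
    picks = rng.choice(len(pairs), size=spec.n_edges, replace=False)
    edges = tuple(
        (names[order[pairs[k][0]]], names[order[pairs[k][1]]]) for k in sorted(picks)
    )
    return TrueDag(names, edges)


def sample_linear_gaussian(dag: TrueDag, spec: BenchmarkSpec) -> ExpressionDataset:
    """Draw i.i.d. samples from the linear-Gaussian model on ``dag``.

    Each node is the weighted sum of its parents plus N(0, noise_sd)
    noise, computed in topological order; weights are drawn once,
    uniform in magnitude on [weight_lo, weight_hi] with random sign.
    The weight/noise stream is independent of the structure stream
    (seed offset), so the same spec used for both steps stays coherent.
    """
    rng = np.random.default_rng(
        None if spec.seed is None else np.random.SeedSequence([spec.seed, 1])
    )
    import networkx as nx

    g = dag.to_networkx()
    topo = list(nx.topological_sort(g))
    idx = {v: k for k, v in enumerate(dag.nodes)}
    weights = {
        e: rng.uniform(spec.weight_lo, spec.weight_hi) * rng.choice([-1.0, 1.0])
        for e in dag.edges
    }
    X = np.zeros((len(dag.nodes), spec.n_samples))
    for node in topo:
        noise = rng.normal(0.0, spec.noise_sd, size=spec.n_samples)
        total = noise
        for parent in g.predecessors(node):
            total = total + weights[(parent, node)] * X[idx[parent]]
        X[idx[node]] = total
    return ExpressionDataset(dag.nodes, X)


def make_benchmark(spec: BenchmarkSpec
                   ) -> tuple[ExpressionDataset, GoldStandard, TrueDag]:
    """One complete benchmark bundle: data, undirected gold standard,
    and the generating DAG."""
    dag = random_dag(spec)
    data = sample_linear_gaussian(dag, spec)
    gold = GoldStandard(dag.nodes, dag.skeleton_edges())
    return data, gold, dag
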