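"""Synthetic prior-knowledge matrices derived from a gold standard.

A *true* prior for a pair is a belief drawn uniformly from (0.5, 1.0]
when the pair is a gold-standard edge and from [0.0, 0.5) otherwise;
0.5 is the non-informative default for pairs that receive no prior.
Corruption models: additive Gaussian noise that always pushes beliefs
the wrong way (down for true edges, up for non-edges), and outright
flips b <- 1 - b.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_model import GoldStandard, Pair, PriorMatrix, all_pairs

__all__ = ["NoiseModel", "true_priors", "noisy_priors", "flipped_priors"]


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian corruption of prior beliefs: per-pair e ~ N(0, sigma)."""

    sigma: float
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("noise sigma must be >= 0")


def _pair_indices(variables: tuple[str, ...]) -> dict[Pair, tuple[int, int]]:
    idx = {v: k for k, v in enumerate(variables)}
    return {p: (idx[p[0]], idx[p[1]]) for p in all_pairs(variables)}


def _sample_true_belief(rng: np.random.Generator, is_edge: bool) -> float:
    # (0.5, 1.0] for edges, [0.0, 0.5) for non-edges
    u = rng.uniform(0.0, 0.5)
    return 1.0 - u if is_edge else u


def true_priors(gold: GoldStandard, coverage: float,
                seed: int | None = None) -> PriorMatrix:
    """Assign true priors to a random ``coverage`` fraction of all pairs.

    A selected pair gets a belief in (0.5, 1] if it is a gold edge and
    in [0, 0.5) otherwise; unselected pairs stay at 0.5.  Selection is
    over all node pairs of the complete graph.
    """
    if not 0.0 <= coverage <= 1.0:
        raise ValueError(f"coverage must lie in [0, 1], got {coverage}")
    rng = np.random.default_rng(seed)
    variables = tuple(sorted(gold.nodes))
    pairs = all_pairs(variables)
    n_select = int(round(coverage * len(pairs)))
    chosen = rng.choice(len(pairs), size=n_select, replace=False)
    beliefs = np.full((len(variables), len(variables)), 0.5)
    pidx = _pair_indices(variables)
    for k in sorted(chosen):
        pair = pairs[k]
        b = _sample_true_belief(rng, pair in gold.true_edges)
        i, j = pidx[pair]
        beliefs[i, j] = beliefs[j, i] = b
    return PriorMatrix(variables, beliefs)


def noisy_priors(B: PriorMatrix, gold: GoldStandard,
                 noise: NoiseModel) -> PriorMatrix:
    """Corrupt beliefs adversarially with |e|, e ~ N(0, sigma), per pair:
    gold edges get b - |e|, non-edges b + |e|; results clamped to [0, 1]."""
    rng = np.random.default_rng(noise.seed)
    variables = B.variables
    beliefs = B.beliefs.copy()
    edges = gold.true_edges
    for pair, (i, j) in _pair_indices(variables).items():
        e = abs(rng.normal(0.0, noise.sigma)) if noise.sigma > 0 else 0.0
        b = beliefs[i, j] + (-e if pair in edges else e)
        beliefs[i, j] = beliefs[j, i] = min(1.0, max(0.0, b))
    return PriorMatrix(variables, beliefs)


def flipped_priors(gold: GoldStandard, true_edge_coverage: float,
                   n_false: int, seed: int | None = None) -> PriorMatrix:
    """True priors on a fraction of the gold edges plus ``n_false``
    flipped priors elsewhere.

    A ``true_edge_coverage`` fraction of the gold edges receives a
    belief in (0.5, 1]; then ``n_false`` pairs drawn from the remaining
    pairs receive a true prior that is immediately flipped via
    b <- 1 - b (so a flipped gold edge ends below 0.5 and a flipped
    non-edge above 0.5).  Everything else stays at 0.5.
    """
    if not 0.0 <= true_edge_coverage <= 1.0:
        raise ValueError("true_edge_coverage must lie in [0, 1]")
    if n_false < 0:
        raise ValueError("n_false must be >= 0")
    rng = np.random.default_rng(seed)
    variables = tuple(sorted(gold.nodes))
    beliefs = np.full((len(variables), len(variables)), 0.5)
    pidx = _pair_indices(variables)

    gold_edges = sorted(gold.true_edges)
    n_true = int(round(true_edge_coverage * len(gold_edges)))
    chosen_true = set()
    if n_true:
        picks = rng.choice(len(gold_edges), size=n_true, replace=False)
        chosen_true = {gold_edges[k] for k in sorted(picks)}
    for pair in sorted(chosen_true):
        i, j = pidx[pair]
        beliefs[i, j] = beliefs[j, i] = _sample_true_belief(rng, True)

    remaining = [p for p in all_pairs(variables) if p not in chosen_true]
    if n_false > len(remaining):
        raise ValueError(
            f"n_false={n_false} exceeds the {len(remaining)} unselected pairs"
        )
    if n_false:
        picks = rng.choice(len(remaining), size=n_false, replace=False)
        for k in sorted(picks):
            pair = remaining[k]
            b = _sample_true_belief(rng, pair in gold.true_edges)
            i, j = pidx[pair]
            beliefs[i, j] = beliefs[j, i] = 1.0 - b
    return PriorMatrix(variables, beliefs)
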