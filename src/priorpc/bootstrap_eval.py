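"""Bootstrap consensus edge ranking and AUROC / AUPRC evaluation.

Skeleton searches answer yes/no per edge; to obtain a ranking for ROC
and precision-recall analysis, the chosen algorithm is re-run on K
bootstrap resamples of the samples (columns, drawn with replacement)
and each edge is scored by its frequency of appearance (0..K).  Ties
are broken lexicographically by default; breaking them by a supplied
confidence score is available as an option.

Evaluation follows DREAM conventions: candidate pairs are restricted to
the nodes with at least one gold-standard edge; unranked pairs form a
single bottom tie with score 0; AUROC uses the mid-rank convention and
AUPRC the non-interpolated step summation sum_k (R_k - R_{k-1}) * P_k.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .io_model import (ExpressionDataset, GoldStandard, Pair, RankedEdgeList,
                       Skeleton, all_pairs, canon_pair)

__all__ = [
    "BootstrapConfig",
    "resample_dataset",
    "bootstrap_rank",
    "restrict_nodes",
    "auroc",
    "auprc",
]


@dataclass(frozen=True)
class BootstrapConfig:
    """K resamples (default 20) driven by a master seed; per-resample
    RNG streams are spawned from the master so runs are reproducible
    and independent of execution order."""

    K: int = 20
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")


def resample_dataset(data: ExpressionDataset,
                     rng: np.random.Generator) -> ExpressionDataset:
    """Draw n samples (columns) with replacement."""
    cols = rng.integers(0, data.n, size=data.n)
    return ExpressionDataset(data.variables, data.matrix[:, cols])


def bootstrap_rank(data: ExpressionDataset,
                   algorithm: Callable[[ExpressionDataset], Skeleton],
                   config: BootstrapConfig | None = None,
                   tie_breaker: Mapping[Pair, float] | None = None
                   ) -> RankedEdgeList:
    """Rank edges by their frequency across K bootstrap skeletons.

    ``algorithm`` maps a dataset to a Skeleton and must be
    deterministic given its input.  Ties in frequency are ordered
    lexicographically, or by descending ``tie_breaker`` score (then
    lexicographically) when one is supplied.
    """
    config = config or BootstrapConfig()
    streams = np.random.SeedSequence(config.seed).spawn(config.K)
    counts: dict[Pair, int] = {}
    for k, ss in enumerate(streams):
        resampled = resample_dataset(data, np.random.default_rng(ss))
        try:
            skel = algorithm(resampled)
        except Exception as exc:
            raise RuntimeError(f"algorithm failed on bootstrap resample {k}") from exc
        for edge in skel.edges:
            counts[edge] = counts.get(edge, 0) + 1
    if tie_breaker is None:
        order = sorted(counts, key=lambda p: (-counts[p], p))
    else:
        order = sorted(counts,
                       key=lambda p: (-counts[p], -tie_breaker.get(p, 0.0), p))
    return RankedEdgeList(tuple((p, float(counts[p])) for p in order))


def restrict_nodes(gold: GoldStandard) -> frozenset[str]:
    """Nodes with degree >= 1 in the gold standard; evaluation is
    restricted to pairs within this set."""
    connected = {v for e in gold.true_edges for v in e}
    if not connected:
        raise ValueError("gold standard has no edges")
    return frozenset(connected)


def _evaluation_arrays(ranking: RankedEdgeList, gold: GoldStandard,
                       eval_nodes: Iterable[str],
                       pairs: Sequence[Pair] | None = None
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Scores and 0/1 labels over the evaluated pairs.

    Pairs default to all pairs within ``eval_nodes``; pairs absent from
    the ranking get score 0, forming a single bottom tie.
    """
    if pairs is None:
        pairs = all_pairs(sorted(eval_nodes))
    else:
        node_set = set(eval_nodes)
        pairs = [canon_pair(*p) for p in pairs]
        pairs = [p for p in pairs if p[0] in node_set and p[1] in node_set]
    scored = ranking.scores()
    y = np.array([1 if p in gold.true_edges else 0 for p in pairs])
    s = np.array([scored.get(p, 0.0) for p in pairs])
    return s, y


def auroc(ranking: RankedEdgeList, gold: GoldStandard,
          eval_nodes: Iterable[str],
          pairs: Sequence[Pair] | None = None) -> float:
    """Area under the ROC curve with the mid-rank tie convention.

    Equals the probability that a uniformly drawn gold edge outranks a
    uniformly drawn non-edge, counting ties as 1/2.
    """
    s, y = _evaluation_arrays(ranking, gold, eval_nodes, pairs)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined: need at least one positive and one negative")
    ranks = rankdata(s)  # average ranks for ties
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auprc(ranking: RankedEdgeList, gold: GoldStandard,
          eval_nodes: Iterable[str],
          pairs: Sequence[Pair] | None = None) -> float:
    """Area under the precision-recall curve, stepped over distinct
    score thresholds: sum_k (R_k - R_{k-1}) * P_k, non-interpolated."""
    s, y = _evaluation_arrays(ranking, gold, eval_nodes, pairs)
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("AUPRC undefined: no positives among evaluated pairs")
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(1 - y_sorted)
    # evaluate at the last index of each distinct-score block
    distinct = np.flatnonzero(np.diff(s_sorted, append=np.nan))
    precision = tp[distinct] / (tp[distinct] + fp[distinct])
    recall = tp[distinct] / n_pos
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - prev_recall) * precision))
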