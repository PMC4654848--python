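"""Domain types and text-format I/O for network-skeleton inference.

All structures are undirected: an edge is stored as a *canonical pair*,
the tuple of its two node identifiers sorted lexicographically.  File
formats follow DREAM-challenge conventions — tab-separated text with "."
as the decimal mark:

* expression: genes x samples matrix, first column gene identifiers,
  optional header row of sample names;
* gold standard / edge lists: 3 columns (source, target, indicator) or
  2 columns (source, target);
* prior matrix: either a full square matrix with gene identifiers as
  both header and first column, or a 3-column (node, node, belief) list;
* ranked edges: 3 columns (node, node, score), one row per edge in rank
  order — loadable as a Cytoscape edge table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Pair",
    "canon_pair",
    "all_pairs",
    "ExpressionDataset",
    "PriorMatrix",
    "Skeleton",
    "GoldStandard",
    "RankedEdgeList",
    "read_expression",
    "write_expression",
    "read_edge_list",
    "write_edge_list",
    "read_prior_matrix",
    "write_prior_matrix",
    "read_ranked_edges",
    "write_ranked_edges",
]

Pair = tuple[str, str]


def canon_pair(a: str, b: str) -> Pair:
    """Canonical undirected pair: identifiers sorted lexicographically."""
    if a == b:
        raise ValueError(f"self-pair not allowed: {a!r}")
    return (a, b) if a < b else (b, a)


def all_pairs(variables: Sequence[str]) -> list[Pair]:
    """All canonical pairs over ``variables``, in lexicographic order."""
    vs = sorted(variables)
    return [(vs[i], vs[j]) for i in range(len(vs)) for j in range(i + 1, len(vs))]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpressionDataset:
    """Expression matrix over an ordered variable set.

    Parameters
    ----------
    variables
        Gene identifiers; their order is the canonical variable ordering
        of the dataset (file row order when read from disk).
    matrix
        ``len(variables) x n`` array of expression values (arbitrary
        units); columns are samples.
    """

    variables: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", mat)
        object.__setattr__(self, "variables", tuple(self.variables))
        if len(self.variables) < 2:
            raise ValueError("an expression dataset needs at least 2 genes")
        if len(set(self.variables)) != len(self.variables):
            dupes = sorted({v for v in self.variables if list(self.variables).count(v) > 1})
            raise ValueError(f"duplicate gene identifier(s): {', '.join(dupes)}")
        if mat.ndim != 2 or mat.shape[0] != len(self.variables):
            raise ValueError("matrix shape does not match the variable list")
        if mat.shape[1] < 1:
            raise ValueError("an expression dataset needs at least 1 sample")
        if not np.all(np.isfinite(mat)):
            raise ValueError("expression matrix contains missing/non-finite values")

    @property
    def n(self) -> int:
        """Number of samples."""
        return self.matrix.shape[1]

    def index(self, variable: str) -> int:
        return self.variables.index(variable)


@dataclass(frozen=True)
class PriorMatrix:
    """Symmetric matrix of soft edge beliefs b_ij in [0, 1].

    0.5 is the non-informative value; values above 0.5 favour edge
    existence, below 0.5 its absence.  The diagonal is unused.
    """

    variables: tuple[str, ...]
    beliefs: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.beliefs, dtype=float)
        object.__setattr__(self, "beliefs", b)
        object.__setattr__(self, "variables", tuple(self.variables))
        p = len(self.variables)
        if b.shape != (p, p):
            raise ValueError("belief matrix shape does not match variable list")
        if np.nanmin(b) < 0.0 or np.nanmax(b) > 1.0:
            raise ValueError("prior beliefs must lie in [0, 1]")
        if not np.allclose(b, b.T, atol=1e-9, rtol=0.0):
            raise ValueError("prior matrix must be symmetric (|b_ij - b_ji| <= 1e-9)")

    @classmethod
    def noninformative(cls, variables: Sequence[str]) -> "PriorMatrix":
        p = len(variables)
        return cls(tuple(variables), np.full((p, p), 0.5))

    def get(self, a: str, b: str) -> float:
        i, j = self.variables.index(a), self.variables.index(b)
        return float(self.beliefs[i, j])


@dataclass(frozen=True)
class Skeleton:
    """Undirected graph over gene identifiers — the inference output."""

    nodes: tuple[str, ...]
    edges: frozenset[Pair]

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", tuple(self.nodes))
        node_set = set(self.nodes)
        canon = frozenset(canon_pair(a, b) for a, b in self.edges)
        for a, b in canon:
            if a not in node_set or b not in node_set:
                raise ValueError(f"edge ({a}, {b}) references unknown node")
        object.__setattr__(self, "edges", canon)

    def has_edge(self, a: str, b: str) -> bool:
        return canon_pair(a, b) in self.edges

    def degree(self, node: str) -> int:
        return sum(1 for e in self.edges if node in e)


class GoldStandard(Skeleton):
    """Reference edge set; a directed gold standard is collapsed to its
    undirected skeleton (directions dropped, duplicates merged)."""

    @property
    def true_edges(self) -> frozenset[Pair]:
        return self.edges


@dataclass(frozen=True)
class RankedEdgeList:
    """Edges ordered by score descending, ties lexicographic by pair.

    Scores are bootstrap frequencies (integers in 0..K) or any
    confidence value; only the induced order matters downstream.
    """

    entries: tuple[tuple[Pair, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        seen: set[Pair] = set()
        canon_entries = []
        for (a, b), s in self.entries:
            pair = canon_pair(a, b)
            if pair in seen:
                raise ValueError(f"duplicate pair in ranking: {pair}")
            seen.add(pair)
            canon_entries.append((pair, float(s)))
        expected = sorted(canon_entries, key=lambda e: (-e[1], e[0]))
        if canon_entries != expected:
            raise ValueError("ranking must be sorted by score desc, ties lexicographic")
        object.__setattr__(self, "entries", tuple(canon_entries))

    @classmethod
    def from_scores(cls, scores: dict[Pair, float]) -> "RankedEdgeList":
        """Build a valid ranking from an unordered pair -> score mapping."""
        items = sorted(((canon_pair(*p), float(s)) for p, s in scores.items()),
                       key=lambda e: (-e[1], e[0]))
        return cls(tuple(items))

    def scores(self) -> dict[Pair, float]:
        return {p: s for p, s in self.entries}

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _looks_numeric(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_expression(path: str | Path) -> ExpressionDataset:
    """Read a genes x samples TSV matrix.

    The first column holds gene identifiers; the remaining columns are
    numeric sample values.  A header row of sample names is detected by
    its non-numeric second field and skipped.  Row order defines the
    canonical variable ordering.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", header=None, dtype=str, comment=None)
    if raw.shape[1] < 2:
        raise ValueError(f"{path}: expected at least one sample column")
    start = 0
    if not _looks_numeric(str(raw.iloc[0, 1])):
        start = 1  # header row of sample names
    body = raw.iloc[start:]
    genes = [str(g) for g in body.iloc[:, 0]]
    values = np.empty((len(genes), raw.shape[1] - 1), dtype=float)
    for r, (_, row) in enumerate(body.iterrows()):
        for c in range(1, raw.shape[1]):
            cell = row.iloc[c]
            try:
                values[r, c - 1] = float(cell)
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: non-numeric value {cell!r} at gene {genes[r]!r}, "
                    f"sample column {c}"
                ) from None
    return ExpressionDataset(tuple(genes), values)


def write_expression(data: ExpressionDataset, path: str | Path,
                     header: bool = True) -> None:
    df = pd.DataFrame(data.matrix, index=list(data.variables),
                      columns=[f"S{k + 1}" for k in range(data.n)])
    df.to_csv(path, sep="\t", header=header, index=True, float_format="%.10g")


def read_edge_list(path: str | Path, directed: bool = True) -> GoldStandard:
    """Read a DREAM-style edge list into an undirected gold standard.

    Accepts 3 columns (source, target, indicator in {0, 1}) or 2 columns
    (source, target).  Indicator-0 rows are ignored; directed pairs are
    collapsed to canonical undirected pairs and duplicates merged.
    Self-loop rows are skipped with a warning.  ``directed`` only
    documents the input convention — output is always undirected.
    """
    path = Path(path)
    nodes: set[str] = set()
    edges: set[Pair] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) == 2:
                src, tgt, flag = fields[0], fields[1], "1"
            elif len(fields) == 3:
                src, tgt, flag = fields
            else:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 or 3 tab-separated columns, "
                    f"got {len(fields)}"
                )
            if flag not in {"0", "1"}:
                raise ValueError(f"{path}:{lineno}: indicator must be 0 or 1, got {flag!r}")
            nodes.update((src, tgt))
            if flag == "0":
                continue
            if src == tgt:
                warnings.warn(f"{path}:{lineno}: self-loop {src!r} skipped")
                continue
            edges.add(canon_pair(src, tgt))
    return GoldStandard(tuple(sorted(nodes)), frozenset(edges))


def write_edge_list(gold: Skeleton, path: str | Path) -> None:
    """Write an undirected edge set as a 3-column (a, b, 1) TSV."""
    with open(path, "w") as fh:
        for a, b in sorted(gold.edges):
            fh.write(f"{a}\t{b}\t1\n")


def read_prior_matrix(path: str | Path, variables: Sequence[str]) -> PriorMatrix:
    """Read a prior matrix aligned to the dataset's variable ordering.

    Two dialects: a full square matrix (gene identifiers in the header
    row and first column) or a 3-column (node, node, belief) list.
    Unlisted pairs default to the non-informative value 0.5.
    """
    path = Path(path)
    variables = tuple(variables)
    index = {v: k for k, v in enumerate(variables)}
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
    header = first.split("\t") if first else []

    if len(header) == len(variables) + 1 and set(header[1:]) == set(variables):
        df = pd.read_csv(path, sep="\t", index_col=0)
        missing = set(variables) - set(map(str, df.index))
        if missing:
            raise ValueError(f"{path}: matrix missing variables {sorted(missing)}")
        df = df.loc[list(variables), list(variables)]
        beliefs = df.to_numpy(dtype=float)
        if np.nanmin(beliefs) < 0 or np.nanmax(beliefs) > 1:
            raise ValueError(f"{path}: prior beliefs must lie in [0, 1]")
        if not np.allclose(beliefs, beliefs.T, atol=1e-9, rtol=0.0):
            raise ValueError(f"{path}: prior matrix not symmetric")
        np.fill_diagonal(beliefs, 0.5)
        return PriorMatrix(variables, beliefs)

    # 3-column list
    beliefs = np.full((len(variables), len(variables)), 0.5)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 tab-separated columns, got {len(fields)}"
                )
            a, b, raw_belief = fields
            try:
                belief = float(raw_belief)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric belief {raw_belief!r}") from None
            if not (0.0 <= belief <= 1.0):
                raise ValueError(f"{path}:{lineno}: belief {belief} outside [0, 1]")
            if a not in index or b not in index:
                raise ValueError(f"{path}:{lineno}: unknown variable in pair ({a}, {b})")
            if a == b:
                continue
            beliefs[index[a], index[b]] = belief
            beliefs[index[b], index[a]] = belief
    return PriorMatrix(variables, beliefs)


def write_prior_matrix(prior: PriorMatrix, path: str | Path) -> None:
    """Write the informative entries of a prior matrix as a 3-column TSV."""
    vs = prior.variables
    with open(path, "w") as fh:
        for i in range(len(vs)):
            for j in range(i + 1, len(vs)):
                b = prior.beliefs[i, j]
                if b != 0.5:
                    a, c = canon_pair(vs[i], vs[j])
                    fh.write(f"{a}\t{c}\t{b:.10g}\n")


def read_ranked_edges(path: str | Path) -> RankedEdgeList:
    entries: list[tuple[Pair, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(fields)}")
            a, b, score = fields
            entries.append((canon_pair(a, b), float(score)))
    return RankedEdgeList(tuple(entries))


def write_ranked_edges(ranking: RankedEdgeList, path: str | Path) -> None:
    """Write a ranking as a Cytoscape-compatible (node, node, score) TSV."""
    with open(path, "w") as fh:
        for (a, b), s in ranking.entries:
            fh.write(f"{a}\t{b}\t{s:.10g}\n")
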