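"""Core data containers shared across the alignment pipeline.

A :class:`Network` is an undirected, unweighted graph with labelled nodes
and a sparse symmetric adjacency matrix.  :class:`ElementalSimilarity`
holds the prior node-pair scores H (typically BLAST-derived sequence
similarity); :class:`Matching` is an injective set of (row, column) pairs
extracted from a diffused similarity matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp


class PpialignError(Exception):
    """Base class for errors raised by this package."""


class ParseError(PpialignError):
    """A file could not be parsed; the message names the offending line."""


@dataclass
class Network:
    """Undirected graph with labelled nodes.

    Parameters
    ----------
    name:
        Short identifier (e.g. a species tag).
    nodes:
        Unique node labels in a fixed order; all matrices produced from
        this network are indexed in this order.
    adjacency:
        Symmetric binary sparse matrix with zero diagonal.
    """

    name: str
    nodes: list[str]
    adjacency: sp.csr_matrix

    def __post_init__(self) -> None:
        n = len(self.nodes)
        if n < 1:
            raise ValueError("a network needs at least one node")
        if len(set(self.nodes)) != n:
            raise ValueError("node labels must be unique")
        A = sp.csr_matrix(self.adjacency, dtype=np.float64)
        if A.shape != (n, n):
            raise ValueError(f"adjacency shape {A.shape} != ({n}, {n})")
        if A.diagonal().any():
            raise ValueError("adjacency must have zero diagonal (no self-loops)")
        if (A != A.T).nnz != 0:
            raise ValueError("adjacency must be symmetric")
        self.adjacency = A
        self._index = {label: i for i, label in enumerate(self.nodes)}

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        """Undirected edge count, each pair counted once."""
        return int(self.adjacency.nnz // 2)

    def index_of(self, label: str) -> int:
        return self._index[label]

    def __contains__(self, label: str) -> bool:
        return label in self._index

    def degree(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=0)).ravel()

    @classmethod
    def from_edges(cls, name: str, edges: Sequence[tuple[str, str]],
                   extra_nodes: Sequence[str] = ()) -> "Network":
        """Build a network from undirected label pairs.

        Nodes appear in first-appearance order; duplicate edges (either
        orientation) collapse to one; self-loops are ignored here
        (callers that must warn filter them out beforehand).
        """
        order: dict[str, int] = {}
        for u, v in edges:
            order.setdefault(u, len(order))
            order.setdefault(v, len(order))
        for u in extra_nodes:
            order.setdefault(u, len(order))
        labels = list(order)
        n = len(labels)
        rows, cols = [], []
        seen = set()
        for u, v in edges:
            if u == v:
                continue
            i, j = order[u], order[v]
            key = (min(i, j), max(i, j))
            if key in seen:
                continue
            seen.add(key)
            rows += [i, j]
            cols += [j, i]
        A = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
        return cls(name=name, nodes=labels, adjacency=A)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        coo = sp.triu(self.adjacency).tocoo()
        g.add_edges_from((self.nodes[i], self.nodes[j]) for i, j in zip(coo.row, coo.col))
        return g


@dataclass
class ElementalSimilarity:
    """Prior (topology-free) node-pair similarity matrix H.

    ``scores[i, j]`` is the elemental similarity between node ``i`` of the
    first network and node ``j`` of the second, e.g. a BLAST bit score.
    Entries are non-negative; at least one entry must be positive before
    the matrix can seed the diffusion (the seed vector is normalised to
    unit 1-norm).
    """

    scores: np.ndarray

    def __post_init__(self) -> None:
        H = np.asarray(self.scores, dtype=np.float64)
        if H.ndim != 2:
            raise ValueError("H must be a 2-d matrix")
        if (H < 0).any():
            raise ValueError("elemental similarities must be non-negative")
        self.scores = H

    @property
    def shape(self) -> tuple[int, int]:
        return self.scores.shape

    def require_positive(self) -> None:
        if not (self.scores > 0).any():
            raise ValueError(
                "elemental similarity matrix is all zero; the seed vector "
                "cannot be normalised"
            )


@dataclass
class AnnotationSet:
    """Node -> set-of-terms map for one species.

    ``background`` is the universe the hypergeometric test draws from; it
    always contains every annotated node and may additionally contain
    unannotated ones (e.g. every node of the network).
    """

    mapping: dict[str, set[str]]
    background: set[str]

    def __post_init__(self) -> None:
        for node, terms in self.mapping.items():
            if not terms:
                raise ValueError(f"annotated node {node!r} has no terms")
        if not self.background >= set(self.mapping):
            raise ValueError("background must contain every annotated node")

    @property
    def terms(self) -> set[str]:
        out: set[str] = set()
        for t in self.mapping.values():
            out |= t
        return out

    def nodes_with(self, term: str) -> set[str]:
        return {n for n, ts in self.mapping.items() if term in ts}


@dataclass
class Matching:
    """Injective set of (row, column) index pairs with per-pair scores.

    ``pairs[k]`` matches row ``pairs[k][0]`` of the first network to
    column ``pairs[k][1]`` of the second; ``scores[k]`` is the similarity
    score of that pair on the ORIGINAL (unscaled) matrix it was extracted
    from.  ``labels`` optionally carries the corresponding node labels.
    """

    pairs: list[tuple[int, int]]
    scores: list[float]
    method: str = ""
    shape: tuple[int, int] | None = None
    labels: list[tuple[str, str]] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.pairs) != len(self.scores):
            raise ValueError("pairs and scores must have equal length")
        rows = [i for i, _ in self.pairs]
        cols = [j for _, j in self.pairs]
        if len(set(rows)) != len(rows) or len(set(cols)) != len(cols):
            raise ValueError("matching must be injective in both coordinates")
        if self.shape is not None:
            nr, nc = self.shape
            if any(not (0 <= i < nr and 0 <= j < nc) for i, j in self.pairs):
                raise ValueError("pair index out of range for declared shape")

    @property
    def weight(self) -> float:
        return float(sum(self.scores))

    def __len__(self) -> int:
        return len(self.pairs)

    def as_dict(self) -> dict[int, int]:
        return dict(self.pairs)

    def with_labels(self, netA: "Network", netB: "Network") -> "Matching":
        """Return a copy carrying node labels resolved from the networks."""
        labels = [(netA.nodes[i], netB.nodes[j]) for i, j in self.pairs]
        return Matching(pairs=list(self.pairs), scores=list(self.scores),
                        method=self.method, shape=self.shape, labels=labels,
                        meta=dict(self.meta))
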