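"""Readers and writers for the pipeline's tab-separated file formats.

Formats
-------
Edge list
    ``node1<TAB>node2`` per line, ``#`` comments allowed.  Undirected:
    both orientations collapse to one edge; self-loops are dropped with a
    warning.
Similarity triples
    ``nodeA<TAB>nodeB<TAB>score`` with non-negative scores; repeated
    pairs keep the maximum score (conservative for multi-HSP BLAST
    output).
Annotations
    ``node<TAB>term`` per line.
Matching
    ``nodeA<TAB>nodeB<TAB>score`` preceded by one ``#`` header comment
    recording run parameters; sorted by descending score then labels, so
    byte output is deterministic.

All indexing is internal and 0-based; files carry labels only.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from .model import AnnotationSet, ElementalSimilarity, Matching, Network, ParseError

logger = logging.getLogger(__name__)

__all__ = [
    "read_edge_list",
    "read_similarity_triples",
    "read_annotations",
    "write_matching",
    "read_matching",
]


def _data_lines(path: str | Path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def read_edge_list(path: str | Path, name: str = "") -> Network:
    """Read an undirected network from a tab-separated edge list.

    Nodes are ordered by first appearance; duplicate edges collapse and
    self-loops are dropped with a logged warning.
    """
    name = name or Path(path).stem
    edges: list[tuple[str, str]] = []
    n_loops = 0
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2 or not fields[0] or not fields[1]:
            raise ParseError(f"{path}:{lineno}: expected two tab-separated node labels, got {line!r}")
        u, v = fields[0], fields[1]
        if u == v:
            n_loops += 1
            logger.warning("%s:%d: self-loop on %r dropped", path, lineno, u)
        edges.append((u, v))
    if not edges:
        raise ParseError(f"{path}: empty edge list")
    net = Network.from_edges(name, edges)
    logger.info("read network %s: %d nodes, %d edges (%d self-loops dropped)",
                name, net.n, net.n_edges, n_loops)
    return net


def read_similarity_triples(path: str | Path, netA: Network, netB: Network,
                            missing_policy: str = "error") -> ElementalSimilarity:
    """Read node-pair scores into an H matrix aligned to the two networks.

    Unlisted pairs are 0; repeated pairs keep the maximum score.  Labels
    absent from either network raise (``missing_policy='error'``) or are
    skipped with a warning (``'skip'``).
    """
    if missing_policy not in ("error", "skip"):
        raise ValueError("missing_policy must be 'error' or 'skip'")
    H = np.zeros((netA.n, netB.n))
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected nodeA<TAB>nodeB<TAB>score")
        a, b, raw = fields[0], fields[1], fields[2]
        try:
            score = float(raw)
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-numeric score {raw!r}") from None
        if not np.isfinite(score) or score < 0:
            raise ParseError(f"{path}:{lineno}: score must be finite and non-negative, got {raw}")
        if a not in netA or b not in netB:
            if missing_policy == "skip":
                logger.warning("%s:%d: pair (%r, %r) not in networks; skipped", path, lineno, a, b)
                continue
            raise ParseError(f"{path}:{lineno}: pair ({a!r}, {b!r}) not present in the networks")
        i, j = netA.index_of(a), netB.index_of(b)
        H[i, j] = max(H[i, j], score)
    sim = ElementalSimilarity(H)
    sim.require_positive()
    return sim


def read_annotations(path: str | Path) -> AnnotationSet:
    """Read a node -> term table; background = all nodes in the file."""
    mapping: dict[str, set[str]] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2 or not fields[0] or not fields[1]:
            raise ParseError(f"{path}:{lineno}: expected node<TAB>term")
        mapping.setdefault(fields[0], set()).add(fields[1])
    if not mapping:
        logger.warning("%s: no annotations found; empty annotation set", path)
    return AnnotationSet(mapping=mapping, background=set(mapping))


def write_matching(matching: Matching, path: str | Path) -> None:
    """Write a matching as ``nodeA<TAB>nodeB<TAB>score`` lines.

    Rows are ordered by descending score, ties broken lexicographically
    by (nodeA, nodeB), so output bytes are a deterministic function of
    the matching.  One header comment records the run parameters.
    """
    if matching.labels is not None:
        rows = [(la, lb, s) for (la, lb), s in zip(matching.labels, matching.scores)]
    else:
        rows = [(str(i), str(j), s) for (i, j), s in zip(matching.pairs, matching.scores)]
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    meta = dict(matching.meta)
    if matching.method:
        meta.setdefault("matcher", matching.method)
    header = " ".join(f"{k}={meta[k]}" for k in sorted(meta)) or "matching"
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        for a, b, s in rows:
            fh.write(f"{a}\t{b}\t{s:.10g}\n")


def read_matching(path: str | Path, netA: Network | None = None,
                  netB: Network | None = None) -> Matching:
    """Read a matching written by :func:`write_matching`.

    With networks supplied, labels are resolved back to indices;
    otherwise pairs are stored as (-1, -1) placeholders with labels only.
    """
    labels: list[tuple[str, str]] = []
    scores: list[float] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected nodeA<TAB>nodeB<TAB>score")
        labels.append((fields[0], fields[1]))
        scores.append(float(fields[2]))
    if netA is not None and netB is not None:
        pairs = [(netA.index_of(a), netB.index_of(b)) for a, b in labels]
        shape = (netA.n, netB.n)
    else:
        pairs = [(-k - 1, -k - 1) for k in range(len(labels))]
        shape = None
    return Matching(pairs=pairs, scores=scores, labels=labels, shape=shape,
                    method="file")
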