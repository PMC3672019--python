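"""Alignment-graph construction and quality assessment.

The *alignment graph* has one node per matched pair ``m = (i, j)`` and
an edge between ``m1 = (i1, j1)`` and ``m2 = (i2, j2)`` exactly when
``(i1, i2)`` is an edge of the first network and ``(j1, j2)`` an edge of
the second — a *conserved edge*, an interaction preserved under the node
mapping in both species.  Topological quality is read off the number of
conserved edges and the sizes of the connected components (common
connected subgraphs).

Biological quality treats each connected component as a predicted group
of functionally related proteins and tests it, per species, for
over-representation of annotation terms with an exact hypergeometric
upper tail.  Two summary numbers follow the field's usage:

* TNR (specificity proxy): the percentage of components with at least
  one enriched term;
* TPR (sensitivity proxy): the number of distinct enriched terms covered
  across all components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.stats import hypergeom

from .model import AnnotationSet, Matching, Network

__all__ = [
    "AlignmentGraph",
    "EnrichmentReport",
    "build_alignment_graph",
    "conserved_edge_count",
    "connected_components",
    "hypergeometric_pvalue",
    "enrich_components",
    "assessment_report",
]

DEFAULT_PVALUE_THRESHOLD = 0.05


@dataclass
class AlignmentGraph:
    """Graph on matched pairs; edges are the conserved edges."""

    graph: nx.Graph  # nodes are (label_A, label_B) tuples
    provenance: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class EnrichmentReport:
    """Per-component enrichment calls plus the TPR/TNR summaries.

    ``records`` rows are ``(component index, species, term, p-value,
    enriched flag)``.  ``tnr`` maps species -> percentage of components
    with at least one enriched term (None when there are no components);
    ``tpr`` maps species -> count of distinct enriched terms.
    """

    records: list[tuple[int, str, str, float, bool]]
    tnr: dict[str, float | None]
    tpr: dict[str, int]
    n_components: int
    threshold: float


def build_alignment_graph(matching: Matching, netA: Network, netB: Network) -> AlignmentGraph:
    """Build the alignment graph of a matching over two networks."""
    if matching.shape is not None and matching.shape != (netA.n, netB.n):
        raise ValueError("matching shape does not fit the networks")
    for i, j in matching.pairs:
        if not (0 <= i < netA.n and 0 <= j < netB.n):
            raise IndexError(f"matched pair ({i}, {j}) out of range")
    idx_a = np.fromiter((i for i, _ in matching.pairs), dtype=np.int64,
                        count=len(matching))
    idx_b = np.fromiter((j for _, j in matching.pairs), dtype=np.int64,
                        count=len(matching))
    g = nx.Graph()
    names = [(netA.nodes[i], netB.nodes[j]) for i, j in matching.pairs]
    g.add_nodes_from(names)
    if len(matching) > 1:
        # conserved edge iff both induced adjacency entries are set
        subA = netA.adjacency[np.ix_(idx_a, idx_a)].toarray()
        subB = netB.adjacency[np.ix_(idx_b, idx_b)].toarray()
        both = np.logical_and(subA > 0, subB > 0)
        for k, l in zip(*np.nonzero(np.triu(both, k=1))):
            g.add_edge(names[int(k)], names[int(l)])
    prov = dict(matching.meta)
    if matching.method:
        prov.setdefault("matcher", matching.method)
    return AlignmentGraph(graph=g, provenance=prov)


def conserved_edge_count(ag: AlignmentGraph) -> int:
    """Number of alignment-graph edges, each unordered pair once."""
    return ag.n_edges


def connected_components(ag: AlignmentGraph) -> list[list[tuple[str, str]]]:
    """Maximal connected sets of matched pairs, singletons included.

    Sorted by decreasing size, ties by the lexicographically smallest
    member; nodes within a component are sorted for determinism.
    """
    comps = [sorted(c) for c in nx.connected_components(ag.graph)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return comps


def hypergeometric_pvalue(k: int, n_draw: int, K: int, N: int) -> float:
    """Exact upper-tail P(X >= k) for X ~ Hypergeom(N, K, n_draw).

    ``N`` background size, ``K`` term-annotated nodes in the background,
    ``n_draw`` component size, ``k`` term-annotated nodes observed in it.
    """
    if not (0 <= k <= n_draw <= N and 0 <= K <= N):
        raise ValueError("inconsistent hypergeometric parameters")
    return float(hypergeom.sf(k - 1, N, K, n_draw))


def enrich_components(components: list[list[tuple[str, str]]],
                      annA: AnnotationSet, annB: AnnotationSet,
                      threshold: float = DEFAULT_PVALUE_THRESHOLD,
                      bonferroni: bool = False) -> EnrichmentReport:
    """Test every component for term over-representation, per species.

    Each species is processed independently: the component is projected
    to that species' nodes (restricted to the annotation background, the
    population the test draws from), and every term annotating at least
    one projected node gets an exact hypergeometric upper-tail p-value.
    A term is enriched when p <= threshold (optionally Bonferroni-scaled
    by the number of terms tested in that component/species).
    """
    records: list[tuple[int, str, str, float, bool]] = []
    enriched_terms: dict[str, set[str]] = {"A": set(), "B": set()}
    comps_enriched: dict[str, int] = {"A": 0, "B": 0}
    species = [("A", annA, 0), ("B", annB, 1)]
    for ci, comp in enumerate(components):
        for tag, ann, side in species:
            if not ann.background:
                continue
            proj = {pair[side] for pair in comp} & ann.background
            N = len(ann.background)
            n_draw = len(proj)
            terms = sorted({t for node in proj for t in ann.mapping.get(node, ())})
            correction = max(1, len(terms)) if bonferroni else 1
            hit = False
            for term in terms:
                carriers = ann.nodes_with(term)
                k = len(proj & carriers)
                p = hypergeometric_pvalue(k, n_draw, len(carriers), N)
                enr = p * correction <= threshold
                records.append((ci, tag, term, p, enr))
                if enr:
                    hit = True
                    enriched_terms[tag].add(term)
            if hit:
                comps_enriched[tag] += 1
    n_comp = len(components)
    tnr: dict[str, float | None] = {}
    tpr: dict[str, int] = {}
    for tag, ann, _ in species:
        tnr[tag] = 100.0 * comps_enriched[tag] / n_comp if n_comp else None
        tpr[tag] = len(enriched_terms[tag])
    return EnrichmentReport(records=records, tnr=tnr, tpr=tpr,
                            n_components=n_comp, threshold=threshold)


def assessment_report(matching: Matching, netA: Network, netB: Network,
                      annA: AnnotationSet | None = None,
                      annB: AnnotationSet | None = None,
                      threshold: float = DEFAULT_PVALUE_THRESHOLD) -> dict:
    """Bundle the topological and (if annotations given) biological scores.

    Returns a plain dict suitable for JSON serialisation: conserved-edge
    count, component size histogram, and per-species TPR/TNR when
    annotation sets are supplied.
    """
    ag = build_alignment_graph(matching, netA, netB)
    comps = connected_components(ag)
    sizes = [len(c) for c in comps]
    hist: dict[int, int] = {}
    for s in sizes:
        hist[s] = hist.get(s, 0) + 1
    report = {
        "matcher": matching.method,
        "n_pairs": len(matching),
        "matching_weight": matching.weight,
        "conserved_edges": conserved_edge_count(ag),
        "n_components": len(comps),
        "component_size_histogram": {str(k): hist[k] for k in sorted(hist, reverse=True)},
        "largest_component": max(sizes, default=0),
    }
    if annA is not None and annB is not None:
        enr = enrich_components(comps, annA, annB, threshold=threshold)
        report["enrichment"] = {
            "threshold": threshold,
            "tpr": {"A": enr.tpr["A"], "B": enr.tpr["B"]},
            "tnr": {"A": enr.tnr["A"], "B": enr.tnr["B"]},
        }
    return report


def format_report(report: dict) -> str:
    """Human-readable summary of an assessment report."""
    lines = [
        f"matcher:          {report.get('matcher', '?')}",
        f"matched pairs:    {report['n_pairs']}",
        f"matching weight:  {report['matching_weight']:.6g}",
        f"conserved edges:  {report['conserved_edges']}",
        f"components:       {report['n_components']} "
        f"(largest {report['largest_component']})",
    ]
    if "enrichment" in report:
        e = report["enrichment"]
        for tag in ("A", "B"):
            tnr = e["tnr"][tag]
            tnr_s = f"{tnr:.1f}%" if tnr is not None else "n/a"
            lines.append(f"species {tag}:        TPR = {e['tpr'][tag]} terms, TNR = {tnr_s}")
    return "\n".join(lines)
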