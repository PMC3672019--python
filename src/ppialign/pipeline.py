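"""End-to-end alignment runs: files in, matching + assessment out.

The pipeline chains the stages in their natural order — read the two
networks and the elemental similarity, diffuse with the similarity
iteration, extract a matching, build and assess the alignment graph —
and writes deterministic outputs plus a JSON run manifest.  The same
configuration and inputs always yield byte-identical matching files.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .assess import assessment_report, build_alignment_graph, format_report
from .io import read_annotations, read_edge_list, read_similarity_triples, write_matching
from .isorank import DEFAULT_ALPHA, DEFAULT_ITERATIONS, isorank_iterate
from .matching import (DEFAULT_GROWTH, DEFAULT_SCALE, adaptive_auction_match,
                       auction_match, greedy_match)
from .model import Matching, Network

MATCHERS = ("greedy", "auction", "adaptive-auction")


@dataclass
class RunConfig:
    """Everything one alignment run depends on."""

    netA: str
    netB: str
    similarity: str
    annotations_a: str | None = None
    annotations_b: str | None = None
    alpha: float = DEFAULT_ALPHA
    iterations: int = DEFAULT_ITERATIONS
    matcher: str = "adaptive-auction"
    epsilon0: float | None = None
    growth: float = DEFAULT_GROWTH
    delta: int | None = None
    scale: float = DEFAULT_SCALE
    threshold: float = 0.05
    outdir: str = "alignment_out"
    seed: int = 0
    missing_policy: str = "skip"
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.matcher not in MATCHERS:
            raise ValueError(f"matcher must be one of {MATCHERS}")


def extract_matching(X, matcher: str, *, epsilon0: float | None = None,
                     growth: float = DEFAULT_GROWTH, delta: int | None = None,
                     scale: float = DEFAULT_SCALE) -> Matching:
    """Dispatch to the requested matching heuristic."""
    if matcher == "greedy":
        return greedy_match(X)
    if matcher == "auction":
        M = getattr(X, "X", X)
        eps = epsilon0 if epsilon0 is not None else 1.0 / (min(M.shape) + 1)
        return auction_match(X, epsilon=eps, scale=scale)
    if matcher == "adaptive-auction":
        return adaptive_auction_match(X, epsilon0=epsilon0, growth=growth,
                                      delta=delta, scale=scale)
    raise ValueError(f"unknown matcher {matcher!r}")


def align(config: RunConfig) -> dict:
    """Run the full pipeline described by ``config``.

    Writes ``matching.tsv``, ``alignment_graph.tsv``, ``report.json``
    and ``manifest.json`` into ``config.outdir`` and returns the report.
    """
    config.validate()
    t0 = time.perf_counter()
    netA = read_edge_list(config.netA, "A")
    netB = read_edge_list(config.netB, "B")
    H = read_similarity_triples(config.similarity, netA, netB,
                                missing_policy=config.missing_policy)
    annA = read_annotations(config.annotations_a) if config.annotations_a else None
    annB = read_annotations(config.annotations_b) if config.annotations_b else None
    t_io = time.perf_counter()

    X = isorank_iterate(netA, netB, H, alpha=config.alpha,
                        iterations=config.iterations)
    t_sim = time.perf_counter()

    matching = extract_matching(X, config.matcher, epsilon0=config.epsilon0,
                                growth=config.growth, delta=config.delta,
                                scale=config.scale)
    matching = matching.with_labels(netA, netB)
    matching.meta.update(alpha=config.alpha, iterations=config.iterations,
                         matcher=config.matcher)
    t_match = time.perf_counter()

    report = assessment_report(matching, netA, netB, annA, annB,
                               threshold=config.threshold)
    t_assess = time.perf_counter()

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_matching(matching, outdir / "matching.tsv")
    ag = build_alignment_graph(matching, netA, netB)
    with open(outdir / "alignment_graph.tsv", "w") as fh:
        fh.write("# alignment-graph conserved edges: pairA1 pairB1 pairA2 pairB2\n")
        for (a1, b1), (a2, b2) in sorted(ag.graph.edges()):
            fh.write(f"{a1}\t{b1}\t{a2}\t{b2}\n")
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
        fh.write("\n")
    manifest = {
        "version": __version__,
        "config": {k: v for k, v in vars(config).items() if k != "extra"},
        "timings_s": {
            "io": round(t_io - t0, 6),
            "similarity": round(t_sim - t_io, 6),
            "matching": round(t_match - t_sim, 6),
            "assessment": round(t_assess - t_match, 6),
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
    return report


def assess_precomputed(matching_path: str, netA_path: str, netB_path: str,
                       annotations_a: str | None = None,
                       annotations_b: str | None = None,
                       threshold: float = 0.05) -> dict:
    """Assess a matching file produced earlier (or by another tool)."""
    from .io import read_matching

    netA = read_edge_list(netA_path, "A")
    netB = read_edge_list(netB_path, "B")
    matching = read_matching(matching_path, netA, netB)
    annA = read_annotations(annotations_a) if annotations_a else None
    annB = read_annotations(annotations_b) if annotations_b else None
    return assessment_report(matching, netA, netB, annA, annB, threshold=threshold)


__all__ = ["RunConfig", "align", "assess_precomputed", "extract_matching",
           "format_report", "MATCHERS"]
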