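"""Synthetic network pairs with a planted node correspondence.

The generator produces everything the pipeline consumes — two networks,
an elemental-similarity matrix, annotation sets — together with the
ground-truth bijection, so recovery can be measured without any external
dataset.  Network A is Erdős–Rényi; network B is a relabelled copy with
a chosen fraction of its edges rewired and optional extra nodes, which
emulates divergence between two species' interactomes.  Elemental
similarity supports the truth pairs at a fixed score plus optional
uniform noise on off-truth pairs (a crude stand-in for spurious sequence
hits).  Annotations plant terms on connected modules of A and their
truth images in B.

All randomness flows from a single integer seed; identical seeds give
byte-identical instances.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .io import write_matching
from .model import AnnotationSet, ElementalSimilarity, Matching, Network

__all__ = [
    "PlantedInstance",
    "generate_pair",
    "generate_elemental",
    "generate_annotations",
    "generate_instance",
    "truth_matching",
    "recovery_rate",
    "write_instance",
]

DEFAULT_N = 50
DEFAULT_EDGE_PROB = 0.1
DEFAULT_TRUE_SCORE = 1.0

_MAX_RETRIES = 20


@dataclass
class PlantedInstance:
    """A generated network pair plus ground truth.

    ``truth`` maps each A-node label to its planted counterpart in B;
    ``truth_idx`` is the same bijection on (row, column) indices.
    """

    netA: Network
    netB: Network
    truth: dict[str, str]
    seed: int
    H: ElementalSimilarity | None = None
    annA: AnnotationSet | None = None
    annB: AnnotationSet | None = None

    @property
    def truth_idx(self) -> list[tuple[int, int]]:
        return sorted((self.netA.index_of(a), self.netB.index_of(b))
                      for a, b in self.truth.items())


def _er_edges(n: int, edge_prob: float, rng: np.random.Generator) -> list[tuple[int, int]]:
    iu, ju = np.triu_indices(n, k=1)
    mask = rng.random(len(iu)) < edge_prob
    return list(zip(iu[mask].tolist(), ju[mask].tolist()))


def generate_pair(n: int = DEFAULT_N, edge_prob: float = DEFAULT_EDGE_PROB,
                  rewire_frac: float = 0.0, extra_nodes: int = 0,
                  seed: int = 0) -> PlantedInstance:
    """Generate an Erdős–Rényi network and a rewired, relabelled copy.

    ``ceil(rewire_frac * |E_A|)`` edges of the copy are deleted and the
    same number inserted uniformly among non-edges; ``extra_nodes``
    additional B-nodes are each attached to one random node with
    probability 1/2 (isolated otherwise).  At ``rewire_frac = 0`` and no
    extra nodes, B is isomorphic to A via the returned truth bijection.
    """
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if not 0.0 <= rewire_frac <= 1.0:
        raise ValueError("rewire_frac must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    edges = []
    for _ in range(_MAX_RETRIES):
        edges = _er_edges(n, edge_prob, rng)
        if edges:
            break
    if not edges:
        raise ValueError(f"edge_prob={edge_prob} produced an empty graph "
                         f"after {_MAX_RETRIES} attempts")
    labels_a = [f"a{i}" for i in range(n)]
    netA = Network.from_edges("synthA", [(labels_a[i], labels_a[j]) for i, j in edges],
                              extra_nodes=labels_a)

    # relabelled copy: B-node order is a random permutation of A's nodes
    perm = rng.permutation(n)  # B position -> A index
    pos_of_a = np.empty(n, dtype=np.int64)
    pos_of_a[perm] = np.arange(n)
    labels_b = [f"b{k}" for k in range(n)]
    truth = {labels_a[i]: labels_b[pos_of_a[i]] for i in range(n)}

    b_edge_set = {(min(pos_of_a[i], pos_of_a[j]), max(pos_of_a[i], pos_of_a[j]))
                  for i, j in edges}
    n_rewire = int(np.ceil(rewire_frac * len(b_edge_set)))
    if n_rewire:
        current = sorted(b_edge_set)
        drop = rng.choice(len(current), size=n_rewire, replace=False)
        for k in drop:
            b_edge_set.discard(current[k])
        iu, ju = np.triu_indices(n, k=1)
        all_pairs = list(zip(iu.tolist(), ju.tolist()))
        non_edges = [p for p in all_pairs if p not in b_edge_set]
        add = rng.choice(len(non_edges), size=min(n_rewire, len(non_edges)), replace=False)
        for k in add:
            b_edge_set.add(non_edges[k])
    b_edges = [(labels_b[i], labels_b[j]) for i, j in sorted(b_edge_set)]

    extra_labels = [f"x{k}" for k in range(extra_nodes)]
    for lab in extra_labels:
        if rng.random() < 0.5:
            target = labels_b[int(rng.integers(n))]
            b_edges.append((lab, target))
    netB = Network.from_edges("synthB", b_edges, extra_nodes=labels_b + extra_labels)
    return PlantedInstance(netA=netA, netB=netB, truth=truth, seed=seed)


def generate_elemental(instance: PlantedInstance,
                       true_score: float = DEFAULT_TRUE_SCORE,
                       noise_pairs: int = 0, noise_score_max: float = 0.5,
                       seed: int | None = None) -> ElementalSimilarity:
    """Elemental similarity supporting the truth pairs, plus noise.

    Truth pairs score ``true_score``; ``noise_pairs`` random off-truth
    pairs get Uniform(0, noise_score_max) scores; everything else is 0.
    The result is also stored on ``instance.H``.
    """
    if true_score <= 0:
        raise ValueError("true_score must be positive")
    rng = np.random.default_rng(instance.seed if seed is None else seed)
    nA, nB = instance.netA.n, instance.netB.n
    H = np.zeros((nA, nB))
    truth_set = set(instance.truth_idx)
    for i, j in truth_set:
        H[i, j] = true_score
    n_off = nA * nB - len(truth_set)
    if noise_pairs > n_off:
        raise ValueError(f"noise_pairs={noise_pairs} exceeds the {n_off} off-truth pairs")
    if noise_pairs and noise_score_max > 0:
        off = [(i, j) for i in range(nA) for j in range(nB) if (i, j) not in truth_set]
        picks = rng.choice(len(off), size=noise_pairs, replace=False)
        for k in picks:
            i, j = off[k]
            H[i, j] = rng.uniform(0.0, noise_score_max)
    sim = ElementalSimilarity(H)
    instance.H = sim
    return sim


def generate_annotations(instance: PlantedInstance, n_terms: int = 5,
                         module_size: int = 4,
                         seed: int | None = None) -> tuple[AnnotationSet, AnnotationSet]:
    """Plant each term on one connected module of A and its truth image.

    Modules are grown by breadth-first search from a random start node;
    backgrounds contain every node of each network.  The results are
    also stored on ``instance.annA`` / ``instance.annB``.
    """
    if module_size > instance.netA.n:
        raise ValueError("module_size exceeds the network size")
    rng = np.random.default_rng((instance.seed + 1) if seed is None else seed)
    gA = instance.netA.to_networkx()
    mapA: dict[str, set[str]] = {}
    mapB: dict[str, set[str]] = {}
    nodes = list(instance.netA.nodes)
    for t in range(n_terms):
        term = f"T{t:03d}"
        start = nodes[int(rng.integers(len(nodes)))]
        module = [start]
        frontier = [start]
        seen = {start}
        while frontier and len(module) < module_size:
            nxt = frontier.pop(0)
            for nb in sorted(gA.neighbors(nxt)):
                if nb not in seen:
                    seen.add(nb)
                    module.append(nb)
                    frontier.append(nb)
                    if len(module) >= module_size:
                        break
        for a_node in module:
            mapA.setdefault(a_node, set()).add(term)
            mapB.setdefault(instance.truth[a_node], set()).add(term)
    annA = AnnotationSet(mapping=mapA, background=set(instance.netA.nodes))
    annB = AnnotationSet(mapping=mapB, background=set(instance.netB.nodes))
    instance.annA, instance.annB = annA, annB
    return annA, annB


def generate_instance(n: int = DEFAULT_N, edge_prob: float = DEFAULT_EDGE_PROB,
                      rewire_frac: float = 0.0, extra_nodes: int = 0,
                      true_score: float = DEFAULT_TRUE_SCORE,
                      noise_pairs: int = 0, noise_score_max: float = 0.5,
                      n_terms: int = 0, module_size: int = 4,
                      seed: int = 0) -> PlantedInstance:
    """One-call generator for a complete planted instance."""
    inst = generate_pair(n=n, edge_prob=edge_prob, rewire_frac=rewire_frac,
                         extra_nodes=extra_nodes, seed=seed)
    generate_elemental(inst, true_score=true_score, noise_pairs=noise_pairs,
                       noise_score_max=noise_score_max)
    if n_terms:
        generate_annotations(inst, n_terms=n_terms, module_size=module_size)
    return inst


def truth_matching(instance: PlantedInstance, X=None) -> Matching:
    """The planted bijection as a Matching, scored on X when given."""
    pairs = instance.truth_idx
    M = getattr(X, "X", X)
    if M is not None:
        scores = [float(M[i, j]) for i, j in pairs]
    else:
        scores = [1.0] * len(pairs)
    return Matching(pairs=list(pairs), scores=scores, method="truth",
                    shape=(instance.netA.n, instance.netB.n))


def recovery_rate(matching: Matching, instance: PlantedInstance) -> float:
    """Fraction of truth pairs recovered by a matching."""
    truth = set(instance.truth_idx)
    if not truth:
        return 0.0
    return len(truth & set(matching.pairs)) / len(truth)


def write_instance(instance: PlantedInstance, outdir: str | Path) -> dict[str, Path]:
    """Write an instance in the pipeline's TSV formats plus a truth file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "netA": outdir / "netA.tsv",
        "netB": outdir / "netB.tsv",
        "similarity": outdir / "similarity.tsv",
        "truth": outdir / "truth.tsv",
    }
    for key, net in (("netA", instance.netA), ("netB", instance.netB)):
        with open(paths[key], "w") as fh:
            fh.write(f"# synthetic network {net.name} seed={instance.seed}\n")
            coo = sp.triu(net.adjacency).tocoo()
            for i, j in sorted(zip(coo.row.tolist(), coo.col.tolist())):
                fh.write(f"{net.nodes[i]}\t{net.nodes[j]}\n")
            for lab, d in zip(net.nodes, net.degree()):
                if d == 0:
                    fh.write(f"{lab}\t{lab}\n")  # keeps isolated nodes readable
    if instance.H is not None:
        with open(paths["similarity"], "w") as fh:
            fh.write(f"# synthetic elemental similarity seed={instance.seed}\n")
            nz = np.argwhere(instance.H.scores > 0)
            for i, j in nz:
                fh.write(f"{instance.netA.nodes[i]}\t{instance.netB.nodes[j]}"
                         f"\t{instance.H.scores[i, j]:.10g}\n")
    write_matching(truth_matching(instance).with_labels(instance.netA, instance.netB),
                   paths["truth"])
    if instance.annA is not None and instance.annB is not None:
        for tag, ann in (("annA", instance.annA), ("annB", instance.annB)):
            p = outdir / f"{tag}.tsv"
            paths[tag] = p
            with open(p, "w") as fh:
                fh.write(f"# synthetic annotations seed={instance.seed}\n")
                for node in sorted(ann.mapping):
                    for term in sorted(ann.mapping[node]):
                        fh.write(f"{node}\t{term}\n")
    return paths
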