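import itertools
import math

import numpy as np
import pytest

from ppialign.assess import (assessment_report, build_alignment_graph,
                             connected_components, conserved_edge_count,
                             enrich_components, hypergeometric_pvalue)
from ppialign.model import AnnotationSet, Matching

from conftest import net, random_net


def identity_matching(g, h=None, scores=None):
    h = h or g
    n = min(g.n, h.n)
    return Matching(pairs=[(i, i) for i in range(n)],
                    scores=scores or [1.0] * n, shape=(g.n, h.n))


def brute_conserved(matching, netA, netB):
    """Independent double loop over pairs of matches."""
    count = 0
    A, B = netA.adjacency.toarray(), netB.adjacency.toarray()
    for (i1, j1), (i2, j2) in itertools.combinations(matching.pairs, 2):
        if A[i1, i2] and B[j1, j2]:
            count += 1
    return count


class TestAlignmentGraph:
    def test_identity_matched_triangles(self, triangle):
        ag = build_alignment_graph(identity_matching(triangle), triangle, triangle)
        assert ag.n_nodes == 3 and conserved_edge_count(ag) == 3

    def test_single_pair_has_no_edges(self, triangle):
        m = Matching(pairs=[(0, 0)], scores=[1.0], shape=(3, 3))
        ag = build_alignment_graph(m, triangle, triangle)
        assert ag.n_nodes == 1 and ag.n_edges == 0

    def test_triangle_vs_path_conserves_only_shared_edges(self, triangle, path3):
        ag = build_alignment_graph(identity_matching(triangle, path3), triangle, path3)
        assert conserved_edge_count(ag) == 2

    def test_k4_self_alignment(self):
        k4 = net(list(itertools.combinations("abcd", 2)))
        ag = build_alignment_graph(identity_matching(k4), k4, k4)
        assert conserved_edge_count(ag) == 6

    def test_out_of_range_pair_errors(self, triangle):
        m = Matching(pairs=[(0, 5)], scores=[1.0])
        with pytest.raises(IndexError):
            build_alignment_graph(m, triangle, triangle)

    def test_conserved_count_matches_brute_force_on_random(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            A = random_net(rng, int(rng.integers(3, 10)), name="A")
            B = random_net(rng, int(rng.integers(3, 10)), name="B")
            n = min(A.n, B.n)
            cols = rng.permutation(B.n)[:n]
            m = Matching(pairs=[(i, int(cols[i])) for i in range(n)],
                         scores=[1.0] * n, shape=(A.n, B.n))
            ag = build_alignment_graph(m, A, B)
            assert conserved_edge_count(ag) == brute_conserved(m, A, B)
            assert conserved_edge_count(ag) <= min(A.n_edges, B.n_edges)

    def test_self_alignment_conserves_all_edges(self):
        rng = np.random.default_rng(14)
        g = random_net(rng, 12)
        ag = build_alignment_graph(identity_matching(g), g, g)
        assert conserved_edge_count(ag) == g.n_edges


class TestComponents:
    def test_edgeless_graph_gives_singletons(self, triangle):
        g = net([("a", "b")], extra=["c", "d", "e"])  # path + isolated
        m = Matching(pairs=[(2, 2), (3, 3), (4, 4)], scores=[1] * 3,
                     shape=(g.n, g.n))
        ag = build_alignment_graph(m, g, g)
        comps = connected_components(ag)
        assert [len(c) for c in comps] == [1, 1, 1]

    def test_triangle_is_one_component(self, triangle):
        ag = build_alignment_graph(identity_matching(triangle), triangle, triangle)
        assert [len(c) for c in connected_components(ag)] == [3]

    def test_two_disjoint_conserved_edges(self):
        g = net([("a", "b"), ("c", "d")])
        ag = build_alignment_graph(identity_matching(g), g, g)
        comps = connected_components(ag)
        assert [len(c) for c in comps] == [2, 2]

    def test_sorted_by_size_then_representative(self):
        g = net([("a", "b"), ("b", "c"), ("x", "y")])
        ag = build_alignment_graph(identity_matching(g), g, g)
        comps = connected_components(ag)
        assert len(comps[0]) == 3 and len(comps[1]) == 2


class TestEnrichment:
    def test_planted_module_exact_pvalue(self):
        # 3 of 3 drawn carry the term out of 3 carriers in a background of 10
        p = hypergeometric_pvalue(3, 3, 3, 10)
        assert p == pytest.approx(1 / math.comb(10, 3))
        assert p <= 0.05

    def test_matches_exhaustive_enumeration_small_backgrounds(self):
        rng = np.random.default_rng(6)
        for _ in range(40):
            N = int(rng.integers(2, 13))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(1, N + 1))
            k = int(rng.integers(0, min(K, n) + 1))
            # enumerate all draws of size n from N with K carriers
            hits = total = 0
            for draw in itertools.combinations(range(N), n):
                total += 1
                if sum(1 for x in draw if x < K) >= k:
                    hits += 1
            assert hypergeometric_pvalue(k, n, K, N) == pytest.approx(hits / total)

    def _simple_setup(self):
        # one aligned component of 3 annotated nodes in a background of 10
        comp = [(f"a{i}", f"b{i}") for i in range(3)]
        mapA = {f"a{i}": {"T"} for i in range(3)}
        mapB = {f"b{i}": {"T"} for i in range(3)}
        annA = AnnotationSet(mapA, {f"a{i}" for i in range(10)})
        annB = AnnotationSet(mapB, {f"b{i}" for i in range(10)})
        return [comp], annA, annB

    def test_enriched_component_gives_full_tnr(self):
        comps, annA, annB = self._simple_setup()
        rep = enrich_components(comps, annA, annB)
        assert rep.tnr == {"A": 100.0, "B": 100.0}
        assert rep.tpr == {"A": 1, "B": 1}
        (_, _, term, p, enr) = rep.records[0]
        assert term == "T" and enr and p == pytest.approx(1 / 120)

    def test_component_without_shared_terms_not_enriched(self):
        comp = [("a0", "b0"), ("a1", "b1")]
        annA = AnnotationSet({"a5": {"T"}}, {f"a{i}" for i in range(10)})
        annB = AnnotationSet({"b5": {"T"}}, {f"b{i}" for i in range(10)})
        rep = enrich_components([comp], annA, annB)
        assert rep.tnr == {"A": 0.0, "B": 0.0} and rep.tpr == {"A": 0, "B": 0}

    def test_tpr_counts_union_of_terms(self):
        # two components enriched for the same term count once
        comps = [[("a0", "b0"), ("a1", "b1")], [("a2", "b2"), ("a3", "b3")]]
        mapA = {f"a{i}": {"T"} for i in range(4)}
        annA = AnnotationSet(mapA, set(mapA) | {f"a{i}" for i in range(4, 30)})
        annB = AnnotationSet({}, {f"b{i}" for i in range(30)})
        rep = enrich_components(comps, annA, annB)
        assert rep.tpr["A"] == 1 and rep.tnr["A"] == 100.0

    def test_threshold_monotonicity(self):
        comps, annA, annB = self._simple_setup()
        lo = enrich_components(comps, annA, annB, threshold=0.001)
        hi = enrich_components(comps, annA, annB, threshold=0.5)
        assert hi.tpr["A"] >= lo.tpr["A"]
        assert hi.tnr["A"] >= lo.tnr["A"]

    def test_empty_component_list_flagged(self):
        annA = AnnotationSet({}, {"a"})
        rep = enrich_components([], annA, annA)
        assert rep.tnr["A"] is None and rep.tpr["A"] == 0


class TestAssessmentReport:
    def test_topological_only_without_annotations(self, triangle):
        rep = assessment_report(identity_matching(triangle), triangle, triangle)
        assert rep["conserved_edges"] == 3
        assert "enrichment" not in rep

    def test_self_alignment_limit(self):
        rng = np.random.default_rng(3)
        g = random_net(rng, 10)
        rep = assessment_report(identity_matching(g), g, g)
        assert rep["conserved_edges"] == g.n_edges

    def test_full_report_with_annotations(self, triangle):
        ann = AnnotationSet({"a": {"T"}, "b": {"T"}, "c": {"T"}},
                            {"a", "b", "c", "d", "e", "f", "g", "h", "i", "j"})
        rep = assessment_report(identity_matching(triangle), triangle, triangle,
                                ann, ann)
        assert rep["enrichment"]["tpr"]["A"] == 1
        assert rep["enrichment"]["tnr"]["A"] == 100.0
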