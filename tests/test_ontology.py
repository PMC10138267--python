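"""Ontology parsing, closure, enrichment, similarity and redundancy filtering."""

import math
from collections import deque
from fractions import Fraction

import numpy as np
import pytest

from allodis.ontology import (
    OntologyStructureError,
    SimilarityMatrix,
    ancestor_closure,
    gene_overlap_test,
    independence_filter,
    mds_embedding,
    parse_obo,
    redundancy_filter,
    shortest_path_similarity,
    term_enrichment,
)
from allodis.simulate import SimConfig, gen_ontology
from tests.conftest import CHAIN_OBO


def hypergeom_upper_tail(N, K, n, k):
    """Brute-force P(X >= k) by direct summation of the hypergeometric pmf."""
    total = Fraction(0)
    for x in range(k, min(n, K) + 1):
        total += Fraction(math.comb(K, x) * math.comb(N - K, n - x), math.comb(N, n))
    return float(total)


def bfs_path_nodes(adj, src, dst):
    """Number of nodes on the shortest path via plain breadth-first search."""
    dist = {src: 0}
    q = deque([src])
    while q:
        u = q.popleft()
        if u == dst:
            return dist[u] + 1
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    return None


class TestParseObo:
    def test_minimal_chain(self, chain_ontology):
        assert len(chain_ontology) == 3
        assert chain_ontology.root_ids == {"A"}
        assert chain_ontology.terms["C"].parent_ids == {"B"}

    def test_obsolete_flag_passthrough(self):
        obo = CHAIN_OBO + "\n[Term]\nid: OLD\nname: gone\nis_obsolete: true\n"
        onto = parse_obo(obo)
        assert onto.terms["OLD"].obsolete
        assert "OLD" not in onto.root_ids
        with pytest.raises(KeyError):
            ancestor_closure(onto, "OLD")

    def test_random_dag_roundtrip(self):
        onto, obo_text, *_ = gen_ontology(SimConfig(seed=3, ontology_size=50))
        reparsed = parse_obo(obo_text)
        assert set(reparsed.terms) == set(onto.terms)
        for tid in onto.terms:
            assert reparsed.terms[tid].parent_ids == onto.terms[tid].parent_ids

    def test_cycle_rejected(self):
        obo = (
            "format-version: 1.2\nontology: t\n\n"
            "[Term]\nid: A\nname: a\nis_a: B\n\n[Term]\nid: B\nname: b\nis_a: A\n"
        )
        with pytest.raises(OntologyStructureError, match="cycle"):
            parse_obo(obo)

    def test_dangling_parent_rejected(self):
        obo = "format-version: 1.2\nontology: t\n\n[Term]\nid: A\nname: a\nis_a: MISSING\n"
        with pytest.raises(OntologyStructureError, match="MISSING"):
            parse_obo(obo)

    def test_empty_stream_rejected(self):
        with pytest.raises(ValueError):
            parse_obo("format-version: 1.2\nontology: t\n")


class TestAncestorClosure:
    def test_chain(self, chain_ontology):
        assert ancestor_closure(chain_ontology, "C") == {"A", "B", "C"}

    def test_root_fixed_point(self, chain_ontology):
        assert ancestor_closure(chain_ontology, "A") == {"A"}

    def test_diamond_exhaustive(self, diamond_ontology):
        # all parent-paths from D: D->B->A and D->C->A
        assert ancestor_closure(diamond_ontology, "D") == {"A", "B", "C", "D"}

    def test_unknown_term(self, chain_ontology):
        with pytest.raises(KeyError):
            ancestor_closure(chain_ontology, "nope")

    def test_idempotent(self):
        onto, *_ = gen_ontology(SimConfig(seed=5, ontology_size=40))
        for tid in list(onto.terms)[::7]:
            closure = ancestor_closure(onto, tid)
            closed_again = set()
            for t in closure:
                closed_again |= ancestor_closure(onto, t)
            assert closed_again == set(closure)


class TestTermEnrichment:
    def test_closed_form_example(self):
        # N=20 population, K=5 with the term, study n=4 with k=3 hits
        ann = {f"p{i}": frozenset(["T"] if i < 5 else ["U"]) for i in range(20)}
        study = ["p0", "p1", "p2", "p5"]
        res = {r.term_id: r for r in term_enrichment(study, ann)}
        assert res["T"].k == 3
        assert res["T"].p_raw == pytest.approx(155 / 4845, rel=1e-12)

    def test_saturation(self):
        ann = {f"p{i}": frozenset(["T"]) for i in range(6)}
        res = term_enrichment(list(ann), ann)[0]
        assert (res.k, res.n, res.K, res.N) == (6, 6, 6, 6)
        assert res.p_raw == pytest.approx(1.0)

    def test_zero_hits_tail_is_one(self):
        ann = {"a": frozenset(["T"]), "b": frozenset(["U"]), "c": frozenset(["U"])}
        res = {r.term_id: r for r in term_enrichment(["b"], ann)}
        assert res["T"].p_raw == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_small_populations(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(8, 31))
        ann = {}
        for i in range(N):
            terms = {t for t in "TUV" if rng.random() < 0.4} or {"W"}
            ann[f"p{i}"] = frozenset(terms)
        n = int(rng.integers(2, N))
        study = list(rng.choice(sorted(ann), size=n, replace=False))
        for r in term_enrichment(study, ann):
            assert r.p_raw == pytest.approx(
                hypergeom_upper_tail(r.N, r.K, r.n, r.k), rel=1e-9
            )

    def test_adjustment_dominates_raw(self):
        ann = {f"p{i}": frozenset("TU"[i % 2]) for i in range(10)}
        for method in ("bonferroni", "bh_fdr"):
            for r in term_enrichment(["p0", "p2"], ann, correction=method):
                assert r.p_adj >= r.p_raw - 1e-12

    def test_errors(self):
        ann = {"a": frozenset(["T"])}
        with pytest.raises(ValueError):
            term_enrichment([], ann)
        with pytest.raises(ValueError, match="absent"):
            term_enrichment(["zz"], ann)


class TestIndependenceFilter:
    def test_leukemia_example(self, chain_ontology):
        # B ("leukemia") is an ancestor of C ("myeloid leukemia"): keep C only
        assert independence_filter(chain_ontology, {"B", "C"}) == {"C"}

    def test_siblings_kept(self, diamond_ontology):
        assert independence_filter(diamond_ontology, {"B", "C"}) == {"B", "C"}

    def test_chain_collapses_to_leaf(self, chain_ontology):
        assert independence_filter(chain_ontology, {"A", "B", "C"}) == {"C"}

    def test_antichain_property(self):
        onto, *_ = gen_ontology(SimConfig(seed=9, ontology_size=60))
        ids = sorted(onto.terms)[::3]
        kept = independence_filter(onto, ids)
        for a in kept:
            for b in kept:
                if a != b:
                    assert a not in (ancestor_closure(onto, b) - {b})


class TestShortestPathSimilarity:
    def test_chain_lengths_and_sims(self, chain_ontology):
        # undirected chain A-B-C: lengths (nodes incl. endpoints) max = 3
        sm = shortest_path_similarity(chain_ontology, ["A", "B", "C"])
        assert sm.length_max == 3
        i = {t: k for k, t in enumerate(sm.term_ids)}
        assert sm.sim[i["A"], i["C"]] == pytest.approx(1 / 3)
        assert sm.sim[i["A"], i["B"]] == pytest.approx(2 / 3)
        assert np.allclose(np.diag(sm.sim), 1.0)
        assert np.allclose(sm.sim, sm.sim.T)

    def test_extreme_pair_forced_value(self, diamond_ontology):
        sm = shortest_path_similarity(diamond_ontology, ["B", "C", "D"])
        assert sm.sim.min() == pytest.approx(1 / sm.length_max)

    def test_matches_bfs_oracle(self):
        onto, *_ = gen_ontology(SimConfig(seed=13, ontology_size=80))
        adj = {t: set() for t in onto.terms}
        for t, term in onto.terms.items():
            for p in term.parent_ids:
                adj[t].add(p)
                adj[p].add(t)
        ids = sorted(onto.terms)[::5]
        sm = shortest_path_similarity(onto, ids)
        lengths = np.array(
            [[bfs_path_nodes(adj, a, b) for b in ids] for a in ids]
        )
        lmax = lengths.max()
        assert sm.length_max == lmax
        assert np.allclose(sm.sim, (lmax - lengths + 1) / lmax)

    def test_disconnected_pair_raises(self):
        obo = (
            "format-version: 1.2\nontology: t\n\n"
            "[Term]\nid: A\nname: a\n\n[Term]\nid: B\nname: b\n"
        )
        onto = parse_obo(obo)
        with pytest.raises(ValueError, match="disconnected"):
            shortest_path_similarity(onto, ["A", "B"])


class TestRedundancyFilter:
    def _sim(self, ids, value):
        m = np.full((len(ids), len(ids)), value, dtype=float)
        np.fill_diagonal(m, 1.0)
        return SimilarityMatrix(term_ids=list(ids), sim=m, length_max=2)

    def test_keeps_more_significant(self, chain_ontology):
        sm = self._sim(["B", "C"], 0.95)
        kept = redundancy_filter(sm, {"B": 1e-3, "C": 1e-6}, chain_ontology)
        assert kept == {"C"}

    def test_below_threshold_noop(self, chain_ontology):
        sm = self._sim(["B", "C"], 0.9)  # not strictly greater than 0.9
        kept = redundancy_filter(sm, {"B": 0.5, "C": 0.5}, chain_ontology)
        assert kept == {"B", "C"}

    def test_tie_keeps_higher_term(self, chain_ontology):
        # equal p: keep B (closure depth 2) over C (depth 3)
        sm = self._sim(["B", "C"], 0.95)
        kept = redundancy_filter(sm, {"B": 1e-4, "C": 1e-4}, chain_ontology)
        assert kept == {"B"}

    def test_order_independent_for_distinct_p(self):
        onto, *_ = gen_ontology(SimConfig(seed=21, ontology_size=30))
        ids = sorted(onto.terms)[:12]
        rng = np.random.default_rng(0)
        pvals = {t: float(p) for t, p in zip(ids, rng.permutation(len(ids)) + 1)}
        sm = shortest_path_similarity(onto, ids)
        baseline = redundancy_filter(sm, pvals, onto, threshold=0.5)
        for _ in range(5):
            perm = list(rng.permutation(len(ids)))
            sm2 = SimilarityMatrix(
                term_ids=[ids[i] for i in perm],
                sim=sm.sim[np.ix_(perm, perm)],
                length_max=sm.length_max,
            )
            assert redundancy_filter(sm2, pvals, onto, threshold=0.5) == baseline

    def test_threshold_validation(self, chain_ontology):
        sm = self._sim(["B", "C"], 0.95)
        with pytest.raises(ValueError):
            redundancy_filter(sm, {"B": 0.1, "C": 0.2}, chain_ontology, threshold=1.5)


class TestMdsEmbedding:
    def test_345_triangle_recovered(self):
        d = np.array([[0, 0.3, 0.4], [0.3, 0, 0.5], [0.4, 0.5, 0]])
        sm = SimilarityMatrix(term_ids=["a", "b", "c"], sim=1 - d, length_max=2)
        coords = mds_embedding(sm)
        pts = np.array([coords[t] for t in sm.term_ids])
        for (i, j), want in [((0, 1), 0.3), ((0, 2), 0.4), ((1, 2), 0.5)]:
            assert np.linalg.norm(pts[i] - pts[j]) == pytest.approx(want, abs=1e-6)

    def test_identical_terms_coincide(self):
        d = np.array([[0, 0, 0.4], [0, 0, 0.4], [0.4, 0.4, 0]])
        sm = SimilarityMatrix(term_ids=["a", "b", "c"], sim=1 - d, length_max=2)
        coords = mds_embedding(sm)
        assert coords["a"] == pytest.approx(coords["b"], abs=1e-8)

    def test_2d_stress_not_worse_than_1d(self):
        onto, *_ = gen_ontology(SimConfig(seed=17, ontology_size=40))
        ids = sorted(onto.terms)[::4][:10]
        sm = shortest_path_similarity(onto, ids)
        coords = mds_embedding(sm)
        pts = np.array([coords[t] for t in sm.term_ids])
        d = 1 - sm.sim

        def stress(p):
            dhat = np.linalg.norm(p[:, None, :] - p[None, :, :], axis=-1)
            return float(((d - dhat) ** 2).sum())

        assert stress(pts) <= stress(pts[:, :1]) + 1e-12

    def test_too_few_terms(self):
        sm = SimilarityMatrix(term_ids=["a", "b"], sim=np.eye(2), length_max=2)
        with pytest.raises(ValueError):
            mds_embedding(sm)


class TestGeneOverlapTest:
    def test_disjoint_lists_enumeration(self):
        _, p = gene_overlap_test({"1", "2"}, {"3", "4"}, {"1", "2", "3", "4"})
        assert p == pytest.approx(1 / 3, rel=1e-9)

    def test_identical_lists_most_extreme(self):
        universe = {str(i) for i in range(10)}
        a = {"0", "1", "2"}
        _, p = gene_overlap_test(a, a, universe)
        # only tables at least as extreme: enumerate hypergeometric with margins (3,3)
        probs = [
            math.comb(3, x) * math.comb(7, 3 - x) / math.comb(10, 3)
            for x in range(4)
        ]
        expected = sum(q for q in probs if q <= probs[3] * (1 + 1e-9))
        assert p == pytest.approx(expected, rel=1e-6)

    def test_independent_overlap_near_one(self):
        universe = {str(i) for i in range(20)}
        a = {str(i) for i in range(10)}
        b = {str(i) for i in range(0, 20, 2)}  # overlap 5 = expected 10*10/20
        _, p = gene_overlap_test(a, b, universe)
        assert p > 0.99

    def test_empty_universe(self):
        with pytest.raises(ValueError):
            gene_overlap_test(set(), set(), set())
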