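"""Ontology handling: OBO parsing, closures, enrichment and redundancy filtering.

Disease (and GO-like) ontologies are rooted DAGs under ``is_a``. This module
parses the OBO flat-file format, computes ancestor closures used to propagate
protein-disease annotations upwards, performs hypergeometric term enrichment,
and implements the edge-based semantic-similarity pipeline used to de-redundify
enriched term lists: a shortest-path similarity

    sim(i, j) = (length_max - length_ij + 1) / length_max

where ``length_ij`` counts the nodes (endpoints inclusive) on the shortest
undirected path between terms i and j and ``length_max`` is the longest such
path among the supplied pairs, followed by a greedy filter that keeps only the
more significant term of every pair with sim above a threshold, and a classical
multidimensional-scaling embedding of the retained terms into a 2-D semantic
plane.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import obonet
from scipy import stats

__all__ = [
    "OntologyTerm",
    "Ontology",
    "EnrichmentResult",
    "SimilarityMatrix",
    "parse_obo",
    "ancestor_closure",
    "term_enrichment",
    "independence_filter",
    "shortest_path_similarity",
    "redundancy_filter",
    "mds_embedding",
    "gene_overlap_test",
    "write_enrichment_tsv",
]


class OntologyStructureError(ValueError):
    """Raised for cyclic is_a graphs or dangling parent references."""


@dataclass(frozen=True)
class OntologyTerm:
    term_id: str
    name: str = ""
    parent_ids: frozenset[str] = field(default_factory=frozenset)
    obsolete: bool = False


@dataclass
class Ontology:
    """A rooted DAG of terms under ``is_a`` edges.

    ``root_ids`` are the non-obsolete terms with no parents. Obsolete terms
    are retained for bookkeeping but excluded from every traversal.
    """

    terms: dict[str, OntologyTerm]
    root_ids: frozenset[str]

    def __post_init__(self) -> None:
        self._validate()
        self._closure_cache: dict[str, frozenset[str]] = {}
        self._undirected: nx.Graph | None = None

    def _validate(self) -> None:
        for term in self.terms.values():
            if term.obsolete:
                continue
            for pid in term.parent_ids:
                if pid not in self.terms:
                    raise OntologyStructureError(
                        f"term {term.term_id!r} references missing parent {pid!r}"
                    )
        dg = self._digraph()
        if not nx.is_directed_acyclic_graph(dg):
            cycle = nx.find_cycle(dg)
            raise OntologyStructureError(
                f"is_a graph contains a cycle through {cycle[0][0]!r}"
            )

    def _digraph(self) -> nx.DiGraph:
        """Directed child -> parent graph over non-obsolete terms."""
        dg = nx.DiGraph()
        for term in self.terms.values():
            if term.obsolete:
                continue
            dg.add_node(term.term_id)
            for pid in term.parent_ids:
                dg.add_edge(term.term_id, pid)
        return dg

    def undirected_graph(self) -> nx.Graph:
        if self._undirected is None:
            self._undirected = self._digraph().to_undirected()
        return self._undirected

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)


def parse_obo(obo_text: str | io.TextIOBase) -> Ontology:
    """Parse an OBO 1.2 flat file into an :class:`Ontology`.

    Only the ``[Term]`` stanza keys ``id``, ``name``, ``is_a`` and
    ``is_obsolete`` are interpreted. Terms without parents become roots.
    """
    handle = io.StringIO(obo_text) if isinstance(obo_text, str) else obo_text
    graph = obonet.read_obo(handle, ignore_obsolete=False)
    terms: dict[str, OntologyTerm] = {}
    for node, data in graph.nodes(data=True):
        if not data:
            # obonet materialises dangling is_a targets as attribute-less nodes
            continue
        obsolete = str(data.get("is_obsolete", "false")).lower() == "true"
        parents = frozenset() if obsolete else frozenset(data.get("is_a", []))
        terms[node] = OntologyTerm(
            term_id=node,
            name=data.get("name", ""),
            parent_ids=parents,
            obsolete=obsolete,
        )
    if not terms:
        raise ValueError("OBO stream contains no [Term] stanza")
    roots = frozenset(
        t.term_id for t in terms.values() if not t.obsolete and not t.parent_ids
    )
    return Ontology(terms=terms, root_ids=roots)


def ancestor_closure(ontology: Ontology, term_id: str) -> frozenset[str]:
    """The term itself plus every term reachable by following is_a parents."""
    if term_id not in ontology.terms:
        raise KeyError(f"unknown term {term_id!r}")
    term = ontology.terms[term_id]
    if term.obsolete:
        raise KeyError(f"term {term_id!r} is obsolete and excluded from traversal")
    cached = ontology._closure_cache.get(term_id)
    if cached is not None:
        return cached
    seen: set[str] = set()
    stack = [term_id]
    while stack:
        tid = stack.pop()
        if tid in seen:
            continue
        seen.add(tid)
        stack.extend(ontology.terms[tid].parent_ids)
    result = frozenset(seen)
    ontology._closure_cache[term_id] = result
    return result


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    name: str
    k: int  # study-set hits
    n: int  # study-set size
    K: int  # population hits
    N: int  # population size
    p_raw: float
    p_adj: float
    method: str


def term_enrichment(
    study_ids: Iterable[str],
    annotations: Mapping[str, frozenset[str] | set[str]],
    correction: str = "bh_fdr",
    names: Mapping[str, str] | None = None,
) -> list[EnrichmentResult]:
    """Hypergeometric (upper-tail) term enrichment of a study set.

    ``annotations`` maps every population protein to its ancestor-closed term
    set; ``study_ids`` must be a subset of the population. For every term
    annotated in the population, ``p_raw = P(X >= k)`` for X hypergeometric
    with population N, K marked, n drawn. Multiple-testing correction is
    Bonferroni (``min(1, m*p)``) or Benjamini-Hochberg step-up FDR.
    """
    if correction not in ("bonferroni", "bh_fdr"):
        raise ValueError(f"unknown correction {correction!r}")
    study = set(study_ids)
    if not study:
        raise ValueError("study set is empty")
    missing = study - set(annotations)
    if missing:
        raise ValueError(
            f"study ids absent from annotated population: {sorted(missing)[:10]}"
        )
    N = len(annotations)
    n = len(study)
    pop_count: dict[str, int] = {}
    study_count: dict[str, int] = {}
    for pid, terms in annotations.items():
        in_study = pid in study
        for t in terms:
            pop_count[t] = pop_count.get(t, 0) + 1
            if in_study:
                study_count[t] = study_count.get(t, 0) + 1
    term_ids = sorted(pop_count)
    p_raw = np.array(
        [
            stats.hypergeom.sf(study_count.get(t, 0) - 1, N, pop_count[t], n)
            for t in term_ids
        ]
    )
    p_raw = np.clip(p_raw, 0.0, 1.0)
    m = len(term_ids)
    if correction == "bonferroni":
        p_adj = np.minimum(1.0, m * p_raw)
    else:
        order = np.argsort(p_raw, kind="stable")
        adj = np.empty(m)
        running = 1.0
        for rank_from_end, idx in enumerate(order[::-1]):
            rank = m - rank_from_end  # 1-based rank of this p in ascending order
            running = min(running, p_raw[idx] * m / rank)
            adj[idx] = running
        p_adj = adj
    results = [
        EnrichmentResult(
            term_id=t,
            name=(names or {}).get(t, ""),
            k=study_count.get(t, 0),
            n=n,
            K=pop_count[t],
            N=N,
            p_raw=float(p_raw[i]),
            p_adj=float(p_adj[i]),
            method=correction,
        )
        for i, t in enumerate(term_ids)
    ]
    results.sort(key=lambda r: (r.p_raw, r.term_id))
    return results


def write_enrichment_tsv(results: Sequence[EnrichmentResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("term_id\tname\tk\tn\tK\tN\tp_raw\tp_adj\tmethod\n")
        for r in results:
            fh.write(
                f"{r.term_id}\t{r.name}\t{r.k}\t{r.n}\t{r.K}\t{r.N}\t"
                f"{r.p_raw:.6g}\t{r.p_adj:.6g}\t{r.method}\n"
            )


def independence_filter(ontology: Ontology, term_ids: Iterable[str]) -> frozenset[str]:
    """Drop every term that is a proper ancestor of another supplied term.

    The result is an antichain under the ancestor relation: only the lowest
    (most specific) term on any root-ward path survives; terms on different
    branches are all kept.
    """
    ids = set(term_ids)
    for tid in ids:
        if tid not in ontology.terms:
            raise KeyError(f"unknown term {tid!r}")
    ancestors_of_supplied: set[str] = set()
    for tid in ids:
        ancestors_of_supplied.update(ancestor_closure(ontology, tid) - {tid})
    return frozenset(ids - ancestors_of_supplied)


@dataclass
class SimilarityMatrix:
    term_ids: list[str]
    sim: np.ndarray
    length_max: int


def shortest_path_similarity(
    ontology: Ontology, term_ids: Sequence[str]
) -> SimilarityMatrix:
    """Edge-based pairwise similarity from undirected shortest-path lengths.

    ``length_ij`` is the number of nodes on the shortest path between i and j
    in the undirected is_a graph of the full ontology (endpoints included, so
    an identical pair has length 1 and adjacent terms length 2). With
    ``length_max`` the largest length among the supplied pairs,
    ``sim = (length_max - length_ij + 1) / length_max``.
    """
    ids = list(term_ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 terms")
    g = ontology.undirected_graph()
    for tid in ids:
        if tid not in g:
            raise KeyError(f"unknown or obsolete term {tid!r}")
    m = len(ids)
    lengths = np.ones((m, m), dtype=int)
    for a in range(m):
        dist = nx.single_source_shortest_path_length(g, ids[a])
        for b in range(a + 1, m):
            if ids[b] not in dist:
                raise ValueError(f"terms {ids[a]!r} and {ids[b]!r} are disconnected")
            lengths[a, b] = lengths[b, a] = dist[ids[b]] + 1
    length_max = int(lengths.max())
    sim = (length_max - lengths + 1) / length_max
    return SimilarityMatrix(term_ids=ids, sim=sim, length_max=length_max)


def redundancy_filter(
    sim: SimilarityMatrix,
    pvalues: Mapping[str, float],
    ontology: Ontology,
    threshold: float = 0.9,
    epsilon: float = 0.0,
) -> frozenset[str]:
    """Collapse near-synonymous term pairs, keeping the more significant term.

    While any retained pair has ``sim > threshold``, the globally least
    significant term participating in such a pair is dropped — a canonical
    fixpoint that does not depend on the order pairs are visited, so the
    result is invariant under permutations of the input for strictly
    distinct p-values. When the worst offenders' p-values agree to within
    ``epsilon`` (exact equality by default), the term located lower in the
    ontology — the one with the larger ancestor closure — is dropped first,
    keeping the higher-level term; any remaining tie breaks by term id.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    ids = sim.term_ids
    missing = [t for t in ids if t not in pvalues]
    if missing:
        raise ValueError(f"p-values missing for terms: {missing[:10]}")
    m = len(ids)
    offending = {
        frozenset((ids[a], ids[b]))
        for a in range(m)
        for b in range(a + 1, m)
        if sim.sim[a, b] > threshold
    }
    retained = set(ids)
    while True:
        live = [p for p in offending if p <= retained]
        if not live:
            break
        candidates = {t for p in live for t in p}
        worst_p = max(pvalues[t] for t in candidates)
        # within epsilon of the worst: prefer to drop the deeper term
        near_worst = [t for t in candidates if abs(pvalues[t] - worst_p) <= epsilon]
        drop = max(
            near_worst,
            key=lambda t: (len(ancestor_closure(ontology, t)), t),
        )
        retained.discard(drop)
    return frozenset(retained)


def mds_embedding(sim: SimilarityMatrix) -> dict[str, tuple[float, float]]:
    """Classical (Torgerson) metric MDS of ``d = 1 - sim`` into two dimensions.

    Double-centres the squared distance matrix and takes the top-two
    eigenvectors scaled by the square root of their eigenvalues; a distance
    matrix exactly embeddable in the plane is reproduced to numerical
    tolerance, up to rotation and reflection.
    """
    m = len(sim.term_ids)
    if m < 3:
        raise ValueError("need at least 3 terms for an embedding")
    d = 1.0 - np.asarray(sim.sim, dtype=float)
    b = _double_centre(d)
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    coords = np.zeros((m, 2))
    for dim in range(2):
        lam = eigval[order[dim]]
        if lam > 0:
            coords[:, dim] = eigvec[:, order[dim]] * math.sqrt(lam)
    return {tid: (float(x), float(y)) for tid, (x, y) in zip(sim.term_ids, coords)}


def _double_centre(d: np.ndarray) -> np.ndarray:
    d2 = d**2
    j = np.eye(len(d)) - np.ones_like(d2) / len(d)
    return -0.5 * j @ d2 @ j


def gene_overlap_test(
    list_a: Iterable[str], list_b: Iterable[str], universe: Iterable[str]
) -> tuple[float, float]:
    """Two-sided Fisher exact test of the overlap between two protein lists.

    Returns ``(odds_ratio, p_two_sided)`` from the 2x2 table
    ``[[|A&B|, |A-B|], [|B-A|, |U-(A|B)|]]``.
    """
    u = set(universe)
    if not u:
        raise ValueError("universe is empty")
    a, b = set(list_a), set(list_b)
    if not a <= u or not b <= u:
        raise ValueError("lists must be subsets of the universe")
    both = len(a & b)
    table = [[both, len(a) - both], [len(b) - both, len(u - (a | b))]]
    res = stats.fisher_exact(table, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
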