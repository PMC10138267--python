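"""Disease-protein projection and PPI graphs, centralities and group statistics.

The disease-protein network follows the diseasome construction: proteins are
nodes and an edge joins two proteins associated with at least one common
disease, weighted by the number of shared diseases. PPI networks are simple
unweighted graphs from binary interaction pairs. Betweenness centrality is
reported unnormalised (raw shortest-path counts) so that absolute thresholds
such as 1000 are meaningful; an optional weighted mode treats edge length as
the reciprocal of the weight. Group comparisons use Wilcoxon rank-sum or
two-sample proportion tests, and covariate-adjusted comparisons an ANCOVA on
log-transformed values.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .annotation import ProteinAnnotation

__all__ = [
    "CentralityTable",
    "GroupComparison",
    "JointCentralitySummary",
    "project_disease_network",
    "build_ppi_graph",
    "compute_centralities",
    "component_summary",
    "compare_groups",
    "joint_centrality_summary",
    "ancova_log",
]


@dataclass
class CentralityTable:
    """Per-node betweenness (raw path counts) and degree."""

    betweenness: dict[str, float]
    degree: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        nodes = sorted(self.betweenness)
        return pd.DataFrame(
            {
                "protein_id": nodes,
                "betweenness": [self.betweenness[n] for n in nodes],
                "degree": [self.degree[n] for n in nodes],
            }
        )


@dataclass
class GroupComparison:
    groups: tuple[str, str]
    n: tuple[int, int]
    summary: tuple[float, float]  # medians or proportions
    test: str
    statistic: float
    p_value: float


@dataclass
class JointCentralitySummary:
    fraction_above: dict[str, float]  # group -> fraction above threshold in both
    correlation: float
    n_included: int


def project_disease_network(
    annotations: Sequence[ProteinAnnotation],
) -> nx.Graph:
    """Project protein-disease annotations onto a weighted protein graph.

    Every annotated protein becomes a node (isolated when it shares no
    disease); proteins sharing >= 1 independent disease term are joined by an
    edge whose weight is the number of shared terms.
    """
    seen: set[str] = set()
    for ann in annotations:
        if ann.protein_id in seen:
            raise ValueError(f"duplicate protein id {ann.protein_id!r}")
        seen.add(ann.protein_id)
    g = nx.Graph()
    for ann in annotations:
        g.add_node(
            ann.protein_id,
            group=ann.group,
            quaternary=ann.quaternary,
            n_diseases=len(ann.doid_independent),
            drug_target=ann.drug_target,
        )
    by_disease: dict[str, list[str]] = {}
    for ann in annotations:
        for d in ann.doid_independent:
            by_disease.setdefault(d, []).append(ann.protein_id)
    for members in by_disease.values():
        for a, b in itertools.combinations(sorted(members), 2):
            if g.has_edge(a, b):
                g[a][b]["weight"] += 1
            else:
                g.add_edge(a, b, weight=1)
    return g


def build_ppi_graph(edges: Iterable[tuple[str, str]]) -> tuple[nx.Graph, int]:
    """Simple undirected PPI graph from binary pairs.

    Duplicate pairs (in either order) collapse to one edge of weight 1;
    self-interactions are dropped and counted. Returns the graph and the
    number of dropped self-loops.
    """
    g = nx.Graph()
    n_self = 0
    for i, pair in enumerate(edges):
        try:
            a, b = pair
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed interaction pair at row {i}: {pair!r}") from exc
        if a == b:
            n_self += 1
            continue
        g.add_edge(a, b, weight=1)
    return g, n_self


def compute_centralities(graph: nx.Graph, weighted: bool = False) -> CentralityTable:
    """Unnormalised betweenness (shortest-path transit counts) and degree.

    With ``weighted=True`` edges act as distances of ``1/weight`` so heavier
    (more shared diseases) edges are shorter.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    if weighted:
        for _, _, data in graph.edges(data=True):
            data["_length"] = 1.0 / data.get("weight", 1)
        bc = nx.betweenness_centrality(graph, normalized=False, weight="_length")
    else:
        bc = nx.betweenness_centrality(graph, normalized=False)
    return CentralityTable(
        betweenness={n: float(v) for n, v in bc.items()},
        degree={n: int(d) for n, d in graph.degree()},
    )


def component_summary(graph: nx.Graph) -> tuple[frozenset[str], int, int]:
    """(largest component, n of smaller multi-node components, n isolated).

    Size ties for the largest component are broken by the lexicographically
    smallest member so outputs are deterministic.
    """
    comps = [frozenset(c) for c in nx.connected_components(graph)]
    if not comps:
        return frozenset(), 0, 0
    comps.sort(key=lambda c: (-len(c), min(c)))
    largest = comps[0]
    isolated = sum(1 for c in comps if len(c) == 1)
    n_small = len(comps) - 1 - (isolated if len(largest) > 1 else isolated - 1)
    return largest, n_small, isolated


def compare_groups(
    values: Mapping[str, float | bool],
    grouping: Mapping[str, str],
    test: str = "wilcoxon",
) -> GroupComparison:
    """Two-group comparison: Wilcoxon rank-sum or a two-sample proportion test.

    The rank-sum test uses the exact null distribution when the combined
    sample size is at most 12 and there are no ties, and otherwise a
    tie-corrected normal approximation without continuity correction. The
    proportion test is the two-sided chi-square test without continuity
    correction on boolean flags.
    """
    labels = sorted(set(grouping.values()))
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    samples = {lab: [values[k] for k in sorted(values) if grouping[k] == lab] for lab in labels}
    a, b = samples[labels[0]], samples[labels[1]]
    if not a or not b:
        raise ValueError("both groups must be non-empty")
    if test == "wilcoxon":
        xa, xb = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
        n_tot = len(xa) + len(xb)
        has_ties = len(np.unique(np.concatenate([xa, xb]))) < n_tot
        if n_tot <= 12 and not has_ties:
            res = stats.mannwhitneyu(xa, xb, method="exact", alternative="two-sided")
        elif len(np.unique(np.concatenate([xa, xb]))) == 1:
            # degenerate: every observation tied — no separation at all
            res = type("R", (), {"statistic": len(xa) * len(xb) / 2, "pvalue": 1.0})
        else:
            res = stats.mannwhitneyu(
                xa, xb, method="asymptotic", use_continuity=False,
                alternative="two-sided",
            )
        return GroupComparison(
            groups=(labels[0], labels[1]),
            n=(len(xa), len(xb)),
            summary=(float(np.median(xa)), float(np.median(xb))),
            test="wilcoxon_rank_sum",
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
        )
    if test == "proportions":
        for sample in (a, b):
            if not all(isinstance(v, (bool, np.bool_)) for v in sample):
                raise TypeError("proportions test requires boolean flags")
        counts = np.array([sum(a), sum(b)], dtype=float)
        nobs = np.array([len(a), len(b)], dtype=float)
        p_pool = counts.sum() / nobs.sum()
        p1, p2 = counts / nobs
        if p_pool in (0.0, 1.0):
            chi2, p = 0.0, 1.0
        else:
            var = p_pool * (1 - p_pool) * (1 / nobs[0] + 1 / nobs[1])
            chi2 = (p1 - p2) ** 2 / var
            p = float(stats.chi2.sf(chi2, df=1))
        return GroupComparison(
            groups=(labels[0], labels[1]),
            n=(len(a), len(b)),
            summary=(float(p1), float(p2)),
            test="proportions_chi2",
            statistic=float(chi2),
            p_value=p,
        )
    raise ValueError(f"unknown test {test!r}")


def joint_centrality_summary(
    cent_a: CentralityTable,
    cent_b: CentralityTable,
    groups: Mapping[str, str],
    threshold: float = 1000.0,
) -> JointCentralitySummary:
    """Joint high-betweenness fractions and log-scale correlation of two networks.

    Proteins with zero betweenness in either table are excluded; the Pearson
    correlation is computed on log10 betweenness over the included proteins,
    and per group the fraction of its included proteins exceeding the
    threshold in both networks is reported.
    """
    shared = sorted(set(cent_a.betweenness) & set(cent_b.betweenness))
    if not shared:
        raise ValueError("no shared proteins between the two centrality tables")
    included = [
        p for p in shared if cent_a.betweenness[p] > 0 and cent_b.betweenness[p] > 0
    ]
    if len(included) >= 2:
        la = np.log10([cent_a.betweenness[p] for p in included])
        lb = np.log10([cent_b.betweenness[p] for p in included])
        corr = float(np.corrcoef(la, lb)[0, 1]) if np.std(la) > 0 and np.std(lb) > 0 else float("nan")
    else:
        corr = float("nan")
    frac: dict[str, float] = {}
    for lab in sorted(set(groups.values())):
        members = [p for p in included if groups.get(p) == lab]
        if members:
            hits = sum(
                1
                for p in members
                if cent_a.betweenness[p] > threshold and cent_b.betweenness[p] > threshold
            )
            frac[lab] = hits / len(members)
    return JointCentralitySummary(
        fraction_above=frac, correlation=corr, n_included=len(included)
    )


def ancova_log(
    y: Mapping[str, float],
    x: Mapping[str, float],
    group: Mapping[str, str],
    pseudocount: float = 1.0,
) -> tuple[float, float]:
    """ANCOVA on log10-transformed response and covariate.

    Fits ``log10(y+c) ~ log10(x+c) + group`` and returns the F-test p-value
    for the group main effect, plus the p-value of the group-by-covariate
    interaction from the model including it (test of equal slopes).
    """
    keys = sorted(set(y) & set(x) & set(group))
    labels = sorted({group[k] for k in keys})
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    ly = np.log10(np.array([y[k] for k in keys], dtype=float) + pseudocount)
    lx = np.log10(np.array([x[k] for k in keys], dtype=float) + pseudocount)
    if not (np.all(np.isfinite(ly)) and np.all(np.isfinite(lx))):
        raise ValueError("log transform produced non-finite values; check pseudocount")
    if np.std(lx) == 0:
        raise ValueError("constant covariate: ANCOVA design is degenerate")
    df = pd.DataFrame(
        {"ly": ly, "lx": lx, "grp": [group[k] for k in keys]}
    )
    main = smf.ols("ly ~ lx + C(grp)", data=df).fit()
    inter = smf.ols("ly ~ lx * C(grp)", data=df).fit()
    main_anova = sm.stats.anova_lm(main, typ=2)
    inter_anova = sm.stats.anova_lm(inter, typ=2)
    group_effect_p = float(main_anova.loc["C(grp)", "PR(>F)"])
    slope_equality_p = float(inter_anova.loc["lx:C(grp)", "PR(>F)"])
    return group_effect_p, slope_equality_p
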