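"""Residue-interaction matrices, mutation clustering and interface enrichment.

Residue-interaction networks (non-covalent contacts from 3-D structures) and
dynamic community labels arrive as typed edge/label tables. Domain contacts
are binned into a 50x50 matrix of normalised sequence units so domains of
different lengths are comparable; matrices are normalised by the domain's
total contact count, optionally rescaled between groups, and log-transformed.
Pathogenic-mutation clustering across communities is scored against a
permutation null that redraws the same number of residues uniformly without
replacement from the community-labelled residues, and interface enrichment of
mutations is tested with an exact binomial model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "RinEdge",
    "ResidueInteractionNetwork",
    "DomainMapping",
    "InteractionMatrix",
    "CommunityAssignment",
    "ClusteringStat",
    "InterfaceEnrichment",
    "select_representative_structure",
    "bin_domain_interactions",
    "normalize_matrix",
    "longrange_comparison",
    "interface_mutation_enrichment",
    "community_clustering_stat",
    "expected_occupied_communities",
]

MATRIX_UNITS = 50
MIN_DOMAIN_LENGTH = 50


@dataclass(frozen=True)
class RinEdge:
    i: int
    j: int
    interaction_type: str  # hbond | vdw | other
    count: int = 1

    def __post_init__(self) -> None:
        if not (1 <= self.i < self.j):
            raise ValueError(f"edge requires 1 <= i < j, got ({self.i}, {self.j})")
        if self.count <= 0:
            raise ValueError("edge count must be positive")


@dataclass
class ResidueInteractionNetwork:
    protein_id: str
    n_residues: int
    edges: list[RinEdge]
    allosteric: bool = False

    def __post_init__(self) -> None:
        for e in self.edges:
            if e.j > self.n_residues:
                raise ValueError(
                    f"edge ({e.i}, {e.j}) outside 1..{self.n_residues}"
                )


@dataclass(frozen=True)
class DomainMapping:
    domain_id: str
    start: int  # inclusive, 1-based
    end: int  # inclusive

    def __post_init__(self) -> None:
        if self.length < MIN_DOMAIN_LENGTH:
            raise ValueError(
                f"domain {self.domain_id!r} shorter than {MIN_DOMAIN_LENGTH} residues"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class InteractionMatrix:
    values: np.ndarray  # 50x50, upper-triangle canonical (i <= j)
    state: str  # raw_counts | domain_normalized | group_scaled | log

    def total(self) -> float:
        return float(self.values.sum())


@dataclass
class CommunityAssignment:
    protein_id: str
    labels: dict[int, str]  # residue -> community

    def communities(self) -> set[str]:
        return set(self.labels.values())

    def interface_residues(
        self, rin: ResidueInteractionNetwork, interaction_type: str | None = None
    ) -> frozenset[int]:
        """Residues with >= 1 contact into a different community."""
        out: set[int] = set()
        for e in rin.edges:
            if interaction_type is not None and e.interaction_type != interaction_type:
                continue
            ci, cj = self.labels.get(e.i), self.labels.get(e.j)
            if ci is None or cj is None or ci == cj:
                continue
            out.add(e.i)
            out.add(e.j)
        return frozenset(out)


@dataclass
class ClusteringStat:
    k: int
    observed_communities: int
    expected_mean: float
    expected_sd: float
    z: float
    p_perm: float
    n_permutations: int
    seed: int


@dataclass
class InterfaceEnrichment:
    scope: str  # community_interface | ppi_interface
    fraction_mutations_in_interface: float
    fraction_residues_in_interface: float
    ratio: float
    p: float


def select_representative_structure(
    candidates: Sequence[tuple[float, float, float, int]],
) -> int | None:
    """Pick the representative structure index, or None if none qualifies.

    Candidates are (coverage fraction, resolution in Angstrom, ligand size,
    number of chains). Structures must cover >= 75% of the protein, be solved
    at better than 3 A, and have fewer than 12 chains; among survivors the
    largest ligand wins, then the best (lowest) resolution, then the highest
    coverage.
    """
    best_idx: int | None = None
    best_key: tuple[float, float, float] | None = None
    for idx, (coverage, resolution, ligand, n_chains) in enumerate(candidates):
        if coverage < 0.75 or resolution >= 3.0 or n_chains >= 12:
            continue
        key = (-ligand, resolution, -coverage)
        if best_key is None or key < best_key:
            best_key = key
            best_idx = idx
    return best_idx


def residue_unit(position: int, domain: DomainMapping) -> int:
    """Normalised sequence unit (1..50) of a residue within a domain."""
    u = math.floor((position - domain.start) / domain.length * MATRIX_UNITS) + 1
    return min(MATRIX_UNITS, u)


def bin_domain_interactions(
    rin: ResidueInteractionNetwork, domain: DomainMapping
) -> InteractionMatrix:
    """Bin a domain's residue contacts into the canonical 50x50 matrix.

    The domain is divided into 50 equal-length units; every edge with both
    endpoints inside the domain adds its contact count to cell (u_i, u_j)
    with u_i <= u_j, so the matrix total equals the domain's contact total.
    """
    if not (1 <= domain.start <= domain.end <= rin.n_residues):
        raise ValueError(
            f"domain {domain.domain_id!r} outside residue range 1..{rin.n_residues}"
        )
    m = np.zeros((MATRIX_UNITS, MATRIX_UNITS))
    for e in rin.edges:
        if domain.start <= e.i <= domain.end and domain.start <= e.j <= domain.end:
            ui, uj = residue_unit(e.i, domain), residue_unit(e.j, domain)
            if ui > uj:
                ui, uj = uj, ui
            m[ui - 1, uj - 1] += e.count
    return InteractionMatrix(values=m, state="raw_counts")


def normalize_matrix(
    raw: InteractionMatrix,
    domain_total: float,
    group_scale: float = 1.0,
    log_epsilon: float | None = None,
) -> InteractionMatrix:
    """Domain-total normalisation, optional group rescaling, optional log10.

    Cells are divided by the domain's total contact count (correcting for
    domain size), multiplied by ``group_scale`` when one group's panel is
    rescaled to the other's abundance, and finally ``log10(x + epsilon)``
    transformed when ``log_epsilon`` is given.
    """
    if domain_total <= 0:
        raise ValueError("domain_total must be positive")
    if group_scale <= 0:
        raise ValueError("group_scale must be positive")
    if np.any(raw.values < 0):
        raise ValueError("negative cells in input matrix")
    vals = raw.values / domain_total
    state = "domain_normalized"
    if group_scale != 1.0:
        vals = vals * group_scale
        state = "group_scaled"
    if log_epsilon is not None:
        vals = np.log10(vals + log_epsilon)
        state = "log"
    return InteractionMatrix(values=vals, state=state)


def longrange_fraction(matrix: InteractionMatrix, offset_threshold: int) -> float:
    """Share of a domain's contact mass at sequence separation >= threshold units."""
    total = matrix.values.sum()
    if total == 0:
        return 0.0
    idx = np.abs(np.subtract.outer(np.arange(MATRIX_UNITS), np.arange(MATRIX_UNITS)))
    return float(matrix.values[idx >= offset_threshold].sum() / total)


def longrange_comparison(
    matrices_allosteric: Sequence[InteractionMatrix],
    matrices_other: Sequence[InteractionMatrix],
    offset_threshold: int = 20,
    log_epsilon: float = 1e-6,
) -> tuple[np.ndarray, dict[str, list[float]], float]:
    """Compare long-range contact fractions between two domain panels.

    Returns the difference of group-mean log10 matrices, the per-domain
    long-range fractions per group (computed on the count-scale matrices),
    and a two-sided Wilcoxon rank-sum p comparing those fractions (NaN when
    either group has a single domain).
    """
    if not matrices_allosteric or not matrices_other:
        raise ValueError("both matrix panels must be non-empty")
    if not (1 <= offset_threshold <= MATRIX_UNITS - 1):
        raise ValueError(f"offset threshold must be in 1..{MATRIX_UNITS - 1}")

    def mean_log(mats: Sequence[InteractionMatrix]) -> np.ndarray:
        stack = []
        for m in mats:
            vals = m.values
            if m.state != "log":
                total = vals.sum()
                vals = np.log10((vals / total if total > 0 else vals) + log_epsilon)
            stack.append(vals)
        return np.mean(stack, axis=0)

    diff = mean_log(matrices_allosteric) - mean_log(matrices_other)
    fracs = {
        "allosteric": [longrange_fraction(m, offset_threshold) for m in matrices_allosteric],
        "other": [longrange_fraction(m, offset_threshold) for m in matrices_other],
    }
    if len(fracs["allosteric"]) < 2 or len(fracs["other"]) < 2:
        p = float("nan")
    else:
        p = float(
            stats.mannwhitneyu(
                fracs["allosteric"], fracs["other"], alternative="two-sided"
            ).pvalue
        )
    return diff, fracs, p


def interface_mutation_enrichment(
    n_residues: int,
    interface: Iterable[int],
    mutations: Iterable[int],
    scope: str = "community_interface",
) -> InterfaceEnrichment:
    """Enrichment of mutations in an interface residue set.

    The enrichment ratio compares the fraction of mutations falling in the
    interface with the interface's share of the protein; the p-value is a
    two-sided exact binomial test of the in-interface mutation count with
    success probability |interface| / L.
    """
    iface = set(interface)
    muts = set(mutations)
    if not muts:
        raise ValueError("empty mutation set")
    if any(not (1 <= r <= n_residues) for r in iface | muts):
        raise ValueError("residues outside 1..L")
    p_iface = len(iface) / n_residues
    in_iface = len(muts & iface)
    frac_mut = in_iface / len(muts)
    ratio = frac_mut / p_iface if p_iface > 0 else float("nan")
    p = float(stats.binomtest(in_iface, len(muts), p_iface).pvalue)
    return InterfaceEnrichment(
        scope=scope,
        fraction_mutations_in_interface=frac_mut,
        fraction_residues_in_interface=p_iface,
        ratio=ratio,
        p=p,
    )


def expected_occupied_communities(sizes: Sequence[int], k: int) -> float:
    """Closed-form expected number of communities hit by k uniform draws.

    Drawing k residues without replacement from N labelled residues split
    into communities of the given sizes, E[occupied] =
    sum_i (1 - C(N - s_i, k) / C(N, k)).
    """
    n = sum(sizes)
    if not (1 <= k <= n):
        raise ValueError("k must be in 1..N")
    return float(
        sum(1.0 - math.comb(n - s, k) / math.comb(n, k) for s in sizes)
    )


def community_clustering_stat(
    communities: CommunityAssignment,
    mutated_residues: Iterable[int],
    n_perm: int = 2000,
    seed: int = 0,
) -> ClusteringStat:
    """Permutation test of mutation clustering across dynamic communities.

    The observed statistic is the number of distinct communities containing a
    mutated residue. The null redraws the same number of residues uniformly
    without replacement from all community-labelled residues; the p-value is
    lower-tailed (fewer occupied communities = more clustered) with the +1
    correction, p = (1 + #{perm <= obs}) / (n_perm + 1).
    """
    labels = communities.labels
    if len(set(labels.values())) < 2:
        raise ValueError("need at least 2 communities")
    muts = sorted(set(mutated_residues))
    k = len(muts)
    if k == 0:
        raise ValueError("empty mutation set")
    residues = sorted(labels)
    if k > len(residues):
        raise ValueError("more mutations than labelled residues")
    label_arr = np.array([labels[r] for r in residues])
    observed = len({labels[r] for r in muts if r in labels})
    rng = np.random.default_rng(seed)
    perm = np.empty(n_perm, dtype=np.int64)
    n = len(residues)
    for it in range(n_perm):
        draw = rng.choice(n, size=k, replace=False)
        perm[it] = len(np.unique(label_arr[draw]))
    exp_mean = float(perm.mean())
    exp_sd = float(perm.std(ddof=1)) if n_perm > 1 else 0.0
    z = (observed - exp_mean) / exp_sd if exp_sd > 0 else 0.0
    p = (1 + int(np.sum(perm <= observed))) / (n_perm + 1)
    return ClusteringStat(
        k=k,
        observed_communities=observed,
        expected_mean=exp_mean,
        expected_sd=exp_sd,
        z=float(z),
        p_perm=float(p),
        n_permutations=n_perm,
        seed=seed,
    )
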