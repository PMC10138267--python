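"""Synthetic-data generators with seeded randomness and planted effects.

Every input the pipeline consumes can be generated at desk scale: a rooted
disease ontology with names and MedGen/OMIM cross references, protein-disease
annotation tables with group-specific disease-count laws, a toy genome with
exon intervals and GWAS study tables carrying a planted proximity-enrichment
factor, residue-interaction networks with community labels and controllably
clustered mutations, orthogroup alignments with a planted divergence, PPI
edges with a controllable allosteric hub bias, premature-stop-codon variant
tables, and a phenotype comorbidity network. Each generator is a pure
function of (config, seed) and emits, alongside the data, the ground truth
needed to verify recovery of the planted effect.

Default parameters emulate the regime of the study the pipeline addresses:
allosteric proteins are a small minority of the proteome, carry about twice
as many disease associations as non-allosteric disease proteins, and their
genes attract roughly twice the genomic-average share of GWAS variants;
most synthetic GWA studies have moderate case counts (10^3-10^4) and few
genome-wide-significant variants.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .annotation import DiseaseRecord
from .evolution import (
    AlignmentRow,
    MultipleAlignment,
    Orthogroup,
    OrthogroupMember,
    PscVariant,
)
from .gwas import Gene, GenomeAnnotation, GwasStudy, genome_base_fractions
from .ontology import Ontology, OntologyTerm, parse_obo
from .structure import (
    CommunityAssignment,
    DomainMapping,
    ResidueInteractionNetwork,
    RinEdge,
)

__all__ = [
    "SimConfig",
    "gen_ontology",
    "gen_disease_annotations",
    "gen_genome_and_gwas",
    "gen_rin_communities_mutations",
    "gen_msa_orthogroups_ppi_comorbidity",
    "write_all",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_NAME_WORDS = [
    "congenital", "familial", "juvenile", "progressive", "hereditary",
    "myopathy", "neuropathy", "leukemia", "carcinoma", "dystrophy",
    "syndrome", "anemia", "ataxia", "deficiency", "dysplasia",
]


@dataclass
class SimConfig:
    """Planted parameters of the synthetic study.

    The defaults define the study conditions; tests and the acceptance
    script exercise recovery of these values.
    """

    seed: int = 0
    # proteome / annotations
    n_proteins: int = 400
    allosteric_fraction: float = 0.10
    disease_fraction: float = 0.30  # share of non-allosteric proteins with disease
    mu_diseases_allosteric: float = 3.0
    mu_diseases_other: float = 1.5
    nb_dispersion: float = 2.0
    # ontology
    ontology_size: int = 120
    ontology_branching: int = 2
    # genome / GWAS
    n_chromosomes: int = 2
    chromosome_length: int = 400_000
    n_genes: int = 60
    exons_per_gene: int = 3
    exon_length: int = 400
    n_studies: int = 8
    n_traits: int = 4
    mean_variants_per_study: float = 8.0
    enrichment_allosteric: float = 2.0
    enrichment_disease: float = 1.5
    proximity_cutoff: int = 100_000
    # structure
    rin_residues: int = 300
    rin_communities: int = 6
    rin_edges: int = 900
    rin_intra_fraction: float = 0.8
    n_mutations: int = 8
    mutation_kappa: float = 1.0  # 1 = uniform over residues; larger = clustered
    # evolution
    msa_length: int = 200
    msa_partners: int = 5
    msa_divergence: float = 0.10
    msa_gap_prob: float = 0.03
    # ppi
    ppi_mean_degree: int = 4
    ppi_hub_bias: float = 1.0  # 1 = no allosteric hub bias
    # comorbidity
    n_comorbidity_pairs: int = 300

    def protein_ids(self) -> list[str]:
        return [f"P{i:05d}" for i in range(self.n_proteins)]


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


# ---------------------------------------------------------------------------
# ontology


def gen_ontology(
    config: SimConfig,
) -> tuple[Ontology, str, dict[str, str], dict[str, str], dict[str, str]]:
    """A single-root random DAG ontology with names and xref tables.

    Returns (ontology, obo_text, names, medgen_xref, omim_xref) where the
    xref tables map MedGen-/OMIM-style ids to term ids. Parents are drawn
    only among earlier terms so the graph is acyclic by construction.
    """
    if config.ontology_size < 3:
        raise ValueError("ontology_size must be >= 3")
    rng = _rng(config, 1)
    n = config.ontology_size
    ids = [f"DOID:{i + 1:04d}" for i in range(n)]
    parents: dict[str, list[str]] = {ids[0]: []}
    for i in range(1, n):
        k = 1 if config.ontology_branching <= 1 else int(rng.integers(1, config.ontology_branching + 1))
        k = min(k, i)
        if config.ontology_branching <= 1:
            chosen = [ids[i - 1]]  # pure chain
        else:
            chosen = sorted(rng.choice(i, size=k, replace=False).tolist())
            chosen = [ids[j] for j in chosen]
        parents[ids[i]] = chosen
    names: dict[str, str] = {ids[0]: "disease"}
    used: set[frozenset[str]] = set()
    for i in range(1, n):
        while True:
            k = int(rng.integers(2, 4))
            words = rng.choice(len(_NAME_WORDS), size=k, replace=False)
            tokens = frozenset(_NAME_WORDS[w] for w in words) | {f"type {i}"}
            if tokens not in used:
                used.add(tokens)
                break
        base = [_NAME_WORDS[w] for w in words]
        # a comma-inverted variant exercises the bag-of-words matcher
        if rng.random() < 0.3 and len(base) >= 2:
            names[ids[i]] = f"{' '.join(base[1:])}, {base[0]} type {i}"
        else:
            names[ids[i]] = f"{' '.join(base)} type {i}"
    lines = ["format-version: 1.2", "ontology: synthetic-doid", ""]
    for tid in ids:
        lines.append("[Term]")
        lines.append(f"id: {tid}")
        lines.append(f"name: {names[tid]}")
        for p in parents[tid]:
            lines.append(f"is_a: {p} ! {names[p]}")
        lines.append("")
    obo_text = "\n".join(lines)
    ontology = parse_obo(obo_text)
    medgen = {f"MG:{i + 1:05d}": tid for i, tid in enumerate(ids)}
    omim = {f"OMIM:{600000 + i}": tid for i, tid in enumerate(ids)}
    return ontology, obo_text, names, medgen, omim


# ---------------------------------------------------------------------------
# protein-disease annotations


def gen_disease_annotations(
    config: SimConfig,
    ontology: Ontology,
    names: Mapping[str, str],
    medgen_xref: Mapping[str, str],
    omim_xref: Mapping[str, str],
) -> tuple[list[DiseaseRecord], dict[str, str], dict]:
    """Protein-disease records with a group-specific disease-count law.

    Disease counts follow a shifted negative binomial, 1 + NB, whose mean is
    exactly ``mu_diseases_allosteric`` for allosteric and
    ``mu_diseases_other`` for non-allosteric disease proteins (overdispersed,
    emulating heavy-tailed per-protein counts, while every disease protein
    has at least one disease and group means keep their planted ratio).
    Diseases are sampled from leaf terms; a share of records expose only the
    disease name (some comma-inverted), others only MedGen or OMIM ids.
    Returns (records, protein->group, truth).
    """
    rng = _rng(config, 2)
    pids = config.protein_ids()
    n_allo = int(round(config.allosteric_fraction * config.n_proteins))
    groups: dict[str, str] = {}
    for i, pid in enumerate(pids):
        if i < n_allo:
            groups[pid] = "allosteric"
        elif rng.random() < config.disease_fraction:
            groups[pid] = "disease"
        else:
            groups[pid] = "other"
    term_ids = sorted(t for t in ontology.terms if not ontology.terms[t].obsolete)
    children_of: set[str] = set()
    for t in term_ids:
        children_of.update(ontology.terms[t].parent_ids)
    leaves = [t for t in term_ids if t not in children_of]
    med_by_term = {v: k for k, v in medgen_xref.items()}
    omim_by_term = {v: k for k, v in omim_xref.items()}
    records: list[DiseaseRecord] = []
    truth_counts: dict[str, int] = {}
    r = config.nb_dispersion
    sources = ["clinvar", "omim", "uniprot", "hgmd"]
    for pid in pids:
        grp = groups[pid]
        if grp == "other":
            truth_counts[pid] = 0
            continue
        mu = (
            config.mu_diseases_allosteric
            if grp == "allosteric"
            else config.mu_diseases_other
        )
        excess = max(0.0, mu - 1.0)
        k = 1 + int(rng.negative_binomial(r, r / (r + excess))) if excess > 0 else 1
        k = min(k, len(leaves))
        truth_counts[pid] = k
        terms = [leaves[j] for j in rng.choice(len(leaves), size=k, replace=False)]
        for t in terms:
            src = sources[int(rng.integers(0, len(sources)))]
            u = rng.random()
            if src == "hgmd" or u < 0.3:  # name-only record
                records.append(
                    DiseaseRecord(
                        protein_id=pid,
                        source=src,
                        disease_names=frozenset([_scramble_name(names[t], rng)]),
                    )
                )
            elif u < 0.65:
                records.append(
                    DiseaseRecord(
                        protein_id=pid, source=src,
                        medgen_ids=frozenset([med_by_term[t]]),
                    )
                )
            else:
                records.append(
                    DiseaseRecord(
                        protein_id=pid, source=src,
                        omim_ids=frozenset([omim_by_term[t]]),
                    )
                )
    truth = {
        "mu_allosteric": config.mu_diseases_allosteric,
        "mu_other": config.mu_diseases_other,
        "n_allosteric": n_allo,
        "counts": truth_counts,
        "groups": groups,
    }
    return records, groups, truth


def _scramble_name(name: str, rng: np.random.Generator) -> str:
    """Reorder tokens and vary case/commas — same bag of words."""
    tokens = name.lower().replace(",", " ").split()
    order = rng.permutation(len(tokens))
    return " ".join(tokens[i] for i in order)


# ---------------------------------------------------------------------------
# genome + GWAS


def gen_genome_and_gwas(
    config: SimConfig, groups: Mapping[str, str]
) -> tuple[GenomeAnnotation, list[GwasStudy], dict]:
    """Toy genome with planted GWAS proximity enrichment.

    Genes with non-overlapping exon blocks are placed on the chromosomes and
    mapped to proteins of each group. After the genome is realised, its
    per-group base fractions f_g are measured and variants are placed on
    bases nearest to group g with probability E_g * f_g for the planted
    groups, the remainder going to ``other``/unassigned bases in proportion
    to their fractions — so the expected enrichment ratio of group g is
    exactly E_g whatever the random gene layout.
    """
    rng = _rng(config, 3)
    pids = config.protein_ids()
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    chromosomes = {c: config.chromosome_length for c in chrom_names}
    gene_span = config.exons_per_gene * config.exon_length * 3
    genes: dict[str, Gene] = {}
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    # one distinct protein per gene, drawn uniformly so the genome's group
    # composition mirrors the proteome's
    gene_proteins = [
        pids[i] for i in rng.choice(len(pids), size=config.n_genes, replace=False)
    ]
    gi = 0
    attempts = 0
    while gi < config.n_genes and attempts < 50 * config.n_genes:
        attempts += 1
        chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
        start = int(rng.integers(0, config.chromosome_length - gene_span))
        if any(s < start + gene_span and start < e for s, e in placed[chrom]):
            continue
        exons = []
        pos = start
        for _ in range(config.exons_per_gene):
            exons.append((pos, pos + config.exon_length))
            pos += config.exon_length + int(rng.integers(200, 2 * config.exon_length))
        placed[chrom].append((start, pos))
        pid = gene_proteins[gi]
        gid = f"G{gi:04d}"
        genes[gid] = Gene(
            gene_id=gid, chromosome=chrom, strand="+",
            exons=tuple(exons), protein_id=pid,
        )
        gi += 1
    if gi < config.n_genes:
        raise ValueError("could not place all genes; reduce n_genes or enlarge genome")
    genome = GenomeAnnotation(chromosomes=chromosomes, genes=genes)

    index = genome_base_fractions(genome, groups, cutoff=config.proximity_cutoff)
    f = {g: index.fraction(g) for g in ("allosteric", "disease", "other", "unassigned")}
    planted = {"allosteric": config.enrichment_allosteric,
               "disease": config.enrichment_disease}
    target = {g: planted[g] * f[g] for g in planted}
    if sum(target.values()) >= 1.0:
        raise ValueError(
            f"infeasible planted enrichment: required GWAS fraction "
            f"{sum(target.values()):.3f} >= 1"
        )
    rest = 1.0 - sum(target.values())
    f_rest = f["other"] + f["unassigned"]
    for g in ("other", "unassigned"):
        target[g] = rest * (f[g] / f_rest if f_rest > 0 else 0.5)

    # per-group base position pools
    pools: dict[str, list[tuple[str, np.ndarray]]] = {g: [] for g in target}
    gene_ids = sorted(genes)
    gene_group = {g: groups.get(genes[g].protein_id, "other") for g in gene_ids}
    for chrom in chrom_names:
        best = _nearest_gene_array(genome, chrom, gene_ids, config.proximity_cutoff)
        grp_codes = np.array([-1] + [
            ("allosteric", "disease", "other").index(gene_group[g]) for g in gene_ids
        ])
        codes = grp_codes[best + 1]
        for code, g in ((-1, "unassigned"), (0, "allosteric"), (1, "disease"), (2, "other")):
            pos = np.flatnonzero(codes == code)
            if pos.size:
                pools[g].append((chrom, pos))

    group_names = sorted(target)
    probs = np.array([target[g] for g in group_names])
    probs = probs / probs.sum()
    traits = [f"cancer_type_{i + 1}" for i in range(config.n_traits)]
    studies: list[GwasStudy] = []
    for si in range(config.n_studies):
        n_var = 1 + int(rng.poisson(config.mean_variants_per_study - 1))
        n_cases = int(10 ** rng.uniform(3, 5))
        trait = traits[si % len(traits)]
        variants: list[tuple[str, int, float]] = []
        for _ in range(n_var):
            g = group_names[int(rng.choice(len(group_names), p=probs))]
            pool = pools.get(g) or pools["unassigned"] or pools["other"]
            chrom, positions = pool[int(rng.integers(0, len(pool)))]
            pos = int(positions[int(rng.integers(0, positions.size))])
            p = 10 ** (-8.0 - rng.exponential(2.0) - 1e-9)
            variants.append((chrom, pos, p))
        studies.append(
            GwasStudy(study_id=f"GCST{si:04d}", trait=trait, n_cases=n_cases,
                      variants=variants)
        )
    truth = {
        "enrichment": planted,
        "genome_fractions": f,
        "target_gwas_fractions": target,
        "n_variants": sum(len(s.variants) for s in studies),
    }
    return genome, studies, truth


def _nearest_gene_array(
    genome: GenomeAnnotation, chrom: str, gene_ids: Sequence[str], cutoff: int
) -> np.ndarray:
    """Index of the nearest gene (or -1) for every base of a chromosome."""
    length = genome.chromosomes[chrom]
    best_dist = np.full(length, cutoff, dtype=np.int64)
    best_gene = np.full(length, -1, dtype=np.int64)
    for gi, gid in enumerate(gene_ids):
        gene = genome.genes[gid]
        if gene.chromosome != chrom:
            continue
        for s, e in gene.exons:
            lo = max(0, s - cutoff + 1)
            hi = min(length, e + cutoff - 1)
            pos = np.arange(lo, hi)
            d = np.maximum(np.maximum(s - pos, pos - (e - 1)), 0)
            win = best_dist[lo:hi]
            better = d < win
            win[better] = d[better]
            best_gene[lo:hi][better] = gi
    return best_gene


# ---------------------------------------------------------------------------
# residue-interaction networks, communities, mutations


def gen_rin_communities_mutations(
    config: SimConfig, protein_id: str = "P_RIN", seed_offset: int = 0
) -> tuple[
    ResidueInteractionNetwork, CommunityAssignment, DomainMapping, frozenset[int], dict
]:
    """A residue network with contiguous communities and planted mutation
    clustering.

    Communities are contiguous residue blocks; edges fall within a community
    with probability ``rin_intra_fraction``. Mutations are placed by a
    Dirichlet-multinomial over communities with concentration inversely
    proportional to the clustering parameter kappa: kappa = 1 draws residues
    uniformly without replacement (the exact null of the clustering test),
    larger kappa concentrates mutations in few communities.
    """
    if config.rin_residues < 2 * config.rin_communities:
        raise ValueError("need at least 2 residues per community")
    rng = np.random.default_rng([config.seed, 4, seed_offset])
    L, C = config.rin_residues, config.rin_communities
    cuts = np.sort(rng.choice(np.arange(1, L), size=C - 1, replace=False))
    bounds = np.concatenate([[0], cuts, [L]])
    # enforce at least 2 residues per block by regenerating degenerate layouts
    while np.any(np.diff(bounds) < 2):
        cuts = np.sort(rng.choice(np.arange(1, L), size=C - 1, replace=False))
        bounds = np.concatenate([[0], cuts, [L]])
    labels: dict[int, str] = {}
    blocks: list[np.ndarray] = []
    for ci in range(C):
        block = np.arange(bounds[ci] + 1, bounds[ci + 1] + 1)
        blocks.append(block)
        for r in block:
            labels[int(r)] = f"c{ci}"
    sizes = np.array([b.size for b in blocks], dtype=float)
    types = ["hbond", "vdw", "other"]
    type_p = [0.3, 0.5, 0.2]
    edges: dict[tuple[int, int, str], int] = {}
    for _ in range(config.rin_edges):
        t = types[int(rng.choice(3, p=type_p))]
        if rng.random() < config.rin_intra_fraction:
            ci = int(rng.choice(C, p=sizes / sizes.sum()))
            i, j = rng.choice(blocks[ci], size=2, replace=False)
        else:
            ca, cb = rng.choice(C, size=2, replace=False)
            i = int(rng.choice(blocks[ca]))
            j = int(rng.choice(blocks[cb]))
        i, j = int(min(i, j)), int(max(i, j))
        edges[(i, j, t)] = edges.get((i, j, t), 0) + 1
    rin = ResidueInteractionNetwork(
        protein_id=protein_id,
        n_residues=L,
        edges=[RinEdge(i, j, t, c) for (i, j, t), c in sorted(edges.items())],
        allosteric=bool(rng.random() < 0.5),
    )
    communities = CommunityAssignment(protein_id=protein_id, labels=labels)
    dom_len = max(50, min(L, int(0.6 * L)))
    domain = DomainMapping(domain_id=f"{protein_id}_dom1", start=1, end=dom_len)
    k = min(config.n_mutations, L)
    if config.mutation_kappa <= 1.0:
        muts = rng.choice(np.arange(1, L + 1), size=k, replace=False)
    else:
        alpha = (sizes / sizes.sum()) / config.mutation_kappa
        weights = rng.dirichlet(alpha)
        muts_list: list[int] = []
        counts = rng.multinomial(k, weights)
        for ci, c in enumerate(counts):
            c = min(int(c), blocks[ci].size)
            if c:
                muts_list.extend(
                    int(x) for x in rng.choice(blocks[ci], size=c, replace=False)
                )
        muts = np.array(muts_list)
    truth = {
        "kappa": config.mutation_kappa,
        "community_sizes": sizes.astype(int).tolist(),
        "k_mutations": int(muts.size),
    }
    return rin, communities, domain, frozenset(int(m) for m in muts), truth


# ---------------------------------------------------------------------------
# MSA, orthogroups, PPI, comorbidity, PSC variants


def gen_msa(
    config: SimConfig, focal_id: str = "HUMAN_P1", seed_offset: int = 0
) -> tuple[MultipleAlignment, dict]:
    """Orthogroup alignment with per-site divergence q from a human reference."""
    rng = np.random.default_rng([config.seed, 5, seed_offset])
    L = config.msa_length
    ref = rng.choice(list(AMINO_ACIDS), size=L)
    rows = [
        AlignmentRow(
            sequence_id=focal_id, species="homo_sapiens",
            sequence="".join(ref), is_primate=True, is_human=True,
        )
    ]
    species = [f"species_{i}" for i in range(config.msa_partners)]
    for si, sp in enumerate(species):
        seq = ref.copy()
        mutate = rng.random(L) < config.msa_divergence
        for pos in np.flatnonzero(mutate):
            choices = [a for a in AMINO_ACIDS if a != ref[pos]]
            seq[pos] = choices[int(rng.integers(0, len(choices)))]
        gaps = rng.random(L) < config.msa_gap_prob
        seq[gaps] = "-"
        rows.append(
            AlignmentRow(
                sequence_id=f"{sp}_P1", species=sp,
                sequence="".join(seq), is_primate=False, is_human=False,
            )
        )
    return MultipleAlignment(rows=rows), {"divergence": config.msa_divergence}


def gen_orthogroups(
    config: SimConfig,
    n_ortholog: int = 50,
    n_paralog: int = 30,
    n_reference: int = 40,
    n_lower_only: int = 5,
    level: str = "metazoans",
) -> tuple[list[Orthogroup], dict]:
    """Orthogroups with exactly known homolog-class membership.

    Builds ``n_ortholog`` groups whose human member is an ortholog of a
    non-human allosteric protein, ``n_paralog`` groups yielding one paralog
    and one duplicated allosteric protein each, ``n_reference`` plain
    reference groups and ``n_lower_only`` excluded lower-level-only groups.
    """
    groups: list[Orthogroup] = []
    truth = {"ortholog": [], "paralog": [], "duplicated": [], "reference": []}
    idx = 0
    for i in range(n_ortholog):
        hid = f"HORTH{i:04d}"
        groups.append(Orthogroup(
            group_id=f"OG{idx:05d}", taxonomic_level=level,
            members=[
                OrthogroupMember(hid, "homo_sapiens", True, False),
                OrthogroupMember(f"MORTH{i:04d}", "mus_musculus", False, True),
            ],
        ))
        truth["ortholog"].append(hid)
        idx += 1
    for i in range(n_paralog):
        pid, did = f"HPARA{i:04d}", f"HDUP{i:04d}"
        groups.append(Orthogroup(
            group_id=f"OG{idx:05d}", taxonomic_level=level,
            members=[
                OrthogroupMember(did, "homo_sapiens", True, True),
                OrthogroupMember(pid, "homo_sapiens", True, False),
                OrthogroupMember(f"MPARA{i:04d}", "mus_musculus", False, False),
            ],
        ))
        truth["paralog"].append(pid)
        truth["duplicated"].append(did)
        idx += 1
    for i in range(n_reference):
        rid = f"HREF{i:04d}"
        groups.append(Orthogroup(
            group_id=f"OG{idx:05d}", taxonomic_level=level,
            members=[
                OrthogroupMember(rid, "homo_sapiens", True, False),
                OrthogroupMember(f"MREF{i:04d}", "mus_musculus", False, False),
            ],
        ))
        truth["reference"].append(rid)
        idx += 1
    for i in range(n_lower_only):
        groups.append(Orthogroup(
            group_id=f"OG{idx:05d}", taxonomic_level=level,
            members=[
                OrthogroupMember(f"HLOW{i:04d}", "homo_sapiens", True, False),
                OrthogroupMember(f"MLOW{i:04d}", "mus_musculus", False, True),
            ],
            lower_level_only=True,
        ))
        idx += 1
    return groups, truth


def gen_ppi(
    config: SimConfig, groups: Mapping[str, str]
) -> tuple[list[tuple[str, str]], dict]:
    """Scale-free-ish PPI edges with an optional allosteric hub bias.

    Node degrees follow preferential attachment; with hub bias b the
    allosteric label is then re-assigned to nodes with probability
    proportional to degree^(b-1), so b = 1 leaves labels as supplied
    (no association between allostery and degree).
    """
    import networkx as nx

    rng = _rng(config, 6)
    pids = sorted(groups)
    m = max(1, config.ppi_mean_degree // 2)
    g = nx.barabasi_albert_graph(len(pids), m, seed=int(rng.integers(0, 2**31)))
    edges = [(pids[a], pids[b]) for a, b in sorted(g.edges())]
    truth: dict = {"hub_bias": config.ppi_hub_bias}
    if config.ppi_hub_bias != 1.0:
        n_allo = sum(1 for v in groups.values() if v == "allosteric")
        deg = np.array([g.degree(i) for i in range(len(pids))], dtype=float)
        w = deg ** (config.ppi_hub_bias - 1.0)
        chosen = rng.choice(len(pids), size=n_allo, replace=False, p=w / w.sum())
        truth["reassigned_allosteric"] = sorted(pids[i] for i in chosen)
    return edges, truth


def gen_comorbidity(
    config: SimConfig, phenotype_ids: Sequence[str]
) -> tuple[list[tuple[str, str]], dict]:
    """Random phenotype-pair comorbidity network over the xref universe."""
    rng = _rng(config, 7)
    ids = sorted(phenotype_ids)
    pairs: set[tuple[str, str]] = set()
    n_possible = len(ids) * (len(ids) - 1) // 2
    n_target = min(config.n_comorbidity_pairs, n_possible)
    while len(pairs) < n_target:
        a, b = rng.choice(len(ids), size=2, replace=False)
        pair = (ids[min(a, b)], ids[max(a, b)])
        pairs.add(pair)
    return sorted(pairs), {"n_pairs": n_target}


def gen_psc_variants(
    config: SimConfig, protein_lengths: Mapping[str, int],
    intolerant_fraction: float = 0.3,
) -> tuple[list[PscVariant], dict]:
    """Stop-gained variant rows with a planted intolerant protein subset."""
    rng = _rng(config, 8)
    variants: list[PscVariant] = []
    truth_intolerant: list[str] = []
    for pid in sorted(protein_lengths):
        if rng.random() < intolerant_fraction:
            truth_intolerant.append(pid)
            # only rejected rows for intolerant proteins
            if rng.random() < 0.5:
                variants.append(PscVariant(
                    pid, int(rng.integers(1, protein_lengths[pid] + 1)),
                    "Trp->*", float(rng.uniform(1e-6, 1e-4)),
                    "stop_gained", passes_filters=False,
                ))
            continue
        n = 1 + int(rng.poisson(1.5))
        for _ in range(n):
            variants.append(PscVariant(
                pid, int(rng.integers(1, protein_lengths[pid] + 1)),
                "Arg->*", float(rng.uniform(1e-6, 1e-3)),
                "stop_gained", passes_filters=True,
            ))
    return variants, {"intolerant": truth_intolerant}


def gen_msa_orthogroups_ppi_comorbidity(
    config: SimConfig,
    groups: Mapping[str, str],
    phenotype_ids: Sequence[str],
) -> dict:
    """Bundle of the remaining fixtures: MSA, orthogroups, PPI edges,
    comorbidity pairs and PSC variant rows, each with its ground truth."""
    msa, msa_truth = gen_msa(config)
    orthogroups, og_truth = gen_orthogroups(config)
    ppi_edges, ppi_truth = gen_ppi(config, groups)
    pairs, com_truth = gen_comorbidity(config, phenotype_ids)
    lengths = {pid: 200 + 10 * (i % 50) for i, pid in enumerate(sorted(groups))}
    psc, psc_truth = gen_psc_variants(config, lengths)
    return {
        "msa": msa, "msa_truth": msa_truth,
        "orthogroups": orthogroups, "orthogroup_truth": og_truth,
        "ppi_edges": ppi_edges, "ppi_truth": ppi_truth,
        "comorbidity_pairs": pairs, "comorbidity_truth": com_truth,
        "psc_variants": psc, "psc_truth": psc_truth,
        "protein_lengths": lengths,
    }


# ---------------------------------------------------------------------------
# file emission


def write_all(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate every fixture and write it in its on-disk exchange format.

    Emits the OBO ontology, annotation TSVs, genome (chromosome TSV + BED),
    GWAS study TSV, RIN/community/domain/mutation TSVs, aligned FASTA,
    orthogroup TSV, PPI and comorbidity TSVs, PSC TSV and a sim_truth.json
    manifest. Deterministic: same config and seed give identical bytes.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    truth_all: dict = {"seed": config.seed, "config": dataclasses.asdict(config)}

    ontology, obo_text, names, medgen, omim = gen_ontology(config)
    paths["ontology"] = out / "ontology.obo"
    paths["ontology"].write_text(obo_text)
    paths["medgen_xref"] = _write_tsv(
        out / "medgen_xref.tsv", ["medgen_id", "doid"], sorted(medgen.items())
    )
    paths["omim_xref"] = _write_tsv(
        out / "omim_xref.tsv", ["omim_id", "doid"], sorted(omim.items())
    )

    records, groups, ann_truth = gen_disease_annotations(
        config, ontology, names, medgen, omim
    )
    truth_all["annotations"] = {
        k: v for k, v in ann_truth.items() if k != "counts"
    }
    rows = [
        (
            r.protein_id, r.source,
            ";".join(sorted(r.medgen_ids)), ";".join(sorted(r.omim_ids)),
            ";".join(sorted(r.disease_names)),
        )
        for r in records
    ]
    paths["disease_records"] = _write_tsv(
        out / "disease_records.tsv",
        ["protein_id", "source", "medgen_ids", "omim_ids", "disease_names"],
        rows,
    )
    paths["groups"] = _write_tsv(
        out / "protein_groups.tsv", ["protein_id", "group"], sorted(groups.items())
    )

    genome, studies, gwas_truth = gen_genome_and_gwas(config, groups)
    truth_all["gwas"] = gwas_truth
    paths["chromosomes"] = _write_tsv(
        out / "chromosomes.tsv", ["chromosome", "length"],
        sorted(genome.chromosomes.items()),
    )
    bed_rows = []
    for gid in sorted(genome.genes):
        g = genome.genes[gid]
        for s, e in g.exons:
            bed_rows.append((g.chromosome, s, e, f"{gid}|{g.protein_id}"))
    paths["exons"] = _write_tsv(out / "exons.bed", None, bed_rows)
    paths["gwas"] = _write_tsv(
        out / "gwas_studies.tsv",
        ["study_id", "trait", "n_cases", "chrom", "pos", "p"],
        [
            (s.study_id, s.trait, s.n_cases, c, p, f"{pv:.3e}")
            for s in studies
            for (c, p, pv) in s.variants
        ],
    )

    rin, comm, domain, muts, rin_truth = gen_rin_communities_mutations(config)
    truth_all["rin"] = rin_truth
    paths["rin_edges"] = _write_tsv(
        out / "rin_edges.tsv",
        ["protein_id", "res_i", "res_j", "type", "count"],
        [(rin.protein_id, e.i, e.j, e.interaction_type, e.count) for e in rin.edges],
    )
    paths["communities"] = _write_tsv(
        out / "communities.tsv", ["protein_id", "residue", "community"],
        [(comm.protein_id, r, comm.labels[r]) for r in sorted(comm.labels)],
    )
    paths["domains"] = _write_tsv(
        out / "domains.tsv", ["protein_id", "domain_id", "start", "end"],
        [(rin.protein_id, domain.domain_id, domain.start, domain.end)],
    )
    paths["mutations"] = _write_tsv(
        out / "mutations.tsv", ["protein_id", "residue"],
        [(rin.protein_id, r) for r in sorted(muts)],
    )

    bundle = gen_msa_orthogroups_ppi_comorbidity(config, groups, sorted(medgen))
    truth_all["msa"] = bundle["msa_truth"]
    truth_all["orthogroups"] = {
        k: len(v) for k, v in bundle["orthogroup_truth"].items()
    }
    truth_all["ppi"] = bundle["ppi_truth"]
    truth_all["psc_intolerant_n"] = len(bundle["psc_truth"]["intolerant"])
    paths["msa"] = out / "orthogroup_alignment.fasta"
    with open(paths["msa"], "w") as fh:
        for row in bundle["msa"].rows:
            fh.write(f">{row.species}|{row.sequence_id}\n{row.sequence}\n")
    paths["orthogroups"] = _write_tsv(
        out / "orthogroups.tsv",
        ["group_id", "level", "protein_id", "species", "is_human", "allosteric",
         "lower_level_only"],
        [
            (og.group_id, og.taxonomic_level, m.protein_id, m.species,
             int(m.is_human), int(m.allosteric), int(og.lower_level_only))
            for og in bundle["orthogroups"] for m in og.members
        ],
    )
    paths["ppi"] = _write_tsv(
        out / "ppi_edges.tsv", ["protein_a", "protein_b"], bundle["ppi_edges"]
    )
    paths["comorbidity"] = _write_tsv(
        out / "comorbidity_pairs.tsv", ["phenotype_a", "phenotype_b"],
        bundle["comorbidity_pairs"],
    )
    paths["psc"] = _write_tsv(
        out / "psc_variants.tsv",
        ["protein_id", "codon", "amino_change", "allele_frequency",
         "consequence", "passes_filters"],
        [
            (v.protein_id, v.codon, v.amino_change, f"{v.allele_frequency:.3e}",
             v.consequence, int(v.passes_filters))
            for v in bundle["psc_variants"]
        ],
    )
    paths["protein_lengths"] = _write_tsv(
        out / "protein_lengths.tsv", ["protein_id", "length"],
        sorted(bundle["protein_lengths"].items()),
    )

    paths["truth"] = out / "sim_truth.json"
    paths["truth"].write_text(json.dumps(truth_all, indent=2, sort_keys=True))
    return paths


def _write_tsv(path: Path, header: Sequence[str] | None, rows) -> Path:
    with open(path, "w") as fh:
        if header:
            fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    return path
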