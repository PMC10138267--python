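"""Genome base-proximity enrichment of GWAS variants near protein groups.

Every base of the genome (and every GWAS variant) is assigned to the nearest
protein-coding gene with an exon closer than a cutoff (100 kb by default);
bases or variants further than the cutoff from any exon stay unassigned but
remain in all denominators. Enrichment of a protein group g is

    ratio_g = (% of GWAS variants nearest to group g) / (% of genome bases
              nearest to group g)

computed in three modes: per-trait largest study only, per-trait pooled
nonredundant gene lists, or all nonredundant studies pooled. Significance is
assessed by Mantel-Haenszel pooling of per-study 2x2 tables against a
genome-derived reference row, with a Cochran's Q heterogeneity statistic.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.contingency_tables import StratifiedTable

__all__ = [
    "Gene",
    "GenomeAnnotation",
    "ProximityIndex",
    "GwasStudy",
    "EnrichmentResult",
    "PooledTest",
    "assign_nearest_gene",
    "genome_base_fractions",
    "filter_redundant_studies",
    "top_variant_subset",
    "compute_enrichment",
    "mh_pooled_test",
    "read_genome",
    "read_gwas_studies",
]

DEFAULT_CUTOFF_BP = 100_000
GENOME_WIDE_SIGNIFICANCE = 1e-8


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chromosome: str
    strand: str
    exons: tuple[tuple[int, int], ...]  # 0-based half-open
    protein_id: str


@dataclass
class GenomeAnnotation:
    chromosomes: dict[str, int]
    genes: dict[str, Gene]

    def __post_init__(self) -> None:
        for g in self.genes.values():
            length = self.chromosomes.get(g.chromosome)
            if length is None:
                raise ValueError(f"gene {g.gene_id!r} on unknown chromosome {g.chromosome!r}")
            for s, e in g.exons:
                if not (0 <= s < e <= length):
                    raise ValueError(
                        f"exon ({s}, {e}) of {g.gene_id!r} outside chromosome bounds"
                    )


@dataclass
class ProximityIndex:
    """Aggregate base-proximity assignment of a genome.

    ``group_bases`` maps every protein group (plus ``unassigned``) to the
    number of genome bases nearest to it within the cutoff; fractions use the
    full genome length as denominator, so unassigned bases dilute every group.
    """

    group_bases: dict[str, int]
    total_bases: int
    cutoff: int

    def fraction(self, group: str) -> float:
        return self.group_bases.get(group, 0) / self.total_bases


@dataclass
class GwasStudy:
    study_id: str
    trait: str
    n_cases: int
    variants: list[tuple[str, int, float]]  # (chromosome, position, p)


@dataclass
class PooledTest:
    odds_ratio: float
    p_value: float
    cochran_q: float
    q_p_value: float
    n_strata: int
    n_dropped: int


@dataclass
class EnrichmentResult:
    mode: str
    groups: dict[str, tuple[float, float, float]]  # group -> (gwas_frac, genome_frac, ratio)
    n_observations: int
    pooled: dict[str, PooledTest] = field(default_factory=dict)


def _exon_distance(pos: int, start: int, end: int) -> int:
    """bp gap from a position to a half-open exon interval; 0 inside."""
    if pos < start:
        return start - pos
    if pos >= end:
        return pos - (end - 1)
    return 0


def assign_nearest_gene(
    genome: GenomeAnnotation,
    chromosome: str,
    position: int,
    cutoff: int = DEFAULT_CUTOFF_BP,
) -> tuple[str, int] | None:
    """Nearest gene by minimum exon distance, or None beyond the cutoff.

    Distance is zero inside an exon and the bp gap to the closest exon
    boundary otherwise; equidistant genes resolve to the smaller gene id.
    """
    if chromosome not in genome.chromosomes:
        raise KeyError(f"unknown chromosome {chromosome!r}")
    best: tuple[int, str] | None = None
    for gid in sorted(genome.genes):
        gene = genome.genes[gid]
        if gene.chromosome != chromosome:
            continue
        d = min(_exon_distance(position, s, e) for s, e in gene.exons)
        if best is None or d < best[0]:
            best = (d, gid)
    if best is None or best[0] >= cutoff:
        return None
    return best[1], best[0]


def genome_base_fractions(
    genome: GenomeAnnotation,
    protein_groups: Mapping[str, str],
    cutoff: int = DEFAULT_CUTOFF_BP,
) -> ProximityIndex:
    """Assign every genome base to its nearest gene and aggregate by group.

    Genes whose protein lacks a group label count under ``other``. The
    vectorised sweep only touches the window within the cutoff around each
    exon; genes are processed in ascending id with strict-improvement updates
    so distance ties resolve exactly as :func:`assign_nearest_gene`.
    """
    if not genome.chromosomes:
        raise ValueError("empty genome")
    gene_ids = sorted(genome.genes)
    gene_group = {
        gid: protein_groups.get(genome.genes[gid].protein_id, "other")
        for gid in gene_ids
    }
    group_bases: dict[str, int] = {"unassigned": 0}
    total = 0
    for chrom in sorted(genome.chromosomes):
        length = genome.chromosomes[chrom]
        total += length
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
                win_best = best_dist[lo:hi]
                better = d < win_best
                win_best[better] = d[better]
                best_gene[lo:hi][better] = gi
        counts = np.bincount(best_gene + 1, minlength=len(gene_ids) + 1)
        group_bases["unassigned"] += int(counts[0])
        for gi, gid in enumerate(gene_ids):
            grp = gene_group[gid]
            group_bases[grp] = group_bases.get(grp, 0) + int(counts[gi + 1])
    return ProximityIndex(group_bases=group_bases, total_bases=total, cutoff=cutoff)


def assign_study_genes(
    study: GwasStudy, genome: GenomeAnnotation, cutoff: int = DEFAULT_CUTOFF_BP
) -> list[str | None]:
    """Nearest-gene id for each variant (None when unassigned)."""
    out: list[str | None] = []
    for chrom, pos, _ in study.variants:
        hit = assign_nearest_gene(genome, chrom, pos, cutoff)
        out.append(None if hit is None else hit[0])
    return out


def filter_redundant_studies(
    studies: Sequence[GwasStudy],
    gene_sets: Mapping[str, frozenset[str]],
) -> list[GwasStudy]:
    """Drop redundant studies within each trait.

    Studies with no assigned variant are removed. Within a trait, a study is
    redundant if its variant set is identical to another retained study's or
    its candidate gene set is a subset of another's; of such a pair the study
    with more genes is kept, ties by more cancer cases, then smaller study id.
    """
    eligible = [s for s in studies if gene_sets.get(s.study_id)]
    retained: list[GwasStudy] = []
    by_trait: dict[str, list[GwasStudy]] = {}
    for s in eligible:
        by_trait.setdefault(s.trait, []).append(s)
    for trait in sorted(by_trait):
        group = sorted(
            by_trait[trait],
            key=lambda s: (-len(gene_sets[s.study_id]), -s.n_cases, s.study_id),
        )
        kept: list[GwasStudy] = []
        for cand in group:
            cset = gene_sets[cand.study_id]
            cvars = frozenset(cand.variants)
            redundant = any(
                cset <= gene_sets[k.study_id] or cvars == frozenset(k.variants)
                for k in kept
            )
            if not redundant:
                kept.append(cand)
        retained.extend(kept)
    retained.sort(key=lambda s: s.study_id)
    return retained


def top_variant_subset(
    study: GwasStudy, fraction: float = 0.2
) -> list[tuple[str, int, float]]:
    """The ceil(fraction * n) variants with the smallest p-values.

    Boundary ties in p resolve by (chromosome, position) ascending.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if not study.variants:
        raise ValueError(f"study {study.study_id!r} has no variants")
    keep = math.ceil(fraction * len(study.variants))
    ranked = sorted(study.variants, key=lambda v: (v[2], v[0], v[1]))
    return ranked[:keep]


def compute_enrichment(
    studies: Sequence[GwasStudy],
    index: ProximityIndex,
    genome: GenomeAnnotation,
    protein_groups: Mapping[str, str],
    mode: str = "all_nonredundant",
    cutoff: int | None = None,
    top_fraction: float | None = None,
    groups: Sequence[str] = ("allosteric", "disease", "other"),
    ref_total: int = 1_000_000,
) -> EnrichmentResult:
    """Group-wise GWAS enrichment ratios (% in GWAS / % in the genome).

    Modes: ``largest_study`` uses, per trait, only the study with the most
    cases; ``all_nonredundant`` pools every retained study's variants;
    ``pooled_genes`` builds one deduplicated candidate-gene list per trait
    and compares group frequencies against all protein-coding genes of the
    genome. ``top_fraction`` restricts each study to its most significant
    variants before pooling. Unassigned variants remain in the denominator.
    Per-group Mantel-Haenszel pooled tests over the per-study 2x2 tables are
    attached for the variant-based modes.
    """
    if not studies:
        raise ValueError("no retained studies")
    cutoff = index.cutoff if cutoff is None else cutoff
    gene_group = {
        gid: protein_groups.get(genome.genes[gid].protein_id, "other")
        for gid in genome.genes
    }
    if mode == "pooled_genes":
        pooled_entries: list[str] = []
        by_trait: dict[str, list[GwasStudy]] = {}
        for s in studies:
            by_trait.setdefault(s.trait, []).append(s)
        for trait in sorted(by_trait):
            trait_genes: set[str] = set()
            for s in by_trait[trait]:
                for g in assign_study_genes(s, genome, cutoff):
                    if g is not None:
                        trait_genes.add(g)
            pooled_entries.extend(sorted(trait_genes))
        n_obs = len(pooled_entries)
        if n_obs == 0:
            raise ValueError("no candidate genes in any trait")
        all_genes = sorted(genome.genes)
        result: dict[str, tuple[float, float, float]] = {}
        for grp in groups:
            gwas_frac = sum(1 for g in pooled_entries if gene_group[g] == grp) / n_obs
            genome_frac = sum(1 for g in all_genes if gene_group[g] == grp) / len(all_genes)
            if genome_frac == 0:
                raise ZeroDivisionError(f"zero genome gene fraction for group {grp!r}")
            result[grp] = (gwas_frac, genome_frac, gwas_frac / genome_frac)
        return EnrichmentResult(mode=mode, groups=result, n_observations=n_obs)
    if mode == "largest_study":
        by_trait = {}
        for s in studies:
            by_trait.setdefault(s.trait, []).append(s)
        use = [
            sorted(by_trait[t], key=lambda s: (-s.n_cases, s.study_id))[0]
            for t in sorted(by_trait)
        ]
    elif mode == "all_nonredundant":
        use = list(studies)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    per_study_groups: dict[str, list[str]] = {}
    for s in use:
        variants = (
            top_variant_subset(s, top_fraction) if top_fraction is not None else s.variants
        )
        sub = GwasStudy(s.study_id, s.trait, s.n_cases, list(variants))
        assigned = assign_study_genes(sub, genome, cutoff)
        per_study_groups[s.study_id] = [
            "unassigned" if g is None else gene_group[g] for g in assigned
        ]
    pooled_groups = [g for s in use for g in per_study_groups[s.study_id]]
    n_obs = len(pooled_groups)
    result = {}
    pooled_tests: dict[str, PooledTest] = {}
    for grp in groups:
        gwas_frac = sum(1 for g in pooled_groups if g == grp) / n_obs
        genome_frac = index.fraction(grp)
        if genome_frac == 0:
            raise ZeroDivisionError(f"zero genome base fraction for group {grp!r}")
        result[grp] = (gwas_frac, genome_frac, gwas_frac / genome_frac)
        tables = []
        ref_in = int(round(genome_frac * ref_total))
        for s in use:
            ks = per_study_groups[s.study_id]
            a = sum(1 for g in ks if g == grp)
            b = len(ks) - a
            tables.append(np.array([[a, b], [ref_in, ref_total - ref_in]]))
        try:
            pooled_tests[grp] = mh_pooled_test(tables)
        except ValueError:
            pass  # all strata degenerate for this group
    return EnrichmentResult(
        mode=mode, groups=result, n_observations=n_obs, pooled=pooled_tests
    )


def mh_pooled_test(tables: Sequence[np.ndarray]) -> PooledTest:
    """Mantel-Haenszel pooled odds ratio with Cochran's Q heterogeneity.

    Strata with a zero row or column margin are dropped (counted). The pooled
    OR and its chi-square test of OR=1 come from the stratified-table MH
    estimator; Q uses inverse-variance weights on Haldane-corrected per-stratum
    log odds ratios around the pooled MH estimate, with k-1 degrees of freedom.
    """
    kept = []
    n_dropped = 0
    for t in tables:
        t = np.asarray(t, dtype=float)
        if t.shape != (2, 2):
            raise ValueError(f"stratum has shape {t.shape}, expected 2x2")
        if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
            n_dropped += 1
            continue
        kept.append(t)
    if not kept:
        raise ValueError("all strata dropped (zero margins)")
    st = StratifiedTable(np.stack(kept, axis=-1))
    with np.errstate(divide="ignore", invalid="ignore"):
        or_pooled = float(st.oddsratio_pooled)
        test = st.test_null_odds(correction=False)
    p_value = float(test.pvalue)
    log_pooled = math.log(or_pooled) if or_pooled > 0 else 0.0
    q = 0.0
    for t in kept:
        a, b = t[0]
        c, d = t[1]
        if 0 in (a, b, c, d):
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        log_or = math.log((a * d) / (b * c))
        var = 1 / a + 1 / b + 1 / c + 1 / d
        q += (log_or - log_pooled) ** 2 / var
    df = len(kept) - 1
    q_p = float(stats.chi2.sf(q, df)) if df > 0 else 1.0
    return PooledTest(
        odds_ratio=or_pooled,
        p_value=p_value,
        cochran_q=q,
        q_p_value=q_p,
        n_strata=len(kept),
        n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# file readers

_GTF_GENE_RE = re.compile(r'gene_id "([^"]+)"')
_GTF_PROT_RE = re.compile(r'protein_id "([^"]+)"')


def read_genome(
    chromosomes_tsv: str,
    intervals_path: str,
    gene_to_protein: Mapping[str, str] | None = None,
) -> GenomeAnnotation:
    """Genome from a chromosome-length TSV plus exon intervals in BED or GTF.

    BED intervals are 0-based half-open with the gene id in the name column
    (optionally ``gene|protein``); GTF exon rows are 1-based inclusive and
    converted on read.
    """
    chroms: dict[str, int] = {}
    with open(chromosomes_tsv) as fh:
        header = fh.readline()
        for line in fh:
            name, length = line.rstrip("\n").split("\t")[:2]
            chroms[name] = int(length)
    exons: dict[str, list[tuple[str, int, int]]] = {}
    gene_protein: dict[str, str] = dict(gene_to_protein or {})
    is_gtf = str(intervals_path).endswith((".gtf", ".gff"))
    with open(intervals_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            try:
                if is_gtf:
                    if fields[2] != "exon":
                        continue
                    chrom, start, end = fields[0], int(fields[3]) - 1, int(fields[4])
                    gid = _GTF_GENE_RE.search(fields[8]).group(1)
                    m = _GTF_PROT_RE.search(fields[8])
                    if m:
                        gene_protein.setdefault(gid, m.group(1))
                else:
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                    name = fields[3]
                    gid, _, prot = name.partition("|")
                    if prot:
                        gene_protein.setdefault(gid, prot)
            except (IndexError, ValueError, AttributeError) as exc:
                raise ValueError(f"malformed interval at line {lineno}") from exc
            exons.setdefault(gid, []).append((chrom, start, end))
    genes = {}
    for gid, ivals in exons.items():
        chrom = ivals[0][0]
        genes[gid] = Gene(
            gene_id=gid,
            chromosome=chrom,
            strand="+",
            exons=tuple(sorted((s, e) for _, s, e in ivals)),
            protein_id=gene_protein.get(gid, gid),
        )
    return GenomeAnnotation(chromosomes=chroms, genes=genes)


def read_gwas_studies(
    path: str, p_threshold: float = GENOME_WIDE_SIGNIFICANCE
) -> list[GwasStudy]:
    """Studies from a TSV (study_id, trait, n_cases, chrom, pos, p).

    Only variants below the genome-wide significance threshold are retained.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    studies: dict[str, GwasStudy] = {}
    for row in df.itertuples(index=False):
        s = studies.get(row.study_id)
        if s is None:
            s = GwasStudy(str(row.study_id), str(row.trait), int(row.n_cases), [])
            studies[row.study_id] = s
        if float(row.p) < p_threshold:
            s.variants.append((str(row.chrom), int(row.pos), float(row.p)))
    return [studies[k] for k in sorted(studies)]
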