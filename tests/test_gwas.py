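"""Nearest-gene assignment, base fractions, enrichment and MH pooling."""

import math

import numpy as np
import pytest

from allodis.gwas import (
    Gene,
    GenomeAnnotation,
    GwasStudy,
    ProximityIndex,
    assign_nearest_gene,
    assign_study_genes,
    compute_enrichment,
    filter_redundant_studies,
    genome_base_fractions,
    mh_pooled_test,
    read_genome,
    top_variant_subset,
)


def brute_force_fractions(genome, protein_groups, cutoff):
    """Per-base scan: nearest exon over all genes, ties to the smaller gene id."""
    counts = {"unassigned": 0}
    for chrom in sorted(genome.chromosomes):
        for pos in range(genome.chromosomes[chrom]):
            best = None
            for gid in sorted(genome.genes):
                g = genome.genes[gid]
                if g.chromosome != chrom:
                    continue
                d = min(
                    (s - pos if pos < s else pos - (e - 1) if pos >= e else 0)
                    for s, e in g.exons
                )
                if best is None or d < best[0]:
                    best = (d, gid)
            if best is None or best[0] >= cutoff:
                counts["unassigned"] += 1
            else:
                grp = protein_groups.get(genome.genes[best[1]].protein_id, "other")
                counts[grp] = counts.get(grp, 0) + 1
    return counts


@pytest.fixture
def worked_genome():
    """A 100 kb chromosome where the allosteric gene owns exactly 3.8% of bases.

    Gene A's exon spans [0, 100); gene B's [7500, 7600). Bases up to 3799 are
    nearer A (the midpoint tie falls between integers), so A's basin is 3800
    bases = 3.8% of the chromosome.
    """
    genome = GenomeAnnotation(
        chromosomes={"chr1": 100_000},
        genes={
            "A": Gene("A", "chr1", "+", ((0, 100),), "PA"),
            "B": Gene("B", "chr1", "+", ((7500, 7600),), "PB"),
        },
    )
    groups = {"PA": "allosteric", "PB": "other"}
    return genome, groups


class TestAssignNearestGene:
    def test_inside_exon_distance_zero(self, worked_genome):
        genome, _ = worked_genome
        assert assign_nearest_gene(genome, "chr1", 50) == ("A", 0)

    def test_minimum_distance_wins(self, worked_genome):
        genome, _ = worked_genome
        # position 5000: 4901 bp from A's exon end, 2500 bp from B's start
        assert assign_nearest_gene(genome, "chr1", 5000) == ("B", 2500)

    def test_beyond_cutoff_unassigned(self):
        genome = GenomeAnnotation(
            chromosomes={"chr1": 400_000},
            genes={"A": Gene("A", "chr1", "+", ((0, 100),), "PA")},
        )
        assert assign_nearest_gene(genome, "chr1", 250_099) is None
        assert assign_nearest_gene(genome, "chr1", 100_098) == ("A", 99_999)

    def test_unknown_chromosome(self, worked_genome):
        genome, _ = worked_genome
        with pytest.raises(KeyError):
            assign_nearest_gene(genome, "chrX", 1)


class TestGenomeBaseFractions:
    def test_single_gene_full_coverage(self):
        genome = GenomeAnnotation(
            chromosomes={"chr1": 1000},
            genes={"A": Gene("A", "chr1", "+", ((400, 500),), "PA")},
        )
        idx = genome_base_fractions(genome, {"PA": "allosteric"})
        assert idx.fraction("allosteric") == 1.0

    def test_no_gene_in_reach(self):
        genome = GenomeAnnotation(
            chromosomes={"chr1": 5000},
            genes={"A": Gene("A", "chr1", "+", ((0, 10),), "PA")},
        )
        idx = genome_base_fractions(genome, {"PA": "allosteric"}, cutoff=100)
        assert idx.group_bases["allosteric"] == 109  # exon + 99 flanking bases
        assert idx.group_bases["unassigned"] == 5000 - 109

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_per_base_scan(self, seed):
        rng = np.random.default_rng(seed)
        chroms = {"c1": 20_000, "c2": 12_000}
        genes = {}
        for i in range(6):
            chrom = "c1" if i < 4 else "c2"
            s = int(rng.integers(0, chroms[chrom] - 500))
            genes[f"g{i}"] = Gene(
                f"g{i}", chrom, "+", ((s, s + 100), (s + 300, s + 400)), f"p{i}"
            )
        groups = {f"p{i}": ("allosteric" if i % 3 == 0 else "disease") for i in range(6)}
        genome = GenomeAnnotation(chromosomes=chroms, genes=genes)
        cutoff = 2_000
        idx = genome_base_fractions(genome, groups, cutoff=cutoff)
        assert idx.group_bases == brute_force_fractions(genome, groups, cutoff)

    def test_fraction_invariant_under_uniform_scaling(self, worked_genome):
        genome, groups = worked_genome
        idx1 = genome_base_fractions(genome, groups)
        doubled = GenomeAnnotation(
            chromosomes={c: 2 * l for c, l in genome.chromosomes.items()},
            genes={
                gid: Gene(gid, g.chromosome, g.strand,
                          tuple((2 * s, 2 * e) for s, e in g.exons), g.protein_id)
                for gid, g in genome.genes.items()
            },
        )
        idx2 = genome_base_fractions(doubled, groups, cutoff=200_000)
        for grp in ("allosteric", "other"):
            assert idx2.fraction(grp) == pytest.approx(idx1.fraction(grp), rel=1e-3)


class TestStudyFilters:
    def _study(self, sid, trait, cases, variants):
        return GwasStudy(sid, trait, cases, variants)

    def test_subset_gene_sets_keep_larger(self):
        s1 = self._study("s1", "t", 1000, [("c", 1, 1e-9)])
        s2 = self._study("s2", "t", 1000, [("c", 2, 1e-9)])
        gene_sets = {"s1": frozenset("AB"), "s2": frozenset("ABC")}
        kept = filter_redundant_studies([s1, s2], gene_sets)
        assert [s.study_id for s in kept] == ["s2"]

    def test_disjoint_gene_sets_both_kept(self):
        s1 = self._study("s1", "t", 1000, [("c", 1, 1e-9)])
        s2 = self._study("s2", "t", 1000, [("c", 2, 1e-9)])
        gene_sets = {"s1": frozenset("AB"), "s2": frozenset("CD")}
        assert len(filter_redundant_studies([s1, s2], gene_sets)) == 2

    def test_equal_gene_sets_keep_more_cases(self):
        s1 = self._study("s1", "t", 5_000, [("c", 1, 1e-9)])
        s2 = self._study("s2", "t", 20_000, [("c", 2, 1e-9)])
        gene_sets = {"s1": frozenset("AB"), "s2": frozenset("AB")}
        kept = filter_redundant_studies([s1, s2], gene_sets)
        assert [s.study_id for s in kept] == ["s2"]

    def test_zero_assigned_variants_dropped(self):
        s1 = self._study("s1", "t", 1000, [("c", 1, 1e-9)])
        kept = filter_redundant_studies([s1], {"s1": frozenset()})
        assert kept == []

    def test_different_traits_not_compared(self):
        s1 = self._study("s1", "t1", 1000, [("c", 1, 1e-9)])
        s2 = self._study("s2", "t2", 1000, [("c", 1, 1e-9)])
        gene_sets = {"s1": frozenset("A"), "s2": frozenset("A")}
        assert len(filter_redundant_studies([s1, s2], gene_sets)) == 2


class TestTopVariantSubset:
    def _study(self, ps):
        return GwasStudy("s", "t", 100, [("c", i, p) for i, p in enumerate(ps)])

    def test_fifth_of_ten(self):
        s = self._study([10 ** -(9 + i) for i in range(10)])
        out = top_variant_subset(s)
        assert len(out) == 2
        assert {v[2] for v in out} == {1e-18, 1e-17}

    def test_ceiling_rule(self):
        s = self._study([1e-9, 1e-10, 1e-11])
        assert len(top_variant_subset(s)) == 1

    def test_boundary_tie_by_position(self):
        s = GwasStudy("s", "t", 100, [("c", 5, 1e-9), ("c", 2, 1e-9), ("c", 9, 1e-10)])
        out = top_variant_subset(s)  # ceil(0.6) = 1 with n=3 -> top 1 is 1e-10
        assert out == [("c", 9, 1e-10)]
        out2 = top_variant_subset(s, fraction=0.5)  # 2 kept: tie between pos 5 and 2
        assert out2 == [("c", 9, 1e-10), ("c", 2, 1e-9)]

    def test_fraction_validation(self):
        with pytest.raises(ValueError):
            top_variant_subset(self._study([1e-9]), fraction=0.0)


class TestComputeEnrichment:
    def test_single_allosteric_among_five(self, worked_genome):
        genome, groups = worked_genome
        index = genome_base_fractions(genome, groups)
        assert index.fraction("allosteric") == pytest.approx(0.038)
        study = GwasStudy(
            "s1", "t", 1000,
            [("chr1", 50, 1e-9)] + [("chr1", 9000 + i * 100, 1e-9) for i in range(4)],
        )
        res = compute_enrichment(
            [study], index, genome, groups, mode="all_nonredundant",
            groups=("allosteric", "other"),
        )
        gwas_frac, genome_frac, ratio = res.groups["allosteric"]
        assert gwas_frac == pytest.approx(0.2)
        assert ratio == pytest.approx((1 / 5) / 0.038, rel=1e-12)
        assert round(ratio, 2) == 5.26

    def test_threefold_consistency(self, worked_genome):
        genome, groups = worked_genome
        index = genome_base_fractions(genome, groups)
        n, k = 1000, 114
        variants = [("chr1", 200 + i, 1e-9) for i in range(k)]
        variants += [("chr1", 9000 + i, 1e-9) for i in range(n - k)]
        study = GwasStudy("s1", "t", 1000, variants)
        res = compute_enrichment(
            [study], index, genome, groups, groups=("allosteric", "other")
        )
        gwas_frac, genome_frac, ratio = res.groups["allosteric"]
        assert (gwas_frac, genome_frac) == (pytest.approx(0.114), pytest.approx(0.038))
        assert ratio == pytest.approx(3.0, rel=1e-12)

    def test_null_fractions_give_unit_ratio(self, worked_genome):
        genome, groups = worked_genome
        index = genome_base_fractions(genome, groups)
        # variants proportional to basin sizes: 38 in A's basin, 962 in B's
        variants = [("chr1", i, 1e-9) for i in range(38)]
        variants += [("chr1", 9000 + i, 1e-9) for i in range(962)]
        study = GwasStudy("s1", "t", 1000, variants)
        res = compute_enrichment(
            [study], index, genome, groups, groups=("allosteric", "other")
        )
        assert res.groups["allosteric"][2] == pytest.approx(1.0)
        assert res.groups["other"][2] == pytest.approx(1.0)

    def test_largest_study_mode_picks_max_cases(self, worked_genome):
        genome, groups = worked_genome
        index = genome_base_fractions(genome, groups)
        small = GwasStudy("s1", "t", 100, [("chr1", 50, 1e-9)])
        big = GwasStudy("s2", "t", 10_000, [("chr1", 9000, 1e-9)])
        res = compute_enrichment(
            [small, big], index, genome, groups, mode="largest_study",
            groups=("allosteric", "other"),
        )
        assert res.groups["allosteric"][0] == 0.0  # only s2's variant used
        assert res.n_observations == 1

    def test_pooled_genes_mode(self, worked_genome):
        genome, groups = worked_genome
        index = genome_base_fractions(genome, groups)
        s1 = GwasStudy("s1", "t", 100, [("chr1", 50, 1e-9), ("chr1", 60, 1e-9)])
        s2 = GwasStudy("s2", "t", 200, [("chr1", 9000, 1e-9)])
        res = compute_enrichment(
            [s1, s2], index, genome, groups, mode="pooled_genes",
            groups=("allosteric", "other"),
        )
        # trait gene list {A, B}: half allosteric vs genome gene fraction 1/2
        assert res.groups["allosteric"][2] == pytest.approx(1.0)
        assert res.n_observations == 2


class TestMhPooledTest:
    def test_unit_or_strata(self):
        tables = [np.array([[10, 90], [20, 180]]), np.array([[5, 45], [50, 450]])]
        res = mh_pooled_test(tables)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.cochran_q == pytest.approx(0.0, abs=1e-12)

    def test_single_proportional_stratum(self):
        res = mh_pooled_test([np.array([[10, 90], [100, 900]])])
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)
        assert res.q_p_value == 1.0

    def test_textbook_formula(self):
        tables = [np.array([[12, 34], [8, 41]]), np.array([[7, 20], [15, 52]])]
        res = mh_pooled_test(tables)
        num = sum(t[0, 0] * t[1, 1] / t.sum() for t in tables)
        den = sum(t[0, 1] * t[1, 0] / t.sum() for t in tables)
        assert res.odds_ratio == pytest.approx(num / den, rel=1e-9)

    def test_zero_margin_stratum_dropped(self):
        tables = [np.array([[0, 0], [10, 90]]), np.array([[10, 90], [100, 900]])]
        res = mh_pooled_test(tables)
        assert res.n_strata == 1 and res.n_dropped == 1

    def test_all_dropped_raises(self):
        with pytest.raises(ValueError):
            mh_pooled_test([np.array([[0, 0], [10, 90]])])


class TestReaders:
    def test_bed_and_gtf_equivalent(self, tmp_path):
        chrom = tmp_path / "chrom.tsv"
        chrom.write_text("chromosome\tlength\nchr1\t50000\n")
        bed = tmp_path / "exons.bed"
        bed.write_text("chr1\t100\t200\tgA|P1\nchr1\t5000\t5100\tgB|P2\n")
        gtf = tmp_path / "exons.gtf"
        gtf.write_text(
            'chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "gA"; protein_id "P1";\n'
            'chr1\tsrc\texon\t5001\t5100\t.\t+\t.\tgene_id "gB"; protein_id "P2";\n'
        )
        g_bed = read_genome(str(chrom), str(bed))
        g_gtf = read_genome(str(chrom), str(gtf))
        assert g_bed.genes.keys() == g_gtf.genes.keys()
        for gid in g_bed.genes:
            assert g_bed.genes[gid].exons == g_gtf.genes[gid].exons
            assert g_bed.genes[gid].protein_id == g_gtf.genes[gid].protein_id

    def test_malformed_interval_reports_line(self, tmp_path):
        chrom = tmp_path / "chrom.tsv"
        chrom.write_text("chromosome\tlength\nchr1\t50000\n")
        bed = tmp_path / "exons.bed"
        bed.write_text("chr1\t100\t200\tgA|P1\nchr1\toops\t300\tgB|P2\n")
        with pytest.raises(ValueError, match="line 2"):
            read_genome(str(chrom), str(bed))
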