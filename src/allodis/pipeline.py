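"""End-to-end orchestration of the analysis stages over a fixture directory.

Stages run in dependency order (annotate -> enrich -> network -> comorbidity
-> gwas -> structure -> evolution), each reading the exchange-format files
emitted by the synthetic-data generator (or real equivalents laid out the
same way), writing per-stage TSV outputs and contributing to a summary
report. A single pipeline seed fans out to per-stage sub-seeds so enabling
or disabling one stage never shifts another stage's randomness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation as ann_mod
from . import comorbidity as com_mod
from . import evolution as evo_mod
from . import gwas as gwas_mod
from . import network as net_mod
from . import ontology as onto_mod
from . import structure as struct_mod

ALL_STAGES = (
    "annotate",
    "enrich",
    "network",
    "comorbidity",
    "gwas",
    "structure",
    "evolution",
)


@dataclass
class PipelineConfig:
    input_dir: str
    output_dir: str
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    sim_threshold: float = 0.9
    proximity_cutoff: int = 100_000
    top_fraction: float = 0.2
    betweenness_threshold: float = 1000.0
    max_variants: int | None = None
    n_permutations: int = 2000
    correction: str = "bh_fdr"
    p_significant: float = 0.05


class DependencyError(RuntimeError):
    pass


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise DependencyError(f"stage {stage!r} requires missing input {path}")
    return path


def _load_ontology(indir: Path, stage: str) -> onto_mod.Ontology:
    return onto_mod.parse_obo(_require(indir / "ontology.obo", stage).read_text())


def _load_groups(indir: Path, stage: str) -> dict[str, str]:
    df = pd.read_csv(_require(indir / "protein_groups.tsv", stage), sep="\t")
    return dict(zip(df.protein_id, df.group))


def _load_annotations(outdir: Path, stage: str) -> list[ann_mod.ProteinAnnotation]:
    path = _require(outdir / "annotations.tsv", stage)
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        ind = frozenset(row.doid_independent.split(";")) if row.doid_independent else frozenset()
        full = frozenset(row.doid_full.split(";")) if row.doid_full else frozenset()
        out.append(
            ann_mod.ProteinAnnotation(
                protein_id=row.protein_id,
                allosteric=bool(row.allosteric),
                group=row.group,
                doid_full=full,
                doid_independent=ind,
            )
        )
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the requested stages and return the summary report."""
    indir = Path(config.input_dir)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    unknown = set(config.stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    # fail fast on missing inputs before any computation
    if "gwas" in config.stages:
        _require(indir / "chromosomes.tsv", "gwas")
        _require(indir / "exons.bed", "gwas")
        _require(indir / "gwas_studies.tsv", "gwas")
    report: dict = {"seed": config.seed, "stages": {}}
    for stage in ALL_STAGES:
        if stage in config.stages:
            report["stages"][stage] = _STAGE_FNS[stage](config, indir, outdir)
    (outdir / "summary.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    (outdir / "pipeline_config.json").write_text(
        json.dumps({k: str(v) for k, v in vars(config).items()}, indent=2, sort_keys=True)
    )
    return report


def stage_annotate(config: PipelineConfig, indir: Path, outdir: Path) -> dict:
    ontology = _load_ontology(indir, "annotate")
    groups = _load_groups(indir, "annotate")
    med = pd.read_csv(_require(indir / "medgen_xref.tsv", "annotate"), sep="\t")
    omim = pd.read_csv(_require(indir / "omim_xref.tsv", "annotate"), sep="\t")
    names = {
        tid: term.name for tid, term in ontology.terms.items() if not term.obsolete
    }
    recs_df = pd.read_csv(
        _require(indir / "disease_records.tsv", "annotate"), sep="\t",
        keep_default_na=False,
    )
    records = []
    for row in recs_df.itertuples(index=False):
        records.append(
            ann_mod.DiseaseRecord(
                protein_id=row.protein_id,
                source=row.source,
                medgen_ids=frozenset(filter(None, row.medgen_ids.split(";"))),
                omim_ids=frozenset(filter(None, row.omim_ids.split(";"))),
                disease_names=frozenset(filter(None, row.disease_names.split(";"))),
            )
        )
    annotations, n_excluded = ann_mod.map_to_doid(
        records,
        dict(zip(med.medgen_id, med.doid)),
        dict(zip(omim.omim_id, omim.doid)),
        ann_mod.build_name_index(names),
        ontology,
    )
    for a in annotations:
        a.allosteric = groups.get(a.protein_id) == "allosteric"
        a.group = "allosteric" if a.allosteric else "disease"
    rows = [
        (
            a.protein_id, int(a.allosteric), a.group, len(a.doid_independent),
            ";".join(sorted(a.doid_full)), ";".join(sorted(a.doid_independent)),
        )
        for a in annotations
    ]
    pd.DataFrame(
        rows,
        columns=["protein_id", "allosteric", "group", "n_diseases", "doid_full",
                 "doid_independent"],
    ).to_csv(outdir / "annotations.tsv", sep="\t", index=False)
    return {"n_annotated": len(annotations), "n_excluded": n_excluded}


def stage_enrich(config: PipelineConfig, indir: Path, outdir: Path) -> dict:
    ontology = _load_ontology(indir, "enrich")
    annotations = _load_annotations(outdir, "enrich")
    names = {t: ontology.terms[t].name for t in ontology.terms}
    closed = {a.protein_id: a.doid_full for a in annotations}
    study = [a.protein_id for a in annotations if a.allosteric]
    if not study:
        return {"n_enriched": 0, "note": "no allosteric proteins annotated"}
    results = onto_mod.term_enrichment(study, closed, config.correction, names)
    onto_mod.write_enrichment_tsv(results, outdir / "enrichment.tsv")
    significant = [r.term_id for r in results if r.p_adj < config.p_significant]
    summary = {"n_terms": len(results), "n_significant": len(significant)}
    if len(significant) >= 3:
        sim = onto_mod.shortest_path_similarity(ontology, significant)
        pvals = {r.term_id: r.p_raw for r in results}
        retained = onto_mod.redundancy_filter(
            sim, pvals, ontology, threshold=config.sim_threshold
        )
        summary["n_after_redundancy_filter"] = len(retained)
        kept_idx = [i for i, t in enumerate(sim.term_ids) if t in retained]
        if len(kept_idx) >= 3:
            sub = onto_mod.SimilarityMatrix(
                term_ids=[sim.term_ids[i] for i in kept_idx],
                sim=sim.sim[np.ix_(kept_idx, kept_idx)],
                length_max=sim.length_max,
            )
            coords = onto_mod.mds_embedding(sub)
            pd.DataFrame(
                [(t, x, y) for t, (x, y) in sorted(coords.items())],
                columns=["term_id", "x", "y"],
            ).to_csv(outdir / "semantic_space.tsv", sep="\t", index=False)
    return summary


def stage_network(config: PipelineConfig, indir: Path, outdir: Path) -> dict:
    annotations = _load_annotations(outdir, "network")
    graph = net_mod.project_disease_network(annotations)
    cent = net_mod.compute_centralities(graph)
    cent.to_frame().to_csv(outdir / "disease_network_centralities.tsv", sep="\t", index=False)
    largest, n_small, n_isolated = net_mod.component_summary(graph)
    groups = {a.protein_id: "allosteric" if a.allosteric else "non_allosteric"
              for a in annotations}
    summary = {
        "n_nodes": graph.number_of_nodes(),
        "n_edges": graph.number_of_edges(),
        "largest_component": len(largest),
        "n_small_components": n_small,
        "n_isolated": n_isolated,
    }
    if len(set(groups.values())) == 2:
        cmp_b = net_mod.compare_groups(cent.betweenness, groups, test="wilcoxon")
        counts = {a.protein_id: float(len(a.doid_independent)) for a in annotations}
        cmp_n = net_mod.compare_groups(counts, groups, test="wilcoxon")
        summary["betweenness_wilcoxon_p"] = cmp_b.p_value
        summary["n_diseases_wilcoxon_p"] = cmp_n.p_value
        summary["median_n_diseases"] = dict(zip(cmp_n.groups, cmp_n.summary))
    ppi_path = indir / "ppi_edges.tsv"
    if ppi_path.exists():
        df = pd.read_csv(ppi_path, sep="\t")
        ppi, n_self = net_mod.build_ppi_graph(
            list(zip(df.protein_a, df.protein_b))
        )
        ppi_cent = net_mod.compute_centralities(ppi)
        ppi_cent.to_frame().to_csv(outdir / "ppi_centralities.tsv", sep="\t", index=False)
        summary["ppi_nodes"] = ppi.number_of_nodes()
        summary["ppi_edges"] = ppi.number_of_edges()
        summary["ppi_self_loops_dropped"] = n_self
        try:
            joint = net_mod.joint_centrality_summary(
                cent, ppi_cent, groups, threshold=config.betweenness_threshold
            )
            summary["joint_betweenness"] = {
                "fraction_above": joint.fraction_above,
                "correlation": joint.correlation,
                "n_included": joint.n_included,
            }
        except ValueError:
            pass
    return summary


def stage_comorbidity(config: PipelineConfig, indir: Path, outdir: Path) -> dict:
    ontology = _load_ontology(indir, "comorbidity")
    annotations = _load_annotations(outdir, "comorbidity")
    med = pd.read_csv(_require(indir / "medgen_xref.tsv", "comorbidity"), sep="\t")
    doid_to_pheno: dict[str, set[str]] = {}
    for row in med.itertuples(index=False):
        doid_to_pheno.setdefault(row.doid, set()).add(row.medgen_id)
    pairs_df = pd.read_csv(
        _require(indir / "comorbidity_pairs.tsv", "comorbidity"), sep="\t"
    )
    network = com_mod.ComorbidityNetwork(
        list(zip(pairs_df.phenotype_a, pairs_df.phenotype_b))
    )
    doids = {a.protein_id: a.doid_independent for a in annotations}
    counts = com_mod.comorbidity_profile(doids, ontology, doid_to_pheno, network)
    pd.DataFrame(
        [
            (c.protein_id, c.n_diseases, len(c.phenotype_ids), c.n_comorbid_pairs)
            for c in counts
        ],
        columns=["protein_id", "n_diseases", "n_phenotypes", "n_comorbid_pairs"],
    ).to_csv(outdir / "comorbidity_counts.tsv", sep="\t", index=False)
    summary: dict = {"n_proteins": len(counts)}
    allo = {a.protein_id for a in annotations if a.allosteric}
    flags = {c.protein_id: c.n_comorbid_pairs > 0 for c in counts}
    grouping = {
        p: ("allosteric" if p in allo else "non_allosteric") for p in flags
    }
    if len(set(grouping.values())) == 2:
        cmp = net_mod.compare_groups(flags, grouping, test="proportions")
        summary["comorbid_fraction"] = dict(zip(cmp.groups, cmp.summary))
        summary["proportions_p"] = cmp.p_value
    return summary


def stage_gwas(config: PipelineConfig, indir: Path, outdir: Path) -> dict:
    genome = gwas_mod.read_genome(
        str(indir / "chromosomes.tsv"), str(indir / "exons.bed")
    )
    groups = _load_groups(indir, "gwas")
    studies = gwas_mod.read_gwas_studies(str(indir / "gwas_studies.tsv"))
    if config.max_variants is not None:
        studies = [s for s in studies if len(s.variants) < config.max_variants]
    index = gwas_mod.genome_base_fractions(genome, groups, config.proximity_cutoff)
    gene_sets = {
        s.study_id: frozenset(
            g for g in gwas_mod.assign_study_genes(s, genome, config.proximity_cutoff)
            if g is not None
        )
        for s in studies
    }
    retained = gwas_mod.filter_redundant_studies(studies, gene_sets)
    rows = []
    summary: dict = {
        "n_studies": len(studies),
        "n_retained": len(retained),
        "genome_fractions": {
            g: index.fraction(g) for g in ("allosteric", "disease", "other")
        },
    }
    for mode in ("largest_study", "pooled_genes", "all_nonredundant"):
        res = gwas_mod.compute_enrichment(
            retained, index, genome, groups, mode=mode, cutoff=config.proximity_cutoff
        )
        for grp, (gf, nf, ratio) in res.groups.items():
            rows.append((mode, grp, gf, nf, ratio))
        summary[f"enrichment_{mode}"] = {
            g: res.groups[g][2] for g in res.groups
        }
    res_top = gwas_mod.compute_enrichment(
        retained, index, genome, groups, mode="all_nonredundant",
        cutoff=config.proximity_cutoff, top_fraction=config.top_fraction,
    )
    for grp, (gf, nf, ratio) in res_top.groups.items():
        rows.append(("top_fraction", grp, gf, nf, ratio))
    summary["enrichment_top_fraction"] = {g: res_top.groups[g][2] for g in res_top.groups}
    if "allosteric" in res_top.pooled:
        t = res_top.pooled["allosteric"]
        summary["mh_allosteric"] = {
            "odds_ratio": t.odds_ratio, "p": t.p_value,
            "cochran_q": t.cochran_q, "q_p": t.q_p_value,
        }
    pd.DataFrame(
        rows, columns=["mode", "group", "gwas_fraction", "genome_fraction", "ratio"]
    ).to_csv(outdir / "gwas_enrichment.tsv", sep="\t", index=False)
    return summary


def stage_structure(config: PipelineConfig, indir: Path, outdir: Path) -> dict:
    edges_df = pd.read_csv(_require(indir / "rin_edges.tsv", "structure"), sep="\t")
    comm_df = pd.read_csv(_require(indir / "communities.tsv", "structure"), sep="\t")
    dom_df = pd.read_csv(_require(indir / "domains.tsv", "structure"), sep="\t")
    mut_df = pd.read_csv(_require(indir / "mutations.tsv", "structure"), sep="\t")
    seed = int(np.random.default_rng([config.seed, 60]).integers(0, 2**31))
    summary: dict = {"proteins": {}}
    for pid, pe in edges_df.groupby("protein_id"):
        n_res = int(comm_df[comm_df.protein_id == pid].residue.max())
        rin = struct_mod.ResidueInteractionNetwork(
            protein_id=pid,
            n_residues=max(n_res, int(pe.res_j.max())),
            edges=[
                struct_mod.RinEdge(int(r.res_i), int(r.res_j), r.type, int(r.count))
                for r in pe.itertuples(index=False)
            ],
        )
        labels = {
            int(r.residue): str(r.community)
            for r in comm_df[comm_df.protein_id == pid].itertuples(index=False)
        }
        comm = struct_mod.CommunityAssignment(protein_id=pid, labels=labels)
        muts = set(mut_df[mut_df.protein_id == pid].residue.astype(int))
        entry: dict = {}
        doms = dom_df[dom_df.protein_id == pid]
        for d in doms.itertuples(index=False):
            domain = struct_mod.DomainMapping(d.domain_id, int(d.start), int(d.end))
            mat = struct_mod.bin_domain_interactions(rin, domain)
            entry.setdefault("domain_totals", {})[d.domain_id] = mat.total()
        if muts and len(comm.communities()) >= 2:
            stat = struct_mod.community_clustering_stat(
                comm, muts, n_perm=config.n_permutations, seed=seed
            )
            entry["clustering"] = {
                "k": stat.k,
                "observed_communities": stat.observed_communities,
                "expected_mean": stat.expected_mean,
                "z": stat.z,
                "p_perm": stat.p_perm,
            }
            iface = comm.interface_residues(rin)
            if iface:
                enr = struct_mod.interface_mutation_enrichment(
                    rin.n_residues, iface, muts
                )
                entry["interface_enrichment"] = {
                    "ratio": enr.ratio, "p": enr.p,
                }
        summary["proteins"][pid] = entry
    (outdir / "structure_stats.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True)
    )
    return summary


def stage_evolution(config: PipelineConfig, indir: Path, outdir: Path) -> dict:
    summary: dict = {}
    msa_path = indir / "orthogroup_alignment.fasta"
    if msa_path.exists():
        msa = evo_mod.read_alignment_fasta(str(msa_path), primate_species=())
        focal = next(r.sequence_id for r in msa.rows if r.is_human)
        summary["conservation_percent"] = evo_mod.conservation_score(msa, focal)
    og_df = pd.read_csv(_require(indir / "orthogroups.tsv", "evolution"), sep="\t")
    ogs: dict[str, evo_mod.Orthogroup] = {}
    for row in og_df.itertuples(index=False):
        og = ogs.get(row.group_id)
        if og is None:
            ogs[row.group_id] = og = evo_mod.Orthogroup.__new__(evo_mod.Orthogroup)
            og.group_id = row.group_id
            og.taxonomic_level = row.level
            og.members = []
            og.lower_level_only = bool(row.lower_level_only)
        og.members.append(
            evo_mod.OrthogroupMember(
                row.protein_id, row.species, bool(row.is_human), bool(row.allosteric)
            )
        )
    groups = list(ogs.values())
    level = groups[0].taxonomic_level if groups else "metazoans"
    classes = evo_mod.classify_homologs(groups, level)
    class_counts: dict[str, int] = {}
    for c in classes.values():
        class_counts[c] = class_counts.get(c, 0) + 1
    summary["homolog_classes"] = class_counts
    pd.DataFrame(
        sorted(classes.items()), columns=["protein_id", "homolog_class"]
    ).to_csv(outdir / "homolog_classes.tsv", sep="\t", index=False)
    lengths_df = pd.read_csv(
        _require(indir / "protein_lengths.tsv", "evolution"), sep="\t"
    )
    lengths = dict(zip(lengths_df.protein_id, lengths_df.length))
    psc_df = pd.read_csv(_require(indir / "psc_variants.tsv", "evolution"), sep="\t")
    variants = [
        evo_mod.PscVariant(
            r.protein_id, int(r.codon), r.amino_change, float(r.allele_frequency),
            r.consequence, bool(r.passes_filters),
        )
        for r in psc_df.itertuples(index=False)
    ]
    profiles = evo_mod.psc_profile(variants, lengths)
    pd.DataFrame(
        [
            (p.protein_id, p.length, p.psc_count, p.psc_density,
             p.mean_allele_frequency, int(p.intolerant))
            for p in profiles.values()
        ],
        columns=["protein_id", "length", "psc_count", "psc_density",
                 "mean_allele_frequency", "intolerant"],
    ).to_csv(outdir / "psc_profiles.tsv", sep="\t", index=False)
    n_intol = sum(1 for p in profiles.values() if p.intolerant)
    summary["psc"] = {
        "n_proteins": len(profiles),
        "n_intolerant": n_intol,
        "intolerant_fraction": n_intol / len(profiles) if profiles else 0.0,
    }
    return summary


_STAGE_FNS = {
    "annotate": stage_annotate,
    "enrich": stage_enrich,
    "network": stage_network,
    "comorbidity": stage_comorbidity,
    "gwas": stage_gwas,
    "structure": stage_structure,
    "evolution": stage_evolution,
}
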