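# allodis

Systems-level analyses of **allosteric proteins in genetic disease**, packaged
as a tested, reusable pipeline that runs end to end on synthetic data with
planted, recoverable effects.

Allosteric proteins — proteins regulated through ligand binding at a site
distinct from their functional (orthosteric) site — sit at the crossroads of
cellular regulation. This package implements the quantitative machinery needed
to ask whether such proteins are disproportionately central in human genetic
disease:

- **Ontology enrichment with redundancy filtering.** Disease-ontology (DOID)
  annotations are ancestor-closed and tested for enrichment with the
  hypergeometric upper tail, `P(X ≥ k)` for `X ~ Hypergeom(N, K, n)`, with
  Bonferroni or Benjamini–Hochberg correction. Enriched terms are de-redundified
  with an edge-based semantic similarity,
  `sim(i,j) = (length_max − length_ij + 1) / length_max`, where `length_ij`
  counts the nodes on the shortest undirected is_a path, followed by a filter
  that keeps the more significant term of every pair with `sim > 0.9` and a
  classical MDS embedding of the survivors into a 2-D semantic plane.
- **Disease–protein and PPI networks.** A diseasome-style projection connects
  proteins sharing a disease (edge weight = number of shared diseases);
  unnormalised betweenness centrality (raw shortest-path transit counts),
  component structure, Wilcoxon/proportion group comparisons, joint-centrality
  summaries across two networks, and ANCOVA on log10-transformed values.
- **GWAS base-proximity enrichment.** Every genome base and every
  genome-wide-significant variant (p < 1e-8) is assigned to the nearest
  protein-coding gene with an exon within 100 kb; group enrichment is
  `% of GWAS variants near the group / % of genome bases near the group`,
  computed per-trait (largest study), over pooled nonredundant studies, or on
  deduplicated per-trait gene lists, with Mantel–Haenszel pooling of per-study
  2×2 tables and Cochran's Q heterogeneity.
- **Structural mutation clustering.** Residue-interaction networks binned into
  50×50 domain contact matrices; clustering of pathogenic mutations across
  dynamic communities scored against a uniform-draw permutation null; exact
  binomial enrichment of mutations in community and PPI interfaces.
- **Evolution and loss-of-function.** Conservation as the mean non-primate
  pairwise identity in orthogroup alignments; ortholog/paralog/duplicate
  classification from orthogroup membership; premature-stop-codon (PSC)
  profiles with same-codon allele-frequency merging, where zero observed PSCs
  marks inactivation intolerance.
- **Synthetic data.** Every input the pipeline consumes (OBO ontology,
  annotation TSVs, toy genome + GWAS tables, RIN/community/mutation tables,
  alignments, orthogroups, PPI edges, comorbidity pairs, PSC variants) is
  generated from a seeded configuration with planted effect sizes, alongside a
  ground-truth manifest.

## Worked example

```sh
allodis simulate --seed 1 --out fixtures/
allodis run-all --input-dir fixtures/ --output-dir results/ --seed 1
```

With the default configuration (400 proteins, 10% allosteric, planted 2.0×
allosteric / 1.5× disease GWAS enrichment, 2:1 disease-count ratio, 10% MSA
divergence) the summary reports, among others:

```
annotate     145 proteins mapped to DOID terms, 0 excluded
network      145 nodes, 824 edges, one connected component of 145
             median diseases per protein: allosteric 2.0 vs non-allosteric 1.0
             (Wilcoxon p = 1.1e-06)
gwas         enrichment (all nonredundant studies):
             allosteric 2.56, disease 1.47, other 0.32
evolution    conservation 90.3% (planted divergence 10%)
             homolog classes recovered exactly (50/30/30/40)
             121/400 proteins PSC-intolerant
```

The allosteric enrichment ratio recovers the planted 2.0× within sampling
error of the 73 variants; the disease-count medians reflect the planted 2:1
mean ratio; conservation recovers 100·(1 − q)% for the planted per-site
divergence q = 0.1.

A small worked calculation that needs no simulation: in a genome where 3.8%
of bases lie nearest to allosteric genes, a study with five variants of which
one is allosteric-proximal gives an enrichment of (1/5)/0.038 = **5.26×**,
and a pooled variant set with 11.4% allosteric-proximal variants gives
0.114/0.038 = **3.0×**.

## Layout

```
src/allodis/
  ontology.py     OBO parsing, closures, enrichment, similarity, MDS
  annotation.py   disease-record harmonisation, quaternary classification
  network.py      disease projection, PPI graphs, centralities, statistics
  comorbidity.py  phenotype expansion and comorbidity-pair counting
  gwas.py         genome proximity index, enrichment modes, MH pooling
  structure.py    contact matrices, clustering stat, interface enrichment
  evolution.py    conservation, homolog classes, PSC profiles
  simulate.py     synthetic-data generators with planted effects
  pipeline.py     stage orchestration
  cli.py          command-line interface (allodis simulate / run-all / ...)
```

See `docs/methods.md` for the statistical models, parameter defaults and
known limitations.
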