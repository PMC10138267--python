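# Methods

This note documents the models and procedures implemented in `allodis`, the
parameters that matter, the design choices made where the design was open,
and what the synthetic-data generator does and does not emulate.

## Ontology analyses

**Enrichment.** Protein annotations are DOID term sets closed over `is_a`
ancestors up to the disease root. For each term annotated in the population,
the raw p-value is the hypergeometric upper tail `P(X ≥ k)` with population
size `N`, `K` annotated proteins and a study set of `n`; only enrichment is
tested (no depletion). Correction is Bonferroni (`min(1, m·p)`) or the
standard Benjamini–Hochberg step-up FDR.

**Semantic similarity.** For a set of (typically enriched) terms, the
similarity of a pair is `(length_max − length_ij + 1)/length_max`, where
`length_ij` is the number of nodes, endpoints inclusive, on the shortest path
between the terms in the undirected `is_a` graph. Two conventions were open:

- *Endpoint counting.* Nodes are counted inclusive of endpoints (identical
  terms → 1, adjacent → 2), so that `sim` of a term with itself is exactly 1.
- *Path universe.* Paths are computed on the whole ontology graph, not on the
  subgraph induced by the enriched terms, because induced subgraphs are often
  disconnected. `length_max` is taken over the supplied pairs only.

**Redundancy filter.** While any retained pair has `sim > 0.9` (threshold
configurable), the globally least significant term participating in such a
pair is dropped. This fixpoint formulation is order-independent for distinct
p-values; a greedy pairwise sweep is not, because overlapping pairs can
cascade differently depending on visit order. P-value ties (compared exactly
by default; an epsilon is configurable) are resolved by keeping the term
higher in the ontology, measured as the smaller ancestor closure, then by
term id.

**Embedding.** Classical (Torgerson) metric MDS of the distance matrix
`d = 1 − sim`: double-centre `−d²/2` and scale the top-two eigenvectors by
the square roots of their eigenvalues. A distance matrix exactly embeddable
in the plane is reproduced to numerical tolerance up to rotation/reflection;
negative eigenvalue directions are set to zero.

## Annotation harmonisation

Disease names match by an order-free bag of words (lowercase, commas
stripped, whitespace-tokenised, exact token-set equality — not subset or
Jaccard, because the motivating inconsistencies are pure reorderings such as
"myopathy, congenital" vs "congenital myopathy"). MedGen ids, OMIM ids and
names map to DOID terms and are unioned per protein; proteins with no
mappable term are excluded and counted. Per-protein term sets are reduced to
an antichain by dropping every term that is an ancestor of another associated
term.

Quaternary structure: chains shorter than 30 residues are peptide ligands and
removed (a chain of exactly 30 residues is kept); a structure is a heteromer
with ≥ 2 distinct accessions remaining, a homomer with ≥ 2 chains of one
accession, else a monomer; the protein takes the strongest class across its
structures (heteromer > homomer > monomer).

## Networks

The disease projection contains every annotated protein; two proteins are
joined when they share ≥ 1 independent disease term, with the shared count as
edge weight. Betweenness is reported **unnormalised** (raw shortest-path
transit counts over unordered pairs) so absolute thresholds such as 1000 are
meaningful; the default treats edges as unit length, with an optional
weighted mode using length `1/weight`. Component ties are broken by the
lexicographically smallest member.

Group comparisons: Wilcoxon rank-sum with the exact null for combined
n ≤ 12 without ties, otherwise a tie-corrected normal approximation without
continuity correction (if every observation is tied the p-value is defined
as 1); proportions compared with the chi-square test without continuity
correction. ANCOVA fits `log10(y+c) ~ log10(x+c) + group` (pseudocount
c = 1 by default, as responses are non-negative counts or path counts) and
reports type-II F-tests for the group effect and, from the interaction model,
for slope equality. Joint-centrality summaries exclude proteins with zero
betweenness in either network before correlating log10 betweenness.

## Comorbidity

A protein's independent disease terms are ancestor-closed to the root (the
root itself is typically unmapped and silently skipped), converted to
phenotype ids through a one-to-many cross reference, and every unordered
phenotype pair is looked up in the comorbidity network. Only proteins with
≥ 2 independent disease terms are profiled, matching the network-analysis
protein set.

## GWAS proximity enrichment

Distance from a position to a gene is the bp gap to the nearest exon
boundary, zero inside an exon; strand is ignored. A base or variant is
assigned to the nearest gene when that distance is strictly below the cutoff
(100 kb default, 50 kb supported), with equidistant ties resolved to the
smaller gene id. Unassigned bases and variants stay in every denominator —
this is what makes a five-variant study with one allosteric-proximal variant
a (1/5)/0.038 = 5.26× enrichment regardless of how the other four resolve.

Study curation: variants are filtered at p < 1e-8; studies with no assigned
variant are dropped; within a trait, studies with identical variant sets, or
whose candidate gene set is a subset of another's, are collapsed keeping the
study with more genes, then more cases, then the smaller id. Three analysis
modes: per-trait largest study, all nonredundant studies pooled, and
per-trait deduplicated gene lists compared against the genome-wide gene
composition. A top-fraction mode restricts each study to the `ceil(f·n)`
variants with the smallest p-values (boundary ties by position).

Significance: per-study 2×2 tables (variants in/not in a group vs. a
genome-derived reference row scaled to 1e6 bases) are pooled with the
Mantel–Haenszel estimator; the package reports both the MH chi-square test of
OR = 1 and Cochran's Q (inverse-variance weights on Haldane-corrected log
odds ratios around the pooled estimate, df = k−1), since either may be the
statistic behind any given published p-value. Strata with a zero margin are
dropped with a count.

## Structure

Domains (≥ 50 residues) are divided into 50 equal units; residue `p` maps to
unit `min(50, floor((p − start)/length · 50) + 1)`, and each in-domain edge
adds its contact count to the canonical upper-triangle cell, so the matrix
total equals the in-domain contact total exactly. Normalisation divides by
the domain total, optionally rescales one group's panel, and log10-transforms
with a pseudocount. "Long-range" contacts default to a sequence separation of
≥ 20 of the 50 units — the notion is not standardised, so the threshold is a
parameter — and panels are compared by a two-sided Wilcoxon on per-domain
long-range fractions.

Mutation clustering: the observed statistic is the number of distinct
communities containing ≥ 1 mutated residue; the null redraws the same number
of residues uniformly **without replacement from the community-labelled
residues** (conditioning on the structure's labelled coverage), and
`p = (1 + #{perm ≤ obs})/(n_perm + 1)`, lower-tailed, with the +1 correction
avoiding zero p-values. The permutation mean agrees with the closed-form
occupancy expectation `Σ_i (1 − C(N−s_i, k)/C(N, k))`. Because the statistic
is integer-valued with large probability steps, this p-value is conservative:
under a uniform null its rejection rate at α = 0.05 is ≈ 2%, not 5% — a
property of any fully tie-counting permutation p on a coarse discrete
statistic, worth remembering when interpreting marginal clustering p-values.

Interface enrichment uses a two-sided exact binomial test of the
in-interface mutation count with success probability `|interface|/L`;
interaction-type stratification (e.g. hydrogen bonds only) filters edges
before interface residues are identified.

Representative structures must cover ≥ 75% of the protein, be solved better
than 3 Å and have fewer than 12 chains; among survivors the largest ligand
wins, then resolution, then coverage.

## Evolution and loss of function

Conservation of a human protein is the mean over non-primate partners of the
fraction of identical residues among mutually non-gapped columns, × 100.
Primates (and other human rows) are excluded so all partners share a
comparable divergence time. Strict identity is the default; an optional mode
also counts physicochemically similar residues (small/aromatic/polar/amide/
acidic/basic classes).

Homolog classes per taxonomic level: orthogroups containing only
lower-level proteins are excluded wholesale; a human non-allosteric member is
a *paralog* when the group has a human allosteric member, an *ortholog of a
non-human allosteric protein* when it has only non-human allosteric members,
otherwise a *reference* candidate; a human allosteric member with a human
non-allosteric co-member is a *duplicated allosteric* protein. Orthologs
already identified at the lower level can be excluded from the reference set.

PSC profiles keep stop-gained variants that pass quality filters with
allele frequency > 0 on main isoforms; variants in the same codon producing
the same amino-acid change merge with summed allele frequencies. A protein
with zero surviving PSCs is inactivation-intolerant.

## Synthetic data

All generators are pure functions of (configuration, seed) and emit byte-
identical output on identical input, plus a ground-truth manifest. Defaults
define the simulated study conditions:

| parameter | default | rationale |
|---|---|---|
| n_proteins | 400 | desk-scale proteome |
| allosteric_fraction | 0.10 | small minority, as in real proteomes |
| disease_fraction | 0.30 | share of non-allosteric proteins with disease (~6000/20000 regime) |
| disease counts | 1 + NB, means 3.0 vs 1.5 | shifted negative binomial keeps every disease protein at ≥ 1 disease while the group means retain the planted 2:1 ratio exactly |
| genome | 2 × 400 kb, 60 genes × 3 exons | toy scale; group base fractions mirror proteome composition |
| planted GWAS enrichment | 2.0× allosteric, 1.5× disease | variant groups drawn with probability `E_g · f_g` against the *realised* genome fractions, so the expected ratio is exactly `E_g` for any random layout |
| study sizes | cases log-uniform 1e3–1e5, ~8 variants | the moderate-power regime of most GWA studies |
| RIN | 300 residues, 6 contiguous communities, 900 edges, 80% intra | semi-rigid blocks with mostly internal contacts |
| mutation clustering κ | 1 (uniform) | κ = 1 draws residues uniformly (the exact test null); larger κ concentrates mutations via a Dirichlet-multinomial with concentration ∝ 1/κ |
| MSA divergence q | 0.10 | expected conservation 100·(1−q)% = 90% |
| PPI | preferential attachment, mean degree 4, no hub bias | hub bias b re-assigns the allosteric label ∝ degree^(b−1); b = 1 leaves labels independent of degree |

What the generator does **not** emulate: real genome scale or linkage
disequilibrium, real ontology content, correlated disease co-annotation
structure, alignment errors, or structure-determination biases. Passing the
recovery and calibration suites therefore demonstrates that the estimators
are unbiased and the tests calibrated under the stated sampling models — not
that the biological conclusions transfer to any particular real dataset.

## Numerical choices and degenerate inputs

- Equidistant-gene and component-size ties break deterministically
  (gene id, lexicographic member) so reruns are byte-identical.
- The genome proximity sweep only touches bases within the cutoff window of
  each exon and processes genes in ascending id with strict-improvement
  updates, which reproduces the per-base brute-force scan exactly.
- Long-range comparison of single-domain panels reports NaN rather than a
  meaningless rank-test p.
- All-tied group comparisons return p = 1.
- The pipeline derives per-stage seeds from the run seed by seeding a
  generator with (seed, stage index); disabling one stage leaves the others'
  outputs byte-identical.

## Problem sizes

The test and acceptance workloads use 2 000-protein annotation draws,
~5 000-variant GWAS pools, 100 small-graph betweenness oracles, 500-replicate
null calibrations and 600 simulated proteins for the permutation-test
calibration — sizes at which every planted effect is resolvable against its
Monte-Carlo error while a full run stays within a coffee break on one CPU.
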