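"""Harmonisation of protein-disease records into group-labelled annotations.

Disease associations arrive from heterogeneous catalogues (ClinVar-, OMIM-,
UniProt- and HGMD-style tables) carrying MedGen ids, OMIM ids and/or free-text
disease names. Names are matched by an order-free bag-of-words rule; all
mappable records are converted to disease-ontology (DOID) terms, closed over
ancestors, and reduced to an independent antichain of the most specific terms.
Quaternary structure is classified from per-structure chain evidence with a
30-residue peptide-ligand cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .ontology import Ontology, ancestor_closure, independence_filter

__all__ = [
    "DiseaseRecord",
    "ProteinAnnotation",
    "StructureRecord",
    "QuaternaryEvidence",
    "normalize_disease_name",
    "build_name_index",
    "map_to_doid",
    "classify_quaternary",
    "assign_groups",
]

PEPTIDE_LIGAND_CUTOFF = 30  # chains shorter than this many residues are ligands


@dataclass(frozen=True)
class DiseaseRecord:
    protein_id: str
    source: str  # clinvar | omim | uniprot | hgmd | other
    medgen_ids: frozenset[str] = field(default_factory=frozenset)
    omim_ids: frozenset[str] = field(default_factory=frozenset)
    disease_names: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not (self.medgen_ids or self.omim_ids or self.disease_names):
            raise ValueError(
                f"record for {self.protein_id!r} carries no identifier or name"
            )


@dataclass
class ProteinAnnotation:
    protein_id: str
    allosteric: bool = False
    group: str = "other"  # allosteric | disease | other
    doid_full: frozenset[str] = field(default_factory=frozenset)
    doid_independent: frozenset[str] = field(default_factory=frozenset)
    quaternary: str = "unknown"  # heteromer | homomer | monomer | unknown
    drug_target: bool = False
    signaling: bool = False
    kinase_or_gpcr: bool = False

    @property
    def n_diseases(self) -> int:
        return len(self.doid_independent)


def normalize_disease_name(name: str) -> frozenset[str]:
    """Bag-of-words normal form: lowercase, commas removed, order-free tokens.

    Two names match iff their token sets are equal, so "Myopathy, congenital"
    and "congenital myopathy" collapse to the same key.
    """
    if not name or not name.strip():
        raise ValueError("disease name is empty")
    return frozenset(name.lower().replace(",", " ").split())


def build_name_index(doid_names: Mapping[str, str]) -> dict[frozenset[str], set[str]]:
    """Token-set -> DOID index from an id -> display-name mapping."""
    index: dict[frozenset[str], set[str]] = {}
    for doid, name in doid_names.items():
        if not name or not name.strip():
            continue
        index.setdefault(normalize_disease_name(name), set()).add(doid)
    return index


def _check_xref(xref: Mapping[str, str | set[str] | frozenset[str]], label: str) -> dict[str, frozenset[str]]:
    out: dict[str, frozenset[str]] = {}
    for key, val in xref.items():
        targets = frozenset([val]) if isinstance(val, str) else frozenset(val)
        out[key] = targets
    return out


def map_to_doid(
    records: Iterable[DiseaseRecord],
    medgen_xref: Mapping[str, str | frozenset[str] | set[str]],
    omim_xref: Mapping[str, str | frozenset[str] | set[str]],
    name_index: Mapping[frozenset[str], set[str]],
    ontology: Ontology,
) -> tuple[list[ProteinAnnotation], int]:
    """Map disease records to DOID terms and build per-protein annotations.

    For each protein, DOIDs found via MedGen ids, OMIM ids and normalised
    names are unioned; ``doid_full`` is the ancestor closure of that union and
    ``doid_independent`` the antichain after dropping higher-level terms on
    the same root-ward path. Proteins with no mappable term are excluded;
    the number excluded is returned alongside the annotations.
    """
    medgen = _check_xref(medgen_xref, "medgen")
    omim = _check_xref(omim_xref, "omim")
    per_protein: dict[str, set[str]] = {}
    for rec in records:
        hits = per_protein.setdefault(rec.protein_id, set())
        for mid in rec.medgen_ids:
            hits.update(medgen.get(mid, ()))
        for oid in rec.omim_ids:
            hits.update(omim.get(oid, ()))
        for name in rec.disease_names:
            hits.update(name_index.get(normalize_disease_name(name), ()))
    annotations: list[ProteinAnnotation] = []
    n_excluded = 0
    for pid in sorted(per_protein):
        direct = {t for t in per_protein[pid] if t in ontology}
        if not direct:
            n_excluded += 1
            continue
        full: set[str] = set()
        for t in direct:
            full.update(ancestor_closure(ontology, t))
        independent = independence_filter(ontology, direct)
        annotations.append(
            ProteinAnnotation(
                protein_id=pid,
                group="disease",
                doid_full=frozenset(full),
                doid_independent=independent,
            )
        )
    return annotations, n_excluded


def assign_groups(
    universe: Iterable[str],
    allosteric_ids: Iterable[str],
    disease_ids: Iterable[str],
) -> dict[str, str]:
    """Partition the proteome into allosteric > disease > other.

    Every protein belongs to exactly one group; allostery takes precedence
    over disease association, and the non-allosteric reference set is the
    full universe minus the allosteric set.
    """
    allo = set(allosteric_ids)
    dis = set(disease_ids)
    groups: dict[str, str] = {}
    for pid in universe:
        if pid in allo:
            groups[pid] = "allosteric"
        elif pid in dis:
            groups[pid] = "disease"
        else:
            groups[pid] = "other"
    return groups


@dataclass(frozen=True)
class StructureRecord:
    structure_id: str
    chain_lengths: tuple[int, ...]
    chain_accessions: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.chain_lengths) != len(self.chain_accessions):
            raise ValueError("one accession per chain required")
        if any(l <= 0 for l in self.chain_lengths):
            raise ValueError("chain lengths must be positive")


@dataclass(frozen=True)
class QuaternaryEvidence:
    protein_id: str
    structures: tuple[StructureRecord, ...]


def _classify_structure(struct: StructureRecord) -> str:
    kept = [
        acc
        for length, acc in zip(struct.chain_lengths, struct.chain_accessions)
        if length >= PEPTIDE_LIGAND_CUTOFF
    ]
    if not kept:
        raise ValueError(
            f"structure {struct.structure_id!r} has no chain left after "
            f"peptide-ligand filtering"
        )
    if len(set(kept)) >= 2:
        return "heteromer"
    return "homomer" if len(kept) >= 2 else "monomer"


def classify_quaternary(evidence: QuaternaryEvidence) -> str:
    """Heteromer / homomer / monomer from per-structure chain evidence.

    Chains shorter than 30 residues are peptide ligands and removed first.
    A protein is a heteromer if any structure retains >= 2 distinct
    accessions, else a homomer if any structure retains >= 2 chains of one
    accession, else a monomer.
    """
    if not evidence.structures:
        raise ValueError(f"no structures for {evidence.protein_id!r}")
    classes = {_classify_structure(s) for s in evidence.structures}
    if "heteromer" in classes:
        return "heteromer"
    if "homomer" in classes:
        return "homomer"
    return "monomer"
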