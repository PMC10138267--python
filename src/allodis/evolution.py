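"""Conservation scoring, orthogroup homolog classification, and PSC profiles.

Conservation of a human protein is the average of its pairwise similarities
with every non-primate partner in its orthogroup alignment, where a pairwise
similarity is the fraction of matching residues among mutually non-gapped
columns (primates are excluded so all partners share roughly the same
divergence time from human). Orthogroups classify human proteins relative to
allostery: orthologs of non-human allosteric proteins, paralogs of human
allosteric proteins, duplicated allosteric proteins, and a non-allosteric
reference set. Loss-of-function intolerance is profiled from premature stop
codon (PSC) variants: proteins with zero surviving PSCs are inactivation
intolerant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "AlignmentRow",
    "MultipleAlignment",
    "OrthogroupMember",
    "Orthogroup",
    "PscVariant",
    "PscProfile",
    "conservation_score",
    "classify_homologs",
    "psc_profile",
    "read_alignment_fasta",
]

GAP = "-"

# Broad physicochemical residue classes for the optional similarity mode.
_SIMILARITY_CLASSES = (
    "AGILPV",  # small / aliphatic
    "FWY",  # aromatic
    "CMST",  # polar, uncharged small
    "NQ",  # amide
    "DE",  # acidic
    "HKR",  # basic
)
_CLASS_OF = {aa: i for i, cls in enumerate(_SIMILARITY_CLASSES) for aa in cls}


@dataclass(frozen=True)
class AlignmentRow:
    sequence_id: str
    species: str
    sequence: str
    is_primate: bool = False
    is_human: bool = False


@dataclass
class MultipleAlignment:
    rows: list[AlignmentRow]

    def __post_init__(self) -> None:
        lengths = {len(r.sequence) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")

    def row(self, sequence_id: str) -> AlignmentRow:
        for r in self.rows:
            if r.sequence_id == sequence_id:
                return r
        raise KeyError(f"sequence {sequence_id!r} not in alignment")


def _pairwise_similarity(a: str, b: str, mode: str) -> float:
    n_aligned = 0
    n_match = 0
    for ra, rb in zip(a, b):
        if ra == GAP or rb == GAP:
            continue
        n_aligned += 1
        if ra == rb:
            n_match += 1
        elif mode == "class" and _CLASS_OF.get(ra) == _CLASS_OF.get(rb) is not None:
            n_match += 1
    if n_aligned == 0:
        return float("nan")
    return n_match / n_aligned


def conservation_score(
    msa: MultipleAlignment, focal_human_id: str, mode: str = "identity"
) -> float:
    """Mean pairwise similarity (percent) of a human protein with all
    non-primate partners of its orthogroup alignment.

    For each partner, the denominator is the columns where both rows are
    non-gapped and the numerator the matching residues (strict identity by
    default; ``mode="class"`` also counts physicochemically similar residues).
    """
    if mode not in ("identity", "class"):
        raise ValueError(f"unknown similarity mode {mode!r}")
    focal = msa.row(focal_human_id)
    if not focal.is_human:
        raise ValueError(f"focal row {focal_human_id!r} is not human")
    partners = [
        r
        for r in msa.rows
        if r.sequence_id != focal_human_id and not r.is_primate and not r.is_human
    ]
    if not partners:
        raise ValueError("no eligible non-primate partner in alignment")
    scores = [_pairwise_similarity(focal.sequence, p.sequence, mode) for p in partners]
    scores = [s for s in scores if s == s]  # drop NaN (no shared columns)
    if not scores:
        raise ValueError("no partner shares non-gapped columns with the focal row")
    return 100.0 * sum(scores) / len(scores)


@dataclass(frozen=True)
class OrthogroupMember:
    protein_id: str
    species: str
    is_human: bool
    allosteric: bool


@dataclass
class Orthogroup:
    group_id: str
    taxonomic_level: str  # mammals | vertebrates | metazoans | eukaryotes
    members: list[OrthogroupMember]
    lower_level_only: bool = False

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError(f"orthogroup {self.group_id!r} has fewer than 2 members")


ORTHOLOG = "ortholog_of_nonhuman_allosteric"
PARALOG = "paralog_of_human_allosteric"
DUPLICATED = "duplicated_allosteric"
REFERENCE = "reference_non_allosteric"
EXCLUDED = "excluded"


def classify_homologs(
    orthogroups: Sequence[Orthogroup],
    level: str,
    lower_level_orthologs: Iterable[str] = (),
) -> dict[str, str]:
    """Classify human proteins by their orthogroup's allostery content.

    Groups containing only proteins of the immediately lower taxonomic level
    are excluded wholesale. In an included group, a human non-allosteric
    member is a paralog when the group has a human allosteric member, an
    ortholog when it has only non-human allosteric members, and otherwise a
    reference candidate; a human allosteric member with a non-allosteric
    human co-member is a duplicated allosteric protein. Proteins named in
    ``lower_level_orthologs`` (orthologs of allosteric proteins already found
    at the lower taxonomic level) are removed from the reference set.
    """
    lower = set(lower_level_orthologs)
    classes: dict[str, str] = {}
    seen_in: dict[str, str] = {}
    for og in orthogroups:
        if og.taxonomic_level != level:
            continue
        for m in og.members:
            if not m.is_human:
                continue
            if m.protein_id in seen_in:
                raise ValueError(
                    f"protein {m.protein_id!r} appears in orthogroups "
                    f"{seen_in[m.protein_id]!r} and {og.group_id!r} at level {level!r}"
                )
            seen_in[m.protein_id] = og.group_id
        if og.lower_level_only:
            for m in og.members:
                if m.is_human:
                    classes[m.protein_id] = EXCLUDED
            continue
        has_human_allo = any(m.is_human and m.allosteric for m in og.members)
        has_nonhuman_allo = any((not m.is_human) and m.allosteric for m in og.members)
        has_human_nonallo = any(m.is_human and not m.allosteric for m in og.members)
        for m in og.members:
            if not m.is_human:
                continue
            if m.allosteric:
                classes[m.protein_id] = DUPLICATED if has_human_nonallo else EXCLUDED
            elif has_human_allo:
                classes[m.protein_id] = PARALOG
            elif has_nonhuman_allo:
                classes[m.protein_id] = ORTHOLOG
            elif m.protein_id in lower:
                classes[m.protein_id] = EXCLUDED
            else:
                classes[m.protein_id] = REFERENCE
    return classes


@dataclass(frozen=True)
class PscVariant:
    protein_id: str
    codon: int
    amino_change: str
    allele_frequency: float
    consequence: str
    passes_filters: bool


@dataclass
class PscProfile:
    protein_id: str
    length: int
    psc_count: int
    psc_density: float
    mean_allele_frequency: float
    intolerant: bool


def psc_profile(
    variants: Iterable[PscVariant],
    protein_lengths: Mapping[str, int],
    main_isoforms: Iterable[str] | None = None,
) -> dict[str, PscProfile]:
    """Per-protein premature-stop-codon profiles from exome variant rows.

    Variants are filtered to stop_gained consequences on main isoforms that
    pass all quality filters with allele frequency above zero; variants in
    the same codon producing the same amino-acid change merge into one PSC
    with their allele frequencies summed. Every protein with a known length
    receives a profile; a zero PSC count marks inactivation intolerance.
    """
    main = None if main_isoforms is None else set(main_isoforms)
    merged: dict[str, dict[tuple[int, str], float]] = {}
    for v in variants:
        if v.consequence != "stop_gained" or not v.passes_filters:
            continue
        if v.allele_frequency <= 0:
            continue
        if main is not None and v.protein_id not in main:
            continue
        if v.protein_id not in protein_lengths:
            raise KeyError(f"no length for protein {v.protein_id!r}")
        key = (v.codon, v.amino_change)
        per = merged.setdefault(v.protein_id, {})
        per[key] = per.get(key, 0.0) + v.allele_frequency
    profiles: dict[str, PscProfile] = {}
    for pid in sorted(protein_lengths):
        if main is not None and pid not in main:
            continue
        length = protein_lengths[pid]
        pscs = merged.get(pid, {})
        count = len(pscs)
        mean_af = sum(pscs.values()) / count if count else 0.0
        profiles[pid] = PscProfile(
            protein_id=pid,
            length=length,
            psc_count=count,
            psc_density=count / length,
            mean_allele_frequency=mean_af,
            intolerant=count == 0,
        )
    return profiles


def read_alignment_fasta(
    path: str,
    primate_species: Iterable[str],
    human_species: str = "homo_sapiens",
) -> MultipleAlignment:
    """Aligned FASTA with ``species|protein_id`` headers into an alignment."""
    from Bio import SeqIO

    primates = set(primate_species)
    rows: list[AlignmentRow] = []
    for rec in SeqIO.parse(path, "fasta"):
        species, _, pid = rec.id.partition("|")
        rows.append(
            AlignmentRow(
                sequence_id=pid or rec.id,
                species=species,
                sequence=str(rec.seq),
                is_primate=species in primates or species == human_species,
                is_human=species == human_species,
            )
        )
    return MultipleAlignment(rows=rows)
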