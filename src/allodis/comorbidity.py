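"""Per-protein comorbidity counts against a phenotype comorbidity network.

A protein's disease terms are expanded to all ancestors up to the ontology
root, converted to phenotype (MedGen-style) identifiers through a cross
reference table, and every unordered pair of the resulting phenotype ids is
checked against the comorbidity network; the count of pairs present is the
protein's comorbidity count. Only proteins associated with at least two
independent disease terms enter the analysis.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping

from .ontology import Ontology, ancestor_closure

__all__ = [
    "ComorbidityNetwork",
    "ComorbidityCount",
    "expand_and_convert",
    "count_comorbidities",
    "comorbidity_profile",
]


class ComorbidityNetwork:
    """Unordered phenotype-id pairs; self-pairs are rejected."""

    def __init__(self, pairs: Iterable[tuple[str, str]]):
        self._pairs: set[frozenset[str]] = set()
        for a, b in pairs:
            if a == b:
                raise ValueError(f"self-pair {a!r} not allowed")
            self._pairs.add(frozenset((a, b)))

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return frozenset(pair) in self._pairs

    def __len__(self) -> int:
        return len(self._pairs)


@dataclass
class ComorbidityCount:
    protein_id: str
    n_diseases: int
    phenotype_ids: frozenset[str]
    n_comorbid_pairs: int


def expand_and_convert(
    doid_set: Iterable[str],
    ontology: Ontology,
    doid_to_phenotype: Mapping[str, str | set[str] | frozenset[str]],
) -> tuple[frozenset[str], int]:
    """Ancestor-close a protein's DOIDs, then map each term to phenotype ids.

    One-to-many mappings expand to all targets; unmapped closure terms are
    skipped silently and counted. Returns (phenotype set, n skipped).
    """
    closure: set[str] = set()
    for doid in doid_set:
        closure.update(ancestor_closure(ontology, doid))
    phenotypes: set[str] = set()
    n_skipped = 0
    for term in closure:
        mapped = doid_to_phenotype.get(term)
        if mapped is None:
            n_skipped += 1
        elif isinstance(mapped, str):
            phenotypes.add(mapped)
        else:
            phenotypes.update(mapped)
    return frozenset(phenotypes), n_skipped


def count_comorbidities(
    phenotype_ids: Iterable[str], network: ComorbidityNetwork
) -> int:
    """Number of unordered phenotype-id pairs present in the network."""
    ids = sorted(set(phenotype_ids))
    return sum(
        1 for a, b in itertools.combinations(ids, 2) if (a, b) in network
    )


def comorbidity_profile(
    protein_doids: Mapping[str, frozenset[str]],
    ontology: Ontology,
    doid_to_phenotype: Mapping[str, str | set[str] | frozenset[str]],
    network: ComorbidityNetwork,
    min_diseases: int = 2,
) -> list[ComorbidityCount]:
    """Comorbidity counts for every protein with >= ``min_diseases`` terms.

    The minimum-disease filter applies to the independent DOID count,
    matching the protein set of the disease-network analysis.
    """
    out: list[ComorbidityCount] = []
    for pid in sorted(protein_doids):
        doids = protein_doids[pid]
        if len(doids) < min_diseases:
            continue
        phenos, _ = expand_and_convert(doids, ontology, doid_to_phenotype)
        out.append(
            ComorbidityCount(
                protein_id=pid,
                n_diseases=len(doids),
                phenotype_ids=phenos,
                n_comorbid_pairs=count_comorbidities(phenos, network),
            )
        )
    return out
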