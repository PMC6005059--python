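"""Asymmetric presence/absence inference over entity-quality annotations.

The rules mirror how ontology-aware phenotype aggregation works for skeletal
presence/absence characters:

Presence flows "upward":
  any non-absence quality on an entity E evidences the presence of E and of
  every whole/supertype reachable from E via ``part_of`` or ``is_a`` edges.
  Presence is never inferred across ``develops_from`` (a larval bud does not
  guarantee the adult structure) nor across ``depends_on`` (a girdle does not
  guarantee its fin).

Absence flows "downward":
  absence of W implies absence of every part of W (reverse ``part_of``), of
  every subtype of W (reverse ``is_a``), of everything that structurally
  requires W (reverse ``depends_on``; no fin without its girdle), and of
  everything that develops from W (reverse ``develops_from``; no adult fin
  without its larval bud). The closure is iterated to a fixpoint. Absence of
  a whole says nothing about sibling structures, and presence of a whole never
  implies presence of its parts.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .ontology import AnatomyGraph, DEPENDS_ON, DEVELOPS_FROM, IS_A, PART_OF
from .taxonomy import RANK_ORDER, Taxonomy

ABSENT = "absent"
PRESENT = "present"

ASSERTED = "asserted"
INFERRED = "inferred"
PROPAGATED = "propagated"

#: relations along which presence propagates, subject -> object direction
_PRESENCE_RELATIONS = (PART_OF, IS_A)
#: relations along which absence propagates, object -> subject direction
_ABSENCE_RELATIONS = (PART_OF, IS_A, DEPENDS_ON, DEVELOPS_FROM)


@dataclass(frozen=True)
class PhenotypeAnnotation:
    """A single entity-quality statement tied to a taxon.

    ``quality == "absent"`` encodes an absence statement; any other quality
    (including ``"present"``) is presence-implying. Inferred annotations carry
    a ``chain`` of (subject, relation, object) rule applications tracing the
    derivation back to the source annotation.
    """

    taxon: str
    entity: str
    quality: str
    provenance: str = ASSERTED
    study: str = ""
    chain: tuple[tuple[str, str, str], ...] = ()

    @property
    def is_absent(self) -> bool:
        return self.quality == ABSENT

    def __post_init__(self):
        if self.provenance == ASSERTED and not self.study:
            raise ValueError("asserted annotations must carry a study tag")


def infer_presence(
    annotations: Sequence[PhenotypeAnnotation], graph: AnatomyGraph
) -> list[PhenotypeAnnotation]:
    """Presence closure: new inferred PRESENT annotations.

    For each non-absence annotation on E, emits PRESENT for E and for every
    term reachable from E via ``part_of``/``is_a`` edges (followed subject to
    object). ``develops_from`` and ``depends_on`` are deliberately not
    followed: a precursor or a supporting structure is not evidence of the
    dependent structure.
    """
    new: list[PhenotypeAnnotation] = []
    seen: set[tuple[str, str]] = set()
    for ann in annotations:
        if ann.is_absent:
            continue
        if not graph.has_term(ann.entity):
            continue
        # BFS forward along presence-carrying relations, recording the chain
        frontier: list[tuple[str, tuple]] = [(ann.entity, ())]
        visited = {ann.entity}
        while frontier:
            term, chain = frontier.pop()
            key = (ann.taxon, term)
            if key not in seen:
                seen.add(key)
                new.append(
                    PhenotypeAnnotation(
                        taxon=ann.taxon,
                        entity=term,
                        quality=PRESENT,
                        provenance=INFERRED,
                        study=ann.study,
                        chain=chain,
                    )
                )
            for rel in _PRESENCE_RELATIONS:
                for nxt in graph.objects(term, rel):
                    if nxt not in visited:
                        visited.add(nxt)
                        frontier.append((nxt, chain + ((term, rel, nxt),)))
    return new


def infer_absence(
    annotations: Sequence[PhenotypeAnnotation], graph: AnatomyGraph
) -> list[PhenotypeAnnotation]:
    """Absence closure: new inferred ABSENT annotations (to fixpoint).

    Absence of X propagates to every Y with an edge (Y, r, X) for r in
    {part_of, is_a, depends_on, develops_from}: parts, subtypes, dependents,
    and developmental derivatives of an absent structure are absent.
    """
    new: list[PhenotypeAnnotation] = []
    seen: set[tuple[str, str]] = set()
    worklist: list[tuple[str, str, str, tuple]] = []  # (taxon, term, study, chain)
    for ann in annotations:
        if ann.is_absent and graph.has_term(ann.entity):
            worklist.append((ann.taxon, ann.entity, ann.study, ()))
            seen.add((ann.taxon, ann.entity))
    while worklist:
        taxon, term, study, chain = worklist.pop()
        for rel in _ABSENCE_RELATIONS:
            for dep in graph.subjects(term, rel):
                key = (taxon, dep)
                if key in seen:
                    continue
                seen.add(key)
                step = chain + ((dep, rel, term),)
                new.append(
                    PhenotypeAnnotation(
                        taxon=taxon,
                        entity=dep,
                        quality=ABSENT,
                        provenance=INFERRED,
                        study=study,
                        chain=step,
                    )
                )
                worklist.append((taxon, dep, study, step))
    return new


def close_annotations(
    annotations: Sequence[PhenotypeAnnotation], graph: AnatomyGraph
) -> list[PhenotypeAnnotation]:
    """Input annotations plus the full presence+absence inference closure.

    Inferred annotations that duplicate an existing (taxon, entity, polarity)
    statement are dropped. Rerunning on the output adds nothing (fixpoint).
    """
    existing = {(a.taxon, a.entity, a.is_absent) for a in annotations}
    out = list(annotations)
    for ann in infer_presence(annotations, graph) + infer_absence(annotations, graph):
        key = (ann.taxon, ann.entity, ann.is_absent)
        if key not in existing:
            existing.add(key)
            out.append(ann)
    return out


# ---------------------------------------------------------------------------
# conflict detection


TRUE_POLYMORPHISM = "true_polymorphism"
APPARENT_POLYMORPHISM = "apparent_polymorphism"
ASSERT_VS_INFER = "assert_vs_infer_conflict"


@dataclass(frozen=True)
class Conflict:
    taxon: str
    character: str
    category: str
    presence_support: tuple[PhenotypeAnnotation, ...]
    absence_support: tuple[PhenotypeAnnotation, ...]


@dataclass
class ConflictReport:
    conflicts: list[Conflict] = field(default_factory=list)

    def for_category(self, category: str) -> list[Conflict]:
        return [c for c in self.conflicts if c.category == category]

    def taxa(self) -> set[str]:
        return {c.taxon for c in self.conflicts}

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["taxon", "character", "category", "n_presence", "n_absence"])
            for c in self.conflicts:
                w.writerow(
                    [c.taxon, c.character, c.category,
                     len(c.presence_support), len(c.absence_support)]
                )


def character_support(
    annotations: Sequence[PhenotypeAnnotation],
    character: str,
    graph: AnatomyGraph,
) -> tuple[list[PhenotypeAnnotation], list[PhenotypeAnnotation]]:
    """Annotations implying presence / absence of ``character`` for one taxon.

    A character cell aggregates annotations whose entity is the character term
    itself or any ``is_a`` descendant of it; part-level statements contribute
    only via the inference closure.
    """
    terms = {character} | graph.isa_descendants(character)
    pres = [a for a in annotations if a.entity in terms and not a.is_absent]
    absn = [a for a in annotations if a.entity in terms and a.is_absent]
    return pres, absn


def detect_conflicts(
    annotations: Sequence[PhenotypeAnnotation],
    taxonomy: Taxonomy,
    characters: Sequence[str],
    graph: AnatomyGraph,
) -> ConflictReport:
    """Classify every taxon-character with both implied states.

    * both states asserted at species rank  -> true polymorphism
    * any both-states record above species  -> apparent polymorphism
    * otherwise (species rank, at least one side inferred-only)
                                            -> assertion-vs-inference conflict
    """
    by_taxon: dict[str, list[PhenotypeAnnotation]] = {}
    for a in annotations:
        by_taxon.setdefault(a.taxon, []).append(a)
    report = ConflictReport()
    for taxon, anns in sorted(by_taxon.items()):
        if taxon not in taxonomy:
            continue
        above_species = RANK_ORDER.get(taxonomy.rank(taxon), 99) > RANK_ORDER["species"]
        for char in characters:
            pres, absn = character_support(anns, char, graph)
            if not pres or not absn:
                continue
            if above_species:
                category = APPARENT_POLYMORPHISM
            elif any(a.provenance == ASSERTED for a in pres) and any(
                a.provenance == ASSERTED for a in absn
            ):
                category = TRUE_POLYMORPHISM
            else:
                category = ASSERT_VS_INFER
            report.conflicts.append(
                Conflict(taxon, char, category, tuple(pres), tuple(absn))
            )
    return report


# ---------------------------------------------------------------------------
# IO

ANNOTATION_COLUMNS = ("taxon_id", "entity_id", "quality", "study", "provenance")


def write_annotations(
    annotations: Sequence[PhenotypeAnnotation], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(ANNOTATION_COLUMNS)
        for a in annotations:
            w.writerow([a.taxon, a.entity, a.quality, a.study, a.provenance])


def read_annotations(path: str | Path) -> list[PhenotypeAnnotation]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(
                PhenotypeAnnotation(
                    taxon=row["taxon_id"],
                    entity=row["entity_id"],
                    quality=row["quality"],
                    study=row.get("study", ""),
                    provenance=row.get("provenance", ASSERTED) or ASSERTED,
                )
            )
    return out
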