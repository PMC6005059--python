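"""Taxonomic data propagation: genus/family states flow down to species.

States recorded for a genus or family are copied to each member species that
lacks its own value for that character. Existing species data — asserted,
inferred, polymorphic, or conflicted — are never replaced; blocked overwrites
are logged, with a conflict category when the propagated state disagrees.
Ranks above family are ignored, and after propagation all non-species rows are
removed, yielding a species-only matrix.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .matrix import Cell, POLYMORPHIC, Supermatrix
from .taxonomy import Taxonomy

PROPAGATION_RANKS = ("genus", "family")  # nearest ancestor wins


@dataclass(frozen=True)
class PropagationEntry:
    species: str
    character: str
    source_taxon: str
    source_rank: str
    symbol: str
    source_class: str  # "asserted" (0/1) or "inferred" (2/3)
    new_row: bool = True  # species row did not exist before propagation


@dataclass(frozen=True)
class BlockedEntry:
    species: str
    character: str
    source_taxon: str
    source_rank: str
    proposed_symbol: str
    existing_symbol: str
    conflict_with: Optional[str]  # "asserted"/"inferred"/None if states agree


@dataclass
class PropagationLog:
    applied: list[PropagationEntry] = field(default_factory=list)
    blocked: list[BlockedEntry] = field(default_factory=list)
    precedence_conflicts: list[tuple[str, str, str, str]] = field(
        default_factory=list
    )  # (species, character, genus_source, family_source)
    uninformative_sources: list[tuple[str, str]] = field(default_factory=list)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(
                ["species", "character", "source_taxon", "source_rank",
                 "symbol", "source_class", "blocked", "conflict_with"]
            )
            for e in self.applied:
                w.writerow([e.species, e.character, e.source_taxon,
                            e.source_rank, e.symbol, e.source_class, "0", ""])
            for b in self.blocked:
                w.writerow([b.species, b.character, b.source_taxon,
                            b.source_rank, b.proposed_symbol, "", "1",
                            b.conflict_with or ""])


@dataclass
class PropagationSummary:
    species_added: int
    cells_propagated: int
    contributing_families: int
    contributing_genera: int
    per_character_from_asserted: dict[str, int]
    per_character_from_inferred: dict[str, int]
    conflicts_with_asserted: int
    conflicts_with_inferred: int

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["statistic", "value"])
            w.writerow(["species_added", self.species_added])
            w.writerow(["cells_propagated", self.cells_propagated])
            w.writerow(["contributing_families", self.contributing_families])
            w.writerow(["contributing_genera", self.contributing_genera])
            for c, n in self.per_character_from_asserted.items():
                w.writerow([f"{c}_from_asserted", n])
            for c, n in self.per_character_from_inferred.items():
                w.writerow([f"{c}_from_inferred", n])
            w.writerow(["conflicts_with_asserted", self.conflicts_with_asserted])
            w.writerow(["conflicts_with_inferred", self.conflicts_with_inferred])


def _source_class(symbol: str) -> str:
    return "asserted" if symbol in ("0", "1") else "inferred"


def _provenance_class(cell: Cell) -> str:
    """Classify an existing species cell for conflict bookkeeping."""
    if cell.symbol in ("0", "1") or cell.asserted_present or cell.asserted_absent:
        return "asserted"
    return "inferred"


def propagate(
    matrix: Supermatrix, taxonomy: Taxonomy
) -> tuple[Supermatrix, PropagationLog]:
    """Propagate genus/family states to member species; return species-only matrix.

    Precedence: when both the genus and the family carry data for a character,
    the nearest ancestor (genus) wins and the disagreement is logged. ``?``
    cells propagate nothing. Both-states (0&1) higher-level cells should have
    been scrubbed already; if one survives it propagates nothing and is logged.
    """
    for taxon in matrix.taxa():
        if taxon not in taxonomy:
            raise KeyError(f"matrix taxon {taxon!r} missing from taxonomy")

    log = PropagationLog()
    out = Supermatrix(matrix.characters)

    # existing species rows carry over untouched
    species_rows = [t for t in matrix.taxa() if taxonomy.is_species(t)]
    for sp in species_rows:
        for char in matrix.characters:
            out.set_cell(sp, char, matrix.cell(sp, char))

    # index propagable higher-level cells by (rank, taxon)
    higher_cells: dict[str, dict[str, Cell]] = {}
    for taxon in matrix.taxa():
        rank = taxonomy.rank(taxon)
        if rank not in PROPAGATION_RANKS:
            continue
        for char in matrix.characters:
            cell = matrix.cell(taxon, char)
            if not cell.populated:
                continue
            if cell.symbol == POLYMORPHIC:
                log.uninformative_sources.append((taxon, char))
                continue
            higher_cells.setdefault(taxon, {})[char] = cell

    new_species: set[str] = set()
    # nearest ancestor wins: all genus-level sources apply before any family
    ordered = sorted(higher_cells, key=lambda t: (taxonomy.rank(t) != "genus", t))
    for source in ordered:
        char_cells = higher_cells[source]
        rank = taxonomy.rank(source)
        for sp in taxonomy.species_under(source):
            for char, source_cell in char_cells.items():
                existing = out.cell(sp, char)
                if existing.populated:
                    if sp in matrix.rows and matrix.cell(sp, char).populated:
                        src_states = source_cell.implied_states()
                        ex_states = existing.implied_states()
                        conflict = (
                            _provenance_class(existing)
                            if src_states and ex_states and not (src_states & ex_states)
                            else None
                        )
                        log.blocked.append(
                            BlockedEntry(sp, char, source, rank,
                                         source_cell.symbol, existing.symbol,
                                         conflict)
                        )
                    elif (
                        rank == "family"
                        and existing.propagated_from is not None
                        and existing.symbol != source_cell.symbol
                    ):
                        # genus already filled the cell with a different state
                        log.precedence_conflicts.append(
                            (sp, char, existing.propagated_from, source)
                        )
                    continue
                out.set_cell(
                    sp,
                    char,
                    Cell(symbol=source_cell.symbol, propagated_from=source),
                )
                is_new = sp not in matrix.rows
                if is_new:
                    new_species.add(sp)
                log.applied.append(
                    PropagationEntry(sp, char, source, rank,
                                     source_cell.symbol,
                                     _source_class(source_cell.symbol),
                                     new_row=is_new)
                )

    # drop rows with no populated cells (added species always have one)
    empty = [t for t in out.taxa()
             if not any(out.cell(t, c).populated for c in out.characters)]
    for t in empty:
        del out.rows[t]
    return out, log


def propagation_summary(
    log: PropagationLog, characters: Optional[list[str]] = None
) -> PropagationSummary:
    chars = characters or sorted({e.character for e in log.applied})
    sources = {(e.source_taxon, e.source_rank) for e in log.applied}
    from_asserted = {c: 0 for c in chars}
    from_inferred = {c: 0 for c in chars}
    for e in log.applied:
        if e.source_class == "asserted":
            from_asserted[e.character] = from_asserted.get(e.character, 0) + 1
        else:
            from_inferred[e.character] = from_inferred.get(e.character, 0) + 1
    return PropagationSummary(
        species_added=len({e.species for e in log.applied if e.new_row}),
        cells_propagated=len(log.applied),
        contributing_families=sum(1 for _, r in sources if r == "family"),
        contributing_genera=sum(1 for _, r in sources if r == "genus"),
        per_character_from_asserted=from_asserted,
        per_character_from_inferred=from_inferred,
        conflicts_with_asserted=sum(
            1 for b in log.blocked if b.conflict_with == "asserted"
        ),
        conflicts_with_inferred=sum(
            1 for b in log.blocked if b.conflict_with == "inferred"
        ),
    )
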