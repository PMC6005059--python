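"""Presence/absence supermatrix with per-cell provenance.

Cell symbols follow the convention used for provenance-aware synthetic
supermatrices:

==========  =====================================================
symbol      meaning
==========  =====================================================
``0``       asserted absent
``1``       asserted present (even if also supported by inference)
``2``       inferred-only present
``3``       inferred-only absent (rare; produced and logged)
``0&1``     both states supported (polymorphism or conflict)
``?``       no data
==========  =====================================================
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import dendropy

from .inference import (
    ASSERTED,
    INFERRED,
    PROPAGATED,
    PhenotypeAnnotation,
    character_support,
)
from .ontology import AnatomyGraph
from .taxonomy import RANK_ORDER, Taxonomy

logger = logging.getLogger(__name__)

MISSING = "?"
POLYMORPHIC = "0&1"
SYMBOLS = ("0", "1", "2", "3", POLYMORPHIC, MISSING)

FLAG_CONFLICT = "conflict"
FLAG_POLYMORPHISM = "polymorphism"
FLAG_PROVENANCE_UNKNOWN = "provenance_unknown"


@dataclass
class Cell:
    """One matrix cell: coded symbol plus its supporting annotations."""

    symbol: str = MISSING
    asserted_present: tuple[PhenotypeAnnotation, ...] = ()
    inferred_present: tuple[PhenotypeAnnotation, ...] = ()
    asserted_absent: tuple[PhenotypeAnnotation, ...] = ()
    inferred_absent: tuple[PhenotypeAnnotation, ...] = ()
    propagated_from: Optional[str] = None
    flags: frozenset[str] = frozenset()

    @property
    def populated(self) -> bool:
        return self.symbol != MISSING

    def implied_states(self) -> frozenset[int]:
        """Binary states implied by the symbol (1 = present, 0 = absent)."""
        return {
            "0": frozenset({0}),
            "1": frozenset({1}),
            "2": frozenset({1}),
            "3": frozenset({0}),
            POLYMORPHIC: frozenset({0, 1}),
            MISSING: frozenset(),
        }[self.symbol]


class Supermatrix:
    """taxa x characters grid of provenance-tagged presence/absence cells."""

    def __init__(self, characters: Sequence[str]):
        self.characters = list(characters)
        self.rows: dict[str, dict[str, Cell]] = {}

    def __contains__(self, taxon: str) -> bool:
        return taxon in self.rows

    def taxa(self) -> list[str]:
        return list(self.rows)

    def cell(self, taxon: str, character: str) -> Cell:
        return self.rows.get(taxon, {}).get(character, Cell())

    def set_cell(self, taxon: str, character: str, cell: Cell) -> None:
        if character not in self.characters:
            raise KeyError(f"unknown character {character!r}")
        self.rows.setdefault(
            taxon, {c: Cell() for c in self.characters}
        )[character] = cell

    def populated_count(self, character: Optional[str] = None) -> int:
        chars = [character] if character else self.characters
        return sum(
            1
            for row in self.rows.values()
            for c in chars
            if row[c].populated
        )

    def copy(self) -> "Supermatrix":
        out = Supermatrix(self.characters)
        for taxon, row in self.rows.items():
            out.rows[taxon] = dict(row)
        return out

    # -- IO ------------------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        """Native TSV: symbol column + flags column per character.

        Flags serialize the conflict/polymorphism markers and the propagation
        source so that write-then-read is the identity on symbols and flags.
        """
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            header = ["taxon_id"]
            for c in self.characters:
                header += [c, f"{c}__flags"]
            w.writerow(header)
            for taxon in sorted(self.rows):
                row = [taxon]
                for c in self.characters:
                    cell = self.rows[taxon][c]
                    flags = sorted(cell.flags)
                    if cell.propagated_from:
                        flags.append(f"from:{cell.propagated_from}")
                    row += [cell.symbol, ";".join(flags)]
                w.writerow(row)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Supermatrix":
        with open(path, newline="") as fh:
            reader = csv.reader(fh, delimiter="\t")
            header = next(reader)
            characters = [h for h in header[1:] if not h.endswith("__flags")]
            mat = cls(characters)
            for row in reader:
                taxon = row[0]
                for i, c in enumerate(characters):
                    symbol = row[1 + 2 * i]
                    raw_flags = row[2 + 2 * i]
                    flags = set()
                    source = None
                    for f in filter(None, raw_flags.split(";")):
                        if f.startswith("from:"):
                            source = f[5:]
                        else:
                            flags.add(f)
                    mat.set_cell(
                        taxon,
                        c,
                        Cell(symbol=symbol, propagated_from=source,
                             flags=frozenset(flags)),
                    )
        return mat

    def write_nexus(
        self, path: str | Path, tree: Optional[dendropy.Tree] = None
    ) -> None:
        """NEXUS export (symbols ``0 1 2``, polymorphism ``{0 1}``, missing ``?``).

        Symbol ``3`` is exported as ``0`` (it implies absence) with a warning.
        If ``tree`` is given, a TREES block is appended, producing a single
        merged tree+characters file.
        """
        taxa = sorted(self.rows)
        lines = ["#NEXUS", "", "BEGIN TAXA;", f"\tDIMENSIONS NTAX={len(taxa)};"]
        labels = [t.replace(" ", "_") for t in taxa]
        lines.append("\tTAXLABELS " + " ".join(labels) + ";")
        lines += ["END;", "", "BEGIN CHARACTERS;",
                  f"\tDIMENSIONS NCHAR={len(self.characters)};",
                  '\tFORMAT SYMBOLS="0 1 2" MISSING=? GAP=-;',
                  "\tMATRIX"]
        for taxon, label in zip(taxa, labels):
            coded = []
            for c in self.characters:
                cell = self.rows[taxon][c]
                symbol = cell.symbol
                if symbol == "3":
                    logger.warning(
                        "NEXUS export: inferred-only absence for %s/%s written as 0",
                        taxon, c,
                    )
                    symbol = "0"
                if symbol == POLYMORPHIC:
                    symbol = "{0 1}"
                if FLAG_CONFLICT in cell.flags:
                    symbol = MISSING
                coded.append(symbol)
            lines.append(f"\t{label}\t" + "".join(coded))
        lines += ["\t;", "END;"]
        if tree is not None:
            newick = tree.as_string(schema="newick", suppress_rooting=True).strip()
            lines += ["", "BEGIN TREES;", f"\tTREE merged = [&R] {newick}", "END;"]
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# assembly


def assemble(
    annotations: Sequence[PhenotypeAnnotation],
    characters: Sequence[str],
    taxonomy: Taxonomy,
    graph: AnatomyGraph,
) -> Supermatrix:
    """Build the supermatrix from the (closed) annotation set.

    One row per annotated taxon, any rank. A character cell aggregates all
    annotations whose entity equals the character term or an ``is_a``
    descendant of it. Cells with an author assertion are coded 0/1 even when
    the same state is also inferred; inference-only cells are coded 2 (or the
    reserved 3 for inferred-only absence, which is logged); both-states cells
    are coded 0&1.
    """
    by_taxon: dict[str, list[PhenotypeAnnotation]] = {}
    for a in annotations:
        by_taxon.setdefault(a.taxon, []).append(a)
    mat = Supermatrix(characters)
    for taxon in sorted(by_taxon):
        if taxon not in taxonomy:
            raise KeyError(f"annotated taxon {taxon!r} missing from taxonomy")
        row_used = False
        cells = {}
        for char in characters:
            pres, absn = character_support(by_taxon[taxon], char, graph)
            ap = tuple(a for a in pres if a.provenance == ASSERTED)
            ip = tuple(a for a in pres if a.provenance == INFERRED)
            aa = tuple(a for a in absn if a.provenance == ASSERTED)
            ia = tuple(a for a in absn if a.provenance == INFERRED)
            if pres and absn:
                symbol = POLYMORPHIC
            elif pres:
                symbol = "1" if ap else "2"
            elif absn:
                if aa:
                    symbol = "0"
                else:
                    symbol = "3"
                    logger.warning(
                        "inferred-only absence coded 3 for %s/%s", taxon, char
                    )
            else:
                symbol = MISSING
            if symbol != MISSING:
                row_used = True
            cells[char] = Cell(
                symbol=symbol,
                asserted_present=ap,
                inferred_present=ip,
                asserted_absent=aa,
                inferred_absent=ia,
            )
        if row_used:
            for char, cell in cells.items():
                mat.set_cell(taxon, char, cell)
    return mat


# ---------------------------------------------------------------------------
# scrubbing


@dataclass
class ScrubLog:
    replaced_by_rank: dict[str, int] = field(default_factory=dict)
    species_polymorphisms: list[tuple[str, str]] = field(default_factory=list)
    species_conflicts: list[tuple[str, str]] = field(default_factory=list)


def scrub_apparent_polymorphisms(
    matrix: Supermatrix, taxonomy: Taxonomy
) -> tuple[Supermatrix, ScrubLog]:
    """Replace higher-than-species both-states cells with ``?``.

    Both-states records on genus/family/order rows are apparent polymorphisms:
    the member species carrying each state are unidentified, so the record is
    uninformative for species-level reconstruction and is dropped. Species-rank
    both-states cells are kept (they survive propagation untouched) and flagged
    as true polymorphisms (both states asserted) or assertion-vs-inference
    conflicts (at least one side inference-only).
    """
    out = matrix.copy()
    log = ScrubLog()
    for taxon in matrix.taxa():
        rank = taxonomy.rank(taxon) if taxon in taxonomy else "species"
        above_species = RANK_ORDER.get(rank, 99) > RANK_ORDER["species"]
        for char in matrix.characters:
            cell = matrix.cell(taxon, char)
            if cell.symbol != POLYMORPHIC:
                continue
            if above_species:
                out.set_cell(taxon, char, Cell(symbol=MISSING))
                log.replaced_by_rank[rank] = log.replaced_by_rank.get(rank, 0) + 1
            else:
                if cell.asserted_present and cell.asserted_absent:
                    flag = FLAG_POLYMORPHISM
                    log.species_polymorphisms.append((taxon, char))
                else:
                    flag = FLAG_CONFLICT
                    log.species_conflicts.append((taxon, char))
                new = Cell(
                    symbol=cell.symbol,
                    asserted_present=cell.asserted_present,
                    inferred_present=cell.inferred_present,
                    asserted_absent=cell.asserted_absent,
                    inferred_absent=cell.inferred_absent,
                    propagated_from=cell.propagated_from,
                    flags=cell.flags | {flag},
                )
                out.set_cell(taxon, char, new)
    return out, log


# ---------------------------------------------------------------------------
# missing-data statistics


@dataclass
class MissingDataStats:
    populated_per_character: dict[str, int]
    total_populated: int
    denominator: int
    percent_missing: float
    denominator_convention: str


def percent_missing(populated: int, denominator: int) -> float:
    """100 * (1 - populated/denominator)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return 100.0 * (1.0 - populated / denominator)


def missing_stats(
    matrix: Supermatrix,
    denominator: int,
    convention: str = "final_species_set",
) -> MissingDataStats:
    """Missing-data accounting under an explicit denominator convention.

    The denominator is explicit because two conventions are in use: total
    cells over the species retained in the final matrix, or total cells over
    the full tree tip set after merge.
    """
    per_char = {c: matrix.populated_count(c) for c in matrix.characters}
    total = sum(per_char.values())
    pct = percent_missing(total, denominator)
    return MissingDataStats(per_char, total, denominator, pct, convention)
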