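"""Rank-annotated taxonomy with optional external (NCBI-style) cross-references.

The taxonomy is a rooted tree of taxon records spanning (at least) the ranks
family, genus, and species, mirroring the structure of curated vertebrate
taxonomies used to anchor phenotype annotations. Higher ranks (order and
above) are permitted but play no role in data propagation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional

#: canonical ordering used to compare ranks; larger = more inclusive
RANK_ORDER = {
    "species": 0,
    "genus": 1,
    "family": 2,
    "order": 3,
    "class": 4,
    "root": 5,
}


@dataclass
class TaxonRecord:
    """One taxon: identifier, name, rank, parent link, optional metadata."""

    id: str
    name: str
    rank: str
    parent_id: Optional[str] = None
    ncbi_id: Optional[int] = None
    extinct: bool = False


class TaxonomyError(ValueError):
    pass


class Taxonomy:
    """Indexed collection of :class:`TaxonRecord` forming a rooted tree."""

    def __init__(self, records: Iterable[TaxonRecord]):
        self._records: dict[str, TaxonRecord] = {}
        self._children: dict[str, list[str]] = {}
        for rec in records:
            if rec.id in self._records:
                raise TaxonomyError(f"duplicate taxon id {rec.id!r}")
            self._records[rec.id] = rec
        roots = []
        for rec in self._records.values():
            if rec.parent_id is None:
                roots.append(rec.id)
            else:
                if rec.parent_id not in self._records:
                    raise TaxonomyError(
                        f"taxon {rec.id!r} has unknown parent {rec.parent_id!r}"
                    )
                self._children.setdefault(rec.parent_id, []).append(rec.id)
        if len(roots) != 1:
            raise TaxonomyError(f"taxonomy must have exactly one root, got {len(roots)}")
        self.root_id = roots[0]
        self._by_name: dict[str, list[str]] = {}
        for rec in self._records.values():
            self._by_name.setdefault(rec.name, []).append(rec.id)

    # -- lookups -----------------------------------------------------------

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self._records

    def __iter__(self) -> Iterator[TaxonRecord]:
        return iter(self._records.values())

    def __len__(self) -> int:
        return len(self._records)

    def get(self, taxon_id: str) -> TaxonRecord:
        return self._records[taxon_id]

    def rank(self, taxon_id: str) -> str:
        return self._records[taxon_id].rank

    def name(self, taxon_id: str) -> str:
        return self._records[taxon_id].name

    def ids_by_name(self, name: str) -> list[str]:
        return list(self._by_name.get(name, []))

    def children(self, taxon_id: str) -> list[str]:
        return list(self._children.get(taxon_id, []))

    def parent(self, taxon_id: str) -> Optional[str]:
        return self._records[taxon_id].parent_id

    def ancestors(self, taxon_id: str) -> list[str]:
        """Ancestor ids from immediate parent up to the root."""
        out = []
        cur = self._records[taxon_id].parent_id
        while cur is not None:
            out.append(cur)
            cur = self._records[cur].parent_id
        return out

    def ancestor_at_rank(self, taxon_id: str, rank: str) -> Optional[str]:
        if self.rank(taxon_id) == rank:
            return taxon_id
        for anc in self.ancestors(taxon_id):
            if self.rank(anc) == rank:
                return anc
        return None

    def is_species(self, taxon_id: str) -> bool:
        return self.rank(taxon_id) == "species"

    def species_under(self, taxon_id: str) -> list[str]:
        """All species-rank descendants of ``taxon_id`` (inclusive if species)."""
        out = []
        stack = [taxon_id]
        while stack:
            cur = stack.pop()
            if self.is_species(cur):
                out.append(cur)
            stack.extend(self._children.get(cur, []))
        return sorted(out)

    def species_ids(self) -> list[str]:
        return [r.id for r in self._records.values() if r.rank == "species"]

    # -- IO ----------------------------------------------------------------

    COLUMNS = ("taxon_id", "name", "rank", "parent_id", "ncbi_id", "extinct")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(self.COLUMNS)
            for rec in self._records.values():
                writer.writerow(
                    [
                        rec.id,
                        rec.name,
                        rec.rank,
                        rec.parent_id or "",
                        "" if rec.ncbi_id is None else rec.ncbi_id,
                        "1" if rec.extinct else "0",
                    ]
                )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Taxonomy":
        records = []
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for row in reader:
                records.append(
                    TaxonRecord(
                        id=row["taxon_id"],
                        name=row["name"],
                        rank=row["rank"],
                        parent_id=row["parent_id"] or None,
                        ncbi_id=int(row["ncbi_id"]) if row["ncbi_id"] else None,
                        extinct=row["extinct"] == "1",
                    )
                )
        return cls(records)

    def xref_table(self) -> dict[str, Optional[int]]:
        """taxon_id -> NCBI-style integer cross-reference (or None)."""
        return {r.id: r.ncbi_id for r in self._records.values()}
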