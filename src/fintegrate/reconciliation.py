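"""Taxon-name reconciliation between matrix species and tree tip labels.

Two passes: first pair taxa that share an external (NCBI-style) identifier,
then pair the remainder by normalized exact binomial equality. Normalization
turns underscores into spaces, collapses whitespace, and strips any
subspecies epithet; matching is case-sensitive after normalization. Ambiguous
candidates (one name shared by several tips, or duplicate identifiers on one
side) are never matched, only flagged.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

from .taxonomy import Taxonomy

METHOD_ID = "id"
METHOD_NAME = "exact_name"

CATEGORY_FOSSIL = "fossil"
CATEGORY_UNCONVENTIONAL = "unconventional_name"
CATEGORY_OTHER = "other"

_BINOMIAL_RE = re.compile(r"^[A-Z][a-z]+ [a-z][a-z-]*$")


def normalize_name(name: str) -> str:
    """Underscores to spaces, collapse whitespace, drop subspecies epithets.

    Only trailing tokens that look like real epithets (lowercase alphabetic,
    at least two characters) are treated as subspecies names; short mangled
    suffixes are kept so that perturbed labels stay distinguishable.
    """
    cleaned = " ".join(name.replace("_", " ").split())
    parts = cleaned.split(" ")
    if len(parts) > 2 and all(
        p.isalpha() and p.islower() and len(p) >= 2 for p in parts[2:]
    ):
        parts = parts[:2]
    return " ".join(parts)


@dataclass(frozen=True)
class Match:
    taxon_id: str
    tip_label: str
    method: str


@dataclass
class ReconciliationReport:
    matches: list[Match] = field(default_factory=list)
    unmatched_taxa: dict[str, str] = field(default_factory=dict)  # id -> category
    unmatched_tips: list[str] = field(default_factory=list)
    flagged: list[str] = field(default_factory=list)  # human-readable notes

    def matched_taxa(self) -> set[str]:
        return {m.taxon_id for m in self.matches}

    def matched_tips(self) -> set[str]:
        return {m.tip_label for m in self.matches}

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["record", "taxon_id", "tip_label", "method_or_category"])
            for m in self.matches:
                w.writerow(["match", m.taxon_id, m.tip_label, m.method])
            for taxon, cat in sorted(self.unmatched_taxa.items()):
                w.writerow(["unmatched_taxon", taxon, "", cat])
            for tip in sorted(self.unmatched_tips):
                w.writerow(["unmatched_tip", "", tip, ""])
            for note in self.flagged:
                w.writerow(["flag", "", "", note])


def reconcile(
    matrix_taxa: Mapping[str, str],
    tip_labels: Sequence[str],
    taxon_xrefs: Optional[Mapping[str, Optional[int]]] = None,
    tip_xrefs: Optional[Mapping[str, Optional[int]]] = None,
) -> ReconciliationReport:
    """Match matrix taxa (id -> name) to tree tip labels.

    Pass 1 pairs taxa and tips sharing an external identifier; a taxon matched
    here is excluded from pass 2, and an ID match beats a conflicting name
    match (the discrepancy is flagged). Pass 2 pairs the remainder on
    normalized exact name equality. The mapping is injective in both
    directions; duplicate IDs or homonymous labels on either side are flagged,
    never matched.
    """
    taxon_xrefs = taxon_xrefs or {}
    tip_xrefs = tip_xrefs or {}
    report = ReconciliationReport()
    # deterministic regardless of input order
    taxa = sorted(matrix_taxa)
    tips = sorted(set(tip_labels))

    # duplicate-label tips (homonyms) are never matched
    label_counts: dict[str, int] = {}
    for label in tip_labels:
        label_counts[label] = label_counts.get(label, 0) + 1
    homonyms = {l for l, c in label_counts.items() if c > 1}
    for l in sorted(homonyms):
        report.flagged.append(f"homonymous tip label never matched: {l}")

    matched_taxa: dict[str, Match] = {}
    matched_tips: set[str] = set()

    # -- pass 1: external identifiers
    ids_taxa: dict[int, list[str]] = {}
    for t in taxa:
        x = taxon_xrefs.get(t)
        if x is not None:
            ids_taxa.setdefault(x, []).append(t)
    ids_tips: dict[int, list[str]] = {}
    for tip in tips:
        if tip in homonyms:
            continue
        x = tip_xrefs.get(tip)
        if x is not None:
            ids_tips.setdefault(x, []).append(tip)
    for x in sorted(set(ids_taxa) & set(ids_tips)):
        if len(ids_taxa[x]) > 1 or len(ids_tips[x]) > 1:
            report.flagged.append(f"duplicate external id {x}; not matched")
            continue
        taxon, tip = ids_taxa[x][0], ids_tips[x][0]
        matched_taxa[taxon] = Match(taxon, tip, METHOD_ID)
        matched_tips.add(tip)

    # -- pass 2: normalized exact names among the remainder
    names_taxa: dict[str, list[str]] = {}
    for t in taxa:
        if t in matched_taxa:
            continue
        names_taxa.setdefault(normalize_name(matrix_taxa[t]), []).append(t)
    names_tips: dict[str, list[str]] = {}
    for tip in tips:
        if tip in matched_tips or tip in homonyms:
            continue
        names_tips.setdefault(normalize_name(tip), []).append(tip)
    for name in sorted(set(names_taxa) & set(names_tips)):
        if len(names_taxa[name]) > 1 or len(names_tips[name]) > 1:
            report.flagged.append(f"ambiguous name {name!r}; not matched")
            continue
        taxon, tip = names_taxa[name][0], names_tips[name][0]
        matched_taxa[taxon] = Match(taxon, tip, METHOD_NAME)
        matched_tips.add(tip)

    # pass-1 priority check: an ID-matched taxon whose name points elsewhere
    for taxon, m in matched_taxa.items():
        if m.method == METHOD_ID:
            norm = normalize_name(matrix_taxa[taxon])
            if norm != normalize_name(m.tip_label) and norm in names_tips:
                report.flagged.append(
                    f"id match for {taxon} overrides name match to {norm!r}"
                )

    report.matches = [matched_taxa[t] for t in taxa if t in matched_taxa]
    report.unmatched_taxa = {
        t: CATEGORY_OTHER for t in taxa if t not in matched_taxa
    }
    report.unmatched_tips = [
        tip for tip in tips if tip not in matched_tips
    ]
    return report


def classify_unmatched(
    report: ReconciliationReport, taxonomy: Taxonomy
) -> dict[str, int]:
    """Label unmatched matrix taxa: fossil, unconventional_name, or other.

    Mutates the report's category map and returns counts per category.
    """
    counts = {CATEGORY_FOSSIL: 0, CATEGORY_UNCONVENTIONAL: 0, CATEGORY_OTHER: 0}
    for taxon in report.unmatched_taxa:
        if taxon in taxonomy and taxonomy.get(taxon).extinct:
            cat = CATEGORY_FOSSIL
        else:
            name = taxonomy.name(taxon) if taxon in taxonomy else taxon
            if _BINOMIAL_RE.match(normalize_name(name)):
                cat = CATEGORY_OTHER
            else:
                cat = CATEGORY_UNCONVENTIONAL
        report.unmatched_taxa[taxon] = cat
        counts[cat] += 1
    return counts


def read_xref_table(path: str | Path) -> dict[str, Optional[int]]:
    """Two-column TSV (taxon_id_or_tip_label, ncbi_id) -> mapping."""
    out: dict[str, Optional[int]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        for row in reader:
            out[row[0]] = int(row[1]) if len(row) > 1 and row[1] else None
    return out
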