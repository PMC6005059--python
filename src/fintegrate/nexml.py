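"""Reader for a NeXML subset: otus, characters/format/states, matrix cells.

Supermatrices exported by ontology-driven aggregation tools arrive as NeXML
with cell-level ``meta`` elements recording whether a state is supported by a
direct author assertion, by inference, or both. The metadata predicate is not
standardized, so it is configurable; a cell whose provenance metadata cannot
be interpreted keeps its raw state but is flagged provenance-unknown and a
warning is logged.
"""

from __future__ import annotations

import logging
from pathlib import Path

from lxml import etree

from .matrix import (
    Cell,
    FLAG_PROVENANCE_UNKNOWN,
    MISSING,
    POLYMORPHIC,
    Supermatrix,
)

logger = logging.getLogger(__name__)

NEXML_NS = "http://www.nexml.org/2009"
_N = f"{{{NEXML_NS}}}"

#: default meta property marking a cell's provenance ("asserted"/"inferred"/"both")
DEFAULT_PROVENANCE_PREDICATE = "ps:provenance"


class NexmlError(ValueError):
    pass


def read_nexml_subset(
    path: str | Path,
    provenance_predicate: str = DEFAULT_PROVENANCE_PREDICATE,
) -> Supermatrix:
    """Parse a NeXML characters block into a provenance-coded Supermatrix.

    State symbols in the file are the biological states 0 (absent) and
    1 (present), plus polymorphic state sets; the reader recodes them with the
    provenance metadata into the native symbol set (1/0 asserted, 2 inferred
    present, 3 inferred absent, 0&1 both states, ? missing).
    """
    try:
        doc = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise NexmlError(f"malformed XML: {exc}") from exc
    root = doc.getroot()

    otu_labels: dict[str, str] = {}
    for otu in root.iter(f"{_N}otu"):
        otu_labels[otu.get("id")] = otu.get("label", otu.get("id"))

    characters_el = root.find(f"{_N}characters")
    if characters_el is None:
        raise NexmlError("no characters element found")
    fmt = characters_el.find(f"{_N}format")
    if fmt is None or fmt.find(f"{_N}states") is None:
        raise NexmlError("states block missing from characters format")

    # state id -> set of biological state symbols
    state_symbols: dict[str, frozenset[str]] = {}
    for states in fmt.iter(f"{_N}states"):
        for st in states.iter(f"{_N}state"):
            state_symbols[st.get("id")] = frozenset({st.get("symbol")})
        for poly in states.iter(f"{_N}polymorphic_state_set"):
            members = frozenset(
                m.get("state") for m in poly.iter(f"{_N}member")
            )
            symbols = frozenset().union(
                *(state_symbols.get(m, frozenset()) for m in members)
            )
            state_symbols[poly.get("id")] = symbols
        for unc in states.iter(f"{_N}uncertain_state_set"):
            state_symbols[unc.get("id")] = frozenset({MISSING})

    char_labels: dict[str, str] = {}
    for char in fmt.iter(f"{_N}char"):
        char_labels[char.get("id")] = char.get("label", char.get("id"))

    mat = Supermatrix(list(char_labels.values()))
    matrix_el = characters_el.find(f"{_N}matrix")
    if matrix_el is None:
        raise NexmlError("matrix element missing")
    for row in matrix_el.iter(f"{_N}row"):
        taxon = otu_labels.get(row.get("otu"), row.get("otu"))
        for cell_el in row.iter(f"{_N}cell"):
            char_id = cell_el.get("char")
            character = char_labels.get(char_id)
            if character is None:
                continue
            symbols = state_symbols.get(cell_el.get("state"))
            if symbols is None:
                logger.warning("unknown state id %r; cell left missing", cell_el.get("state"))
                continue
            provenance, flags = _cell_provenance(cell_el, provenance_predicate, taxon, character)
            mat.set_cell(taxon, character, _code_cell(symbols, provenance, flags))
    return mat


def _cell_provenance(cell_el, predicate: str, taxon: str, character: str):
    provenance = None
    flags: set[str] = set()
    metas = [m for m in cell_el.iter(f"{_N}meta") if m.get("property") == predicate]
    if metas:
        content = (metas[0].get("content") or "").strip().lower()
        if content in ("asserted", "inferred", "both"):
            provenance = content
        else:
            logger.warning(
                "unparseable provenance %r for %s/%s; downgrading to provenance-unknown",
                content, taxon, character,
            )
            flags.add(FLAG_PROVENANCE_UNKNOWN)
    else:
        flags.add(FLAG_PROVENANCE_UNKNOWN)
    return provenance, flags


def _code_cell(symbols: frozenset[str], provenance, flags: set[str]) -> Cell:
    if symbols == frozenset({MISSING}) or not symbols:
        return Cell(symbol=MISSING, flags=frozenset(flags))
    if symbols == frozenset({"0", "1"}):
        return Cell(symbol=POLYMORPHIC, flags=frozenset(flags))
    (state,) = symbols
    if provenance == "inferred":
        symbol = "2" if state == "1" else "3"
        if symbol == "3":
            logger.warning("inferred-only absence encountered in NeXML input")
    else:
        # asserted, both, or provenance-unknown: keep the author-level coding
        symbol = state
    return Cell(symbol=symbol, flags=frozenset(flags))
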