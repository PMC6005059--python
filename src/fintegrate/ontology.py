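"""Anatomy graph: anatomical terms connected by typed, directed edges.

Edges follow the conventions of multispecies anatomy ontologies:

* ``part_of``      - subject is a part of object (fin ray part_of fin)
* ``is_a``         - subject is a subtype of object (pectoral fin is_a paired fin)
* ``develops_from``- subject develops from object (fin develops_from larval fin bud)
* ``depends_on``   - subject structurally requires object (fin depends_on girdle;
  paired fins never occur without their supporting girdle)

``part_of`` and ``is_a`` must each be acyclic. The graph is the substrate for
the asymmetric presence/absence inference rules in :mod:`fintegrate.inference`.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Optional

import networkx as nx

PART_OF = "part_of"
IS_A = "is_a"
DEVELOPS_FROM = "develops_from"
DEPENDS_ON = "depends_on"

RELATIONS = (PART_OF, IS_A, DEVELOPS_FROM, DEPENDS_ON)

Edge = tuple[str, str, str]  # (subject, relation, object)


class OntologyError(ValueError):
    pass


class AnatomyGraph:
    def __init__(
        self,
        terms: dict[str, str] | Iterable[str],
        edges: Iterable[Edge] = (),
    ):
        if isinstance(terms, dict):
            self.labels = dict(terms)
        else:
            self.labels = {t: t for t in terms}
        self.edges: set[Edge] = set()
        # adjacency indexed by relation for the inference worklist
        self._out: dict[str, dict[str, set[str]]] = {
            r: {} for r in RELATIONS
        }  # relation -> subject -> objects
        self._in: dict[str, dict[str, set[str]]] = {
            r: {} for r in RELATIONS
        }  # relation -> object -> subjects
        for edge in edges:
            self.add_edge(*edge)
        self.validate()

    def add_edge(self, subject: str, relation: str, obj: str) -> None:
        if relation not in RELATIONS:
            raise OntologyError(f"unknown relation {relation!r}")
        for term in (subject, obj):
            if term not in self.labels:
                raise OntologyError(f"dangling term {term!r} in edge")
        self.edges.add((subject, relation, obj))
        self._out[relation].setdefault(subject, set()).add(obj)
        self._in[relation].setdefault(obj, set()).add(subject)

    def validate(self) -> None:
        for rel in (PART_OF, IS_A):
            g = nx.DiGraph(
                (s, o) for (s, r, o) in self.edges if r == rel
            )
            if not nx.is_directed_acyclic_graph(g):
                raise OntologyError(f"cycle detected in {rel} edges")

    # -- traversal helpers ---------------------------------------------------

    def objects(self, subject: str, relation: str) -> set[str]:
        return set(self._out[relation].get(subject, ()))

    def subjects(self, obj: str, relation: str) -> set[str]:
        return set(self._in[relation].get(obj, ()))

    def isa_descendants(self, term: str) -> set[str]:
        """All terms that are (transitively) subtypes of ``term``."""
        out: set[str] = set()
        stack = [term]
        while stack:
            cur = stack.pop()
            for sub in self._in[IS_A].get(cur, ()):
                if sub not in out:
                    out.add(sub)
                    stack.append(sub)
        return out

    def has_term(self, term: str) -> bool:
        return term in self.labels

    # -- IO --------------------------------------------------------------------

    def to_tsv(self, edges_path: str | Path, labels_path: Optional[str | Path] = None) -> None:
        with open(edges_path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["subject", "relation", "object"])
            for s, r, o in sorted(self.edges):
                w.writerow([s, r, o])
        if labels_path is not None:
            with open(labels_path, "w", newline="") as fh:
                w = csv.writer(fh, delimiter="\t", lineterminator="\n")
                w.writerow(["term", "label"])
                for t in sorted(self.labels):
                    w.writerow([t, self.labels[t]])


def build_anatomy_graph(
    edge_table: Iterable[Edge],
    labels: Optional[dict[str, str]] = None,
) -> AnatomyGraph:
    """Validate an edge table into an :class:`AnatomyGraph`.

    Terms are collected from the edge endpoints plus any labels given; an
    unknown relation label or a ``part_of``/``is_a`` cycle is rejected.
    """
    edges = [tuple(e) for e in edge_table]
    for e in edges:
        if len(e) != 3:
            raise OntologyError(f"malformed edge row {e!r}")
        if e[1] not in RELATIONS:
            raise OntologyError(f"unknown relation {e[1]!r}")
    terms: dict[str, str] = {}
    if labels:
        terms.update(labels)
    for s, _, o in edges:
        terms.setdefault(s, s)
        terms.setdefault(o, o)
    return AnatomyGraph(terms, edges)


def read_anatomy_graph(
    edges_path: str | Path, labels_path: Optional[str | Path] = None
) -> AnatomyGraph:
    labels: dict[str, str] = {}
    if labels_path is not None and Path(labels_path).exists():
        with open(labels_path, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                labels[row["term"]] = row["label"]
    edges = []
    with open(edges_path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            edges.append((row["subject"], row["relation"], row["object"]))
    return build_anatomy_graph(edges, labels)
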