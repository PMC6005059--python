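"""Inference rules: the asymmetric presence/absence closure and conflicts."""

import random

import pytest

from fintegrate.inference import (
    ABSENT,
    APPARENT_POLYMORPHISM,
    ASSERT_VS_INFER,
    PRESENT,
    TRUE_POLYMORPHISM,
    PhenotypeAnnotation,
    close_annotations,
    detect_conflicts,
    infer_absence,
    infer_presence,
)
from fintegrate.ontology import AnatomyGraph, OntologyError, build_anatomy_graph

from _oracles import absence_closure_oracle, presence_closure_oracle


def ann(taxon, entity, quality, provenance="asserted", study="s1"):
    return PhenotypeAnnotation(taxon, entity, quality, provenance, study)


def present_entities(annotations, taxon):
    return {a.entity for a in annotations if a.taxon == taxon and not a.is_absent}


def absent_entities(annotations, taxon):
    return {a.entity for a in annotations if a.taxon == taxon and a.is_absent}


# ---------------------------------------------------------------------------
# presence


def test_part_quality_implies_whole_presence(template):
    """A quality on the fin ray evidences the ray, the fin, and its supertypes."""
    out = infer_presence([ann("sp", "pectoral_fin_ray", "unbranched")], template)
    got = present_entities(out, "sp")
    assert {"pectoral_fin_ray", "pectoral_fin", "paired_fin", "fin"} <= got
    # and nothing absence-flavoured appears
    assert not absent_entities(out, "sp")


def test_presence_chain_through_nested_parts():
    graph = build_anatomy_graph(
        [("E", "part_of", "F"), ("F", "part_of", "G")]
    )
    out = infer_presence([ann("sp", "E", "round")], graph)
    assert present_entities(out, "sp") == {"E", "F", "G"}


@pytest.mark.parametrize(
    "entity,forbidden",
    [
        ("pectoral_girdle", "pectoral_fin"),  # girdle presence !=> fin presence
        ("pectoral_fin_bud", "pectoral_fin"),  # bud presence !=> fin presence
        ("pectoral_fin", "pectoral_fin_ray"),  # whole presence !=> part presence
    ],
)
def test_presence_non_inferences(template, entity, forbidden):
    out = infer_presence([ann("sp", entity, PRESENT)], template)
    assert forbidden not in present_entities(out, "sp")


# ---------------------------------------------------------------------------
# absence


def test_girdle_absence_cascades_to_fin_and_ray(template):
    out = infer_absence([ann("sp", "pelvic_girdle", ABSENT)], template)
    got = absent_entities(out, "sp")
    assert {"pelvic_fin", "pelvic_fin_ray", "pelvic_radial"} <= got
    assert "pectoral_fin" not in got


def test_bud_absence_implies_fin_absence(template):
    out = infer_absence([ann("sp", "pectoral_fin_bud", ABSENT)], template)
    assert "pectoral_fin" in absent_entities(out, "sp")


def test_fin_absence_does_not_reach_girdle_or_bud(template):
    """Absence of the fin says nothing about the girdle (girdle-present,
    fin-absent taxa exist) nor about the larval bud."""
    out = infer_absence([ann("sp", "pectoral_fin", ABSENT)], template)
    got = absent_entities(out, "sp")
    assert "pectoral_girdle" not in got
    assert "pectoral_fin_bud" not in got
    assert "pectoral_fin_ray" in got  # parts do go absent


def test_part_absence_does_not_imply_whole_absence(template):
    out = infer_absence([ann("sp", "pectoral_fin_ray", ABSENT)], template)
    assert "pectoral_fin" not in absent_entities(out, "sp")


# ---------------------------------------------------------------------------
# closure properties


def _random_graph(rng, n_terms):
    terms = [f"x{i}" for i in range(n_terms)]
    edges = []
    relations = ("part_of", "is_a", "develops_from", "depends_on")
    for i in range(n_terms):
        for j in range(i + 1, n_terms):
            if rng.random() < 0.12:
                # i -> j keeps part_of/is_a acyclic by index ordering
                edges.append((terms[i], rng.choice(relations), terms[j]))
    return build_anatomy_graph(edges, labels={t: t for t in terms})


def test_closure_matches_reachability_oracle_on_random_graphs():
    rng = random.Random(11)
    for _ in range(40):
        graph = _random_graph(rng, rng.randint(5, 30))
        terms = sorted(graph.labels)
        start = terms[rng.randrange(len(terms))]
        pres = infer_presence([ann("sp", start, "round")], graph)
        assert present_entities(pres, "sp") == presence_closure_oracle(graph, start)
        absn = infer_absence([ann("sp", start, ABSENT)], graph)
        got = absent_entities(absn, "sp") | {start}
        assert got == absence_closure_oracle(graph, start)


def test_closure_is_a_fixpoint_and_monotone(template):
    base = [
        ann("sp", "pectoral_fin_ray", "unbranched"),
        ann("sp2", "pelvic_girdle", ABSENT),
    ]
    closed = close_annotations(base, template)
    again = close_annotations(closed, template)
    assert {(a.taxon, a.entity, a.is_absent) for a in again} == {
        (a.taxon, a.entity, a.is_absent) for a in closed
    }
    # monotonicity: adding an annotation never removes inferable facts
    bigger = close_annotations(base + [ann("sp3", "pelvic_fin", PRESENT)], template)
    assert {(a.taxon, a.entity, a.is_absent) for a in closed} <= {
        (a.taxon, a.entity, a.is_absent) for a in bigger
    }


def test_inferred_annotations_carry_derivation_chains(template):
    out = infer_absence([ann("sp", "pelvic_girdle", ABSENT)], template)
    ray = next(a for a in out if a.entity == "pelvic_fin_ray")
    assert ray.provenance == "inferred"
    assert len(ray.chain) >= 2  # girdle -> fin -> ray
    subjects = [step[0] for step in ray.chain]
    assert subjects[-1] == "pelvic_fin_ray"


def test_asserted_annotation_requires_study_tag():
    with pytest.raises(ValueError):
        PhenotypeAnnotation("sp", "pectoral_fin", PRESENT, "asserted", study="")


# ---------------------------------------------------------------------------
# conflict detection


def test_conflict_categories(template, tiny_taxonomy):
    annotations = [
        # S1: inferred presence (ray thickness) vs asserted absence
        ann("S1", "pelvic_fin_ray", "increased thickness"),
        ann("S1", "pelvic_fin", ABSENT),
        # S2: presence and absence both asserted at species rank
        ann("S2", "pelvic_fin", PRESENT, study="s1"),
        ann("S2", "pelvic_fin", ABSENT, study="s2"),
        # F1: family-rank statements from different studies disagree
        ann("F1", "pectoral_fin", PRESENT, study="s1"),
        ann("F1", "pectoral_fin", ABSENT, study="s3"),
        # S3: unconflicted
        ann("S3", "pectoral_fin", PRESENT),
    ]
    closed = close_annotations(annotations, template)
    report = detect_conflicts(
        closed, tiny_taxonomy, ["pectoral_fin", "pelvic_fin"], template
    )
    by_taxon = {(c.taxon, c.character): c.category for c in report.conflicts}
    assert by_taxon[("S1", "pelvic_fin")] == ASSERT_VS_INFER
    assert by_taxon[("S2", "pelvic_fin")] == TRUE_POLYMORPHISM
    assert by_taxon[("F1", "pectoral_fin")] == APPARENT_POLYMORPHISM
    assert ("S3", "pectoral_fin") not in by_taxon
    for c in report.conflicts:
        assert c.presence_support and c.absence_support


# ---------------------------------------------------------------------------
# graph validation


def test_part_of_cycle_rejected():
    with pytest.raises(OntologyError):
        build_anatomy_graph([("A", "part_of", "B"), ("B", "part_of", "A")])


def test_unknown_relation_rejected():
    with pytest.raises(OntologyError):
        build_anatomy_graph([("A", "half_of", "B")])


def test_dangling_term_rejected():
    with pytest.raises(OntologyError):
        AnatomyGraph({"A": "a"}, [("A", "part_of", "B")])


def test_trivial_graph_is_valid():
    g = AnatomyGraph({"lonely": "lonely term"})
    assert g.has_term("lonely")
    assert not g.edges
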