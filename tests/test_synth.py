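"""Synthetic-data generator: determinism, parameter semantics, ground truth."""

import pytest

from fintegrate.inference import close_annotations, detect_conflicts
from fintegrate.ontology import IS_A, PART_OF
from fintegrate.synth import (
    CHARACTERS,
    PlacementError,
    ScenarioError,
    SyntheticScenario,
    generate_anatomy_template,
    generate_annotations,
    generate_dataset,
    generate_taxonomy,
    generate_tree,
    plant_trait_history,
    write_fixtures,
)
from fintegrate.trees import is_binary, tree_from_string
from fintegrate.parsimony import parsimony_length

from _oracles import enumerate_parsimony


def scenario(**kw):
    return SyntheticScenario(**kw)


# ---------------------------------------------------------------------------
# scenario validation


def test_scenario_rejects_bad_values():
    with pytest.raises(ScenarioError):
        scenario(n_families=0)
    with pytest.raises(ScenarioError):
        scenario(species_coverage=1.5)
    with pytest.raises(ScenarioError):
        scenario(genera_per_family=(3, 2))
    with pytest.raises(ScenarioError):
        scenario(event_count_loss=1, event_count_regain=2)


# ---------------------------------------------------------------------------
# taxonomy


def test_taxonomy_node_arithmetic():
    sc = scenario(n_families=2, genera_per_family=(2, 2),
                  species_per_genus=(3, 3))
    taxonomy = generate_taxonomy(sc)
    # 1 root + 2 families + 4 genera + 12 species
    assert len(taxonomy) == 1 + 2 + 4 + 12
    assert len(taxonomy.species_ids()) == 12


def test_taxonomy_deterministic():
    sc = scenario(seed=42)
    a = generate_taxonomy(sc)
    b = generate_taxonomy(sc)
    assert [(r.id, r.name, r.rank, r.parent_id, r.ncbi_id) for r in a] == [
        (r.id, r.name, r.rank, r.parent_id, r.ncbi_id) for r in b
    ]


def test_xref_fraction_behaves_binomially():
    """Mean cross-reference rate over many seeds approaches the parameter."""
    frac = 0.5
    rates = []
    for seed in range(40):
        sc = scenario(seed=seed, n_families=4, genera_per_family=(3, 3),
                      species_per_genus=(3, 3), xref_fraction=frac)
        taxonomy = generate_taxonomy(sc)
        species = [taxonomy.get(s) for s in taxonomy.species_ids()]
        rates.append(sum(1 for r in species if r.ncbi_id) / len(species))
    mean = sum(rates) / len(rates)
    assert abs(mean - frac) < 0.05  # ~1440 Bernoulli draws


# ---------------------------------------------------------------------------
# anatomy template


def test_template_structure(template):
    assert ("pectoral_fin_ray", PART_OF, "pectoral_fin") in template.edges
    assert ("pectoral_fin", "depends_on", "pectoral_girdle") in template.edges
    assert ("pelvic_fin", "develops_from", "pelvic_fin_bud") in template.edges
    assert ("pectoral_fin", IS_A, "paired_fin") in template.edges
    template.validate()  # no part_of / is_a cycles


# ---------------------------------------------------------------------------
# tree


def test_tree_polytomy_and_mismatch_controls():
    sc = scenario(seed=1, polytomy_fraction=0.0, mismatch_rate=0.0,
                  extra_tip_rate=0.0)
    taxonomy = generate_taxonomy(sc)
    tree = generate_tree(taxonomy, sc)
    assert is_binary(tree)
    species_names = {taxonomy.name(s) for s in taxonomy.species_ids()}
    tips = {l.taxon.label.replace("_", " ") for l in tree.leaf_node_iter()}
    assert tips == species_names


def test_tree_extra_tips_and_perturbations():
    sc = scenario(seed=2, mismatch_rate=0.1, extra_tip_rate=0.1)
    taxonomy = generate_taxonomy(sc)
    tree = generate_tree(taxonomy, sc)
    n_species = len(taxonomy.species_ids())
    tips = list(tree.leaf_node_iter())
    assert len(tips) == n_species + round(0.1 * n_species)
    perturbed = [t for t, sp in tree.original_labels.items()
                 if sp is not None and t.replace("_", " ") != sp]
    assert len(perturbed) == round(0.1 * n_species)
    assert all(t.endswith("_x") for t in perturbed)
    novel = [t for t, sp in tree.original_labels.items() if sp is None]
    assert len(novel) == round(0.1 * n_species)


def test_tree_deterministic():
    sc = scenario(seed=9)
    taxonomy = generate_taxonomy(sc)
    a = generate_tree(taxonomy, sc).as_string(schema="newick")
    b = generate_tree(taxonomy, sc).as_string(schema="newick")
    assert a == b


# ---------------------------------------------------------------------------
# trait history


def test_no_events_means_all_presence():
    sc = scenario(seed=3, event_count_loss=0, event_count_regain=0)
    taxonomy = generate_taxonomy(sc)
    tree = generate_tree(taxonomy, sc)
    truth = plant_trait_history(tree, sc)
    for char in CHARACTERS:
        assert all(truth.states[char].values())
    assert not truth.events


def test_sparse_losses_recovered_by_parsimony_oracle():
    """Hartigan length on the planted tip states equals the event count."""
    sc = scenario(seed=4, n_families=3, event_count_loss=3,
                  event_count_regain=0, polytomy_fraction=0.0)
    taxonomy = generate_taxonomy(sc)
    tree = generate_tree(taxonomy, sc)
    truth = plant_trait_history(tree, sc)
    # check with the independent enumeration oracle on a small instance
    states = {
        tip: frozenset({1 if truth.states["pectoral_fin"][sp] else 0})
        for tip, sp in truth.tip_name_map.items()
    }
    if sum(1 for _ in tree.leaf_node_iter()) <= 12:
        assert enumerate_parsimony(tree, states).length == 3
    assert parsimony_length(tree, states) == 3


def test_regain_leaves_presence_inside_lost_clade():
    sc = scenario(seed=5, event_count_loss=2, event_count_regain=1)
    taxonomy = generate_taxonomy(sc)
    tree = generate_tree(taxonomy, sc)
    truth = plant_trait_history(tree, sc)
    for char in CHARACTERS:
        regains = [e for e in truth.events
                   if e.character == char and e.kind == "regain"]
        assert len(regains) == 1
        assert regains[0].clade  # regained clade non-empty
        assert all(truth.states[char][sp] for sp in regains[0].clade)
        host = next(
            e for e in truth.events
            if e.character == char and e.kind == "loss"
            and regains[0].clade <= e.clade
        )
        assert not all(truth.states[char][sp] for sp in host.clade)


def test_impossible_sparse_placement_reported():
    tree = tree_from_string("(a,b);")
    tree.original_labels = {"a": "a", "b": "b"}
    sc = scenario(event_count_loss=5, event_count_regain=0)
    with pytest.raises(PlacementError):
        plant_trait_history(tree, sc)


# ---------------------------------------------------------------------------
# annotations


def test_indirect_fraction_one_yields_only_part_level_presence():
    sc = scenario(seed=6, indirect_fraction=1.0, higher_level_fraction=0.0,
                  event_count_loss=0, event_count_regain=0)
    ds = generate_dataset(sc)
    for a in ds.annotations:
        assert a.entity != "pectoral_fin" and a.entity != "pelvic_fin"
        assert not a.is_absent  # all species present, stated via parts


def test_monomorphic_family_replaced_by_family_annotation():
    sc = scenario(seed=7, higher_level_fraction=1.0, event_count_loss=0,
                  event_count_regain=0, indirect_fraction=0.0)
    ds = generate_dataset(sc)
    ranks = {ds.taxonomy.rank(a.taxon) for a in ds.annotations}
    assert ranks == {"family"}  # every species is covered by its family


def test_conflict_rate_zero_is_internally_consistent():
    sc = scenario(seed=8, conflict_rate=0.0)
    ds = generate_dataset(sc)
    closed = close_annotations(ds.annotations, ds.anatomy)
    report = detect_conflicts(
        closed, ds.taxonomy, list(CHARACTERS), ds.anatomy
    )
    assert not report.conflicts


def test_planted_conflicts_are_exactly_the_detected_ones():
    sc = scenario(seed=9, conflict_rate=0.1)
    ds = generate_dataset(sc)
    closed = close_annotations(ds.annotations, ds.anatomy)
    report = detect_conflicts(
        closed, ds.taxonomy, list(CHARACTERS), ds.anatomy
    )
    for char in CHARACTERS:
        detected = sorted(
            c.taxon for c in report.conflicts if c.character == char
        )
        assert detected == ds.planted_conflicts[char]


# ---------------------------------------------------------------------------
# fixtures on disk


def test_fixture_writing_is_deterministic(tmp_path):
    sc = scenario(seed=10, mismatch_rate=0.05, extra_tip_rate=0.05)
    d1 = tmp_path / "a"
    d2 = tmp_path / "b"
    write_fixtures(generate_dataset(sc), d1)
    write_fixtures(generate_dataset(sc), d2)
    files = sorted(p.name for p in d1.iterdir())
    assert files == sorted(p.name for p in d2.iterdir())
    for name in files:
        assert (d1 / name).read_bytes() == (d2 / name).read_bytes()
    # different seed, different tree
    d3 = tmp_path / "c"
    write_fixtures(generate_dataset(scenario(seed=11, mismatch_rate=0.05,
                                             extra_tip_rate=0.05)), d3)
    assert (d1 / "tree.nwk").read_text() != (d3 / "tree.nwk").read_text()
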