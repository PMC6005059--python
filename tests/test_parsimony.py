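"""Parsimony engine: examples, enumeration cross-checks, and invariants."""

import logging
import random

import pytest

from fintegrate.parsimony import (
    change_bounds,
    count_mprs,
    parsimony_length,
    min_regains_over_resolutions,
    sample_mprs,
    summarize_mprs,
)
from fintegrate.trees import is_binary, resolve_polytomies, tree_from_string

from _oracles import enumerate_parsimony, random_states, random_tree


def _states(mapping):
    out = {}
    for k, v in mapping.items():
        if v is None:
            out[k] = frozenset()
        elif isinstance(v, int):
            out[k] = frozenset({v})
        else:
            out[k] = frozenset(v)
    return out


@pytest.mark.parametrize(
    "newick,tips,length",
    [
        ("((a,b),(c,d));", {"a": 1, "b": 1, "c": 0, "d": 0}, 1),
        ("(a,b,c);", {"a": 1, "b": 1, "c": 0}, 1),
        ("((a,b),(c,d));", {"a": 1, "b": 0, "c": 1, "d": 0}, 2),
        ("((a,b),(c,d));", {"a": 1, "b": None, "c": 0, "d": (0, 1)}, 1),
        ("((a,b),c);", {"a": 1, "b": 1, "c": 1}, 0),
    ],
)
def test_length_examples(newick, tips, length):
    tree = tree_from_string(newick)
    assert parsimony_length(tree, _states(tips)) == length


@pytest.mark.parametrize(
    "newick,tips,count",
    [
        ("(a,b);", {"a": 1, "b": 0}, 2),  # either root state costs one step
        ("((a,b),(c,d));", {"a": 1, "b": 1, "c": 1, "d": 1}, 1),
        ("(a,b,c);", {"a": 1, "b": 1, "c": 0}, 1),  # root must be 1
    ],
)
def test_mpr_count_examples(newick, tips, count):
    tree = tree_from_string(newick)
    assert count_mprs(tree, _states(tips)) == count


def test_single_absent_tip_is_one_certain_loss():
    tree = tree_from_string("((a,b),(c,(d,e)));")
    states = _states({"a": 1, "b": 1, "c": 1, "d": 1, "e": 0})
    bounds = change_bounds(tree, states)
    assert (bounds.gain_min, bounds.gain_max) == (0, 0)
    assert (bounds.loss_min, bounds.loss_max) == (1, 1)


def test_all_missing_is_zero_length_with_warning(caplog):
    tree = tree_from_string("((a,b),c);")
    states = _states({"a": None, "b": None, "c": None})
    with caplog.at_level(logging.WARNING):
        assert parsimony_length(tree, states) == 0
    assert any("all tips missing" in r.message for r in caplog.records)


def test_matches_enumeration_on_random_trees():
    """Length, MPR count and per-type bounds equal exhaustive enumeration."""
    rng = random.Random(20240917)
    for _ in range(150):
        tree = random_tree(rng, rng.randint(2, 10))
        states = random_states(rng, tree)
        oracle = enumerate_parsimony(tree, states)
        assert parsimony_length(tree, states) == oracle.length
        assert count_mprs(tree, states) == oracle.count
        bounds = change_bounds(tree, states)
        assert (bounds.gain_min, bounds.gain_max) == (
            oracle.gain_min,
            oracle.gain_max,
        )
        assert (bounds.loss_min, bounds.loss_max) == (
            oracle.loss_min,
            oracle.loss_max,
        )


def test_length_invariant_under_rerooting():
    """Unit-cost symmetric model: the root placement cannot change the length."""
    rng = random.Random(7)
    for _ in range(20):
        tree = random_tree(rng, rng.randint(4, 10))
        states = random_states(rng, tree, p_missing=0.1, p_poly=0.1)
        base = parsimony_length(tree, states)
        clone = tree.clone(depth=1)
        internal_edges = [
            e for e in clone.preorder_edge_iter()
            if e.head_node is not clone.seed_node and not e.head_node.is_leaf()
        ]
        if not internal_edges:
            continue
        edge = internal_edges[rng.randrange(len(internal_edges))]
        clone.reroot_at_edge(edge)
        assert parsimony_length(clone, states) == base


def test_sampled_mprs_achieve_length_and_cover_the_set():
    tree = tree_from_string("((a,b),(c,d));")
    states = _states({"a": 1, "b": 0, "c": 1, "d": 0})
    oracle = enumerate_parsimony(tree, states)
    length = parsimony_length(tree, states)
    labelings, changes = sample_mprs(tree, states, n=400, seed=5)
    assert all(g + l == length for g, l in changes)
    observed = {tuple(sorted(lab.items())) for lab in labelings}
    expected = {tuple(sorted(lab)) for lab in oracle.labelings}
    assert observed == expected  # every MPR seen in 400 draws from a tiny set


def test_sample_requires_positive_n():
    tree = tree_from_string("(a,b);")
    with pytest.raises(ValueError):
        sample_mprs(tree, _states({"a": 1, "b": 0}), n=0, seed=1)


def test_summary_invariant_chain():
    """exact min <= sampled min <= mean <= sampled max <= exact max, both types."""
    rng = random.Random(99)
    for _ in range(10):
        tree = random_tree(rng, 8)
        states = random_states(rng, tree, p_missing=0.2, p_poly=0.2)
        s = summarize_mprs(tree, states, n_samples=60, seed=3)
        assert s.gain_min <= s.sampled_gain_min <= s.sampled_gain_mean
        assert s.sampled_gain_mean <= s.sampled_gain_max <= s.gain_max
        assert s.loss_min <= s.sampled_loss_min <= s.sampled_loss_mean
        assert s.sampled_loss_mean <= s.sampled_loss_max <= s.loss_max
        assert s.gain_min + s.loss_min <= s.length


def test_resolve_polytomies_properties():
    binary = tree_from_string("((a,b),(c,d));")
    resolved = resolve_polytomies(binary, seed=1)
    assert is_binary(resolved)
    assert {l.taxon.label for l in resolved.leaf_node_iter()} == {"a", "b", "c", "d"}

    star = tree_from_string("(a,b,c,d);")
    resolved = resolve_polytomies(star, seed=2)
    assert is_binary(resolved)
    n_internal = sum(1 for _ in resolved.preorder_internal_node_iter())
    assert n_internal == 3  # binary rooted tree on 4 tips

    topologies = set()
    five = tree_from_string("(a,b,c,d,e);")
    for seed in range(100):
        r = resolve_polytomies(five, seed=seed)
        topologies.add(
            r.as_string(schema="newick", suppress_rooting=True).strip()
        )
    assert len(topologies) > 1


def test_resolution_never_lengthens_reconstruction():
    """Any labeling of the polytomous tree extends to a resolution at equal
    cost (give the new nodes the old node's state), so a binary resolution's
    length is at most the hard-polytomy length."""
    rng = random.Random(4242)
    for _ in range(25):
        tree = random_tree(rng, 9, multifurcate=0.6)
        states = random_states(rng, tree)
        base = parsimony_length(tree, states)
        resolved = resolve_polytomies(tree, seed=rng.randint(0, 10**6))
        assert parsimony_length(resolved, states) <= base


def test_min_regains_over_resolutions_finds_gain_free_topology():
    """A hard polytomy can force a regain that some resolution avoids."""
    tree = tree_from_string("(out,(a1,a2,a3,p));")
    states = _states({"out": 1, "a1": 0, "a2": 0, "a3": 0, "p": 1})
    # hard polytomy: cheapest is loss into the polytomy plus regain of p
    assert change_bounds(tree, states).gain_min == 1
    best, table, best_tree = min_regains_over_resolutions(
        tree, states, n_resolutions=50, seed=11
    )
    assert best == 0
    assert len(table) == 50
    assert all(row["gain_min"] >= 0 for row in table)
    assert is_binary(best_tree)


def test_min_regains_zero_for_loss_only_pattern():
    tree = tree_from_string("((a,b),(c,d,e));")
    states = _states({"a": 1, "b": 1, "c": 0, "d": 0, "e": 0})
    best, table, _ = min_regains_over_resolutions(tree, states, 10, seed=0)
    assert best == 0
    assert all(row["gain_min"] == 0 for row in table)
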