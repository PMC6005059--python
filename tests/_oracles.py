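"""Independent brute-force oracles used by the test suite.

Kept deliberately naive: exhaustive enumeration over all internal labelings
for parsimony, and plain graph reachability (networkx) for the inference
closure. Nothing here shares code with the implementation under test.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass

import dendropy
import networkx as nx


# ---------------------------------------------------------------------------
# random trees and states


def random_tree(rng: random.Random, n_tips: int, multifurcate: float = 0.3) -> dendropy.Tree:
    """Random rooted tree by sequential joining, then random edge collapses."""
    ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.is_rooted = True
    lineages = []
    for i in range(n_tips):
        node = dendropy.Node()
        node.taxon = ns.new_taxon(f"t{i}")
        lineages.append(node)
    while len(lineages) > 1:
        a = lineages.pop(rng.randrange(len(lineages)))
        b = lineages.pop(rng.randrange(len(lineages)))
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        lineages.append(parent)
    tree.seed_node = lineages[0]
    internals = [
        n for n in tree.preorder_internal_node_iter() if n is not tree.seed_node
    ]
    for node in internals:
        if rng.random() < multifurcate:
            node.edge.collapse()
    return tree


def random_states(
    rng: random.Random,
    tree: dendropy.Tree,
    p_missing: float = 0.15,
    p_poly: float = 0.15,
) -> dict[str, frozenset[int]]:
    states = {}
    for leaf in tree.leaf_node_iter():
        r = rng.random()
        if r < p_missing:
            s = frozenset()
        elif r < p_missing + p_poly:
            s = frozenset({0, 1})
        else:
            s = frozenset({rng.randint(0, 1)})
        states[leaf.taxon.label] = s
    return states


# ---------------------------------------------------------------------------
# exhaustive parsimony


@dataclass
class EnumResult:
    length: int
    count: int
    gain_min: int
    gain_max: int
    loss_min: int
    loss_max: int
    labelings: list[tuple]  # tuples of (postorder_internal_index, state)


def enumerate_parsimony(tree: dendropy.Tree, states: dict) -> EnumResult:
    """Brute force over all 2^k internal labelings."""
    nodes = list(tree.postorder_node_iter())
    internal = [i for i, n in enumerate(nodes) if not n.is_leaf()]
    index = {id(n): i for i, n in enumerate(nodes)}
    tip_allowed = {}
    for i, n in enumerate(nodes):
        if n.is_leaf():
            allowed = states.get(n.taxon.label, frozenset())
            tip_allowed[i] = allowed if allowed else frozenset({0, 1})
    edges = []  # (parent_idx, child_idx, child_is_leaf)
    for n in nodes:
        for c in n.child_nodes():
            edges.append((index[id(n)], index[id(c)], c.is_leaf()))

    best = None
    results = []  # (cost, gains, assignment)
    for assignment in itertools.product((0, 1), repeat=len(internal)):
        lab = dict(zip(internal, assignment))
        cost = 0
        gains = 0
        for p, c, leaf in edges:
            s = lab[p]
            if leaf:
                if s in tip_allowed[c]:
                    continue
                t = next(iter(tip_allowed[c]))
            else:
                t = lab[c]
            if t != s:
                cost += 1
                if s == 0 and t == 1:
                    gains += 1
        results.append((cost, gains, assignment))
        if best is None or cost < best:
            best = cost
    mprs = [(g, a) for (c, g, a) in results if c == best]
    gain_values = [g for g, _ in mprs]
    return EnumResult(
        length=best,
        count=len(mprs),
        gain_min=min(gain_values),
        gain_max=max(gain_values),
        loss_min=best - max(gain_values),
        loss_max=best - min(gain_values),
        labelings=[
            tuple(zip(internal, a)) for _, a in mprs
        ],
    )


# ---------------------------------------------------------------------------
# inference-closure reachability oracle


def presence_closure_oracle(graph, start: str) -> set[str]:
    g = nx.DiGraph()
    g.add_nodes_from(graph.labels)
    for s, r, o in graph.edges:
        if r in ("part_of", "is_a"):
            g.add_edge(s, o)
    return {start} | nx.descendants(g, start)


def absence_closure_oracle(graph, start: str) -> set[str]:
    g = nx.DiGraph()
    g.add_nodes_from(graph.labels)
    for s, r, o in graph.edges:
        g.add_edge(o, s)  # absence flows object -> subject over every relation
    return {start} | nx.descendants(g, start)
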