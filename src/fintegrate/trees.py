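"""Rooted-tree IO and manipulation helpers built on dendropy.

Trees are rooted, possibly multifurcating, with unique tip labels and no
requirement for branch lengths.
"""

from __future__ import annotations

import random
from pathlib import Path

import dendropy


class TreeError(ValueError):
    pass


def read_tree(path: str | Path, schema: str | None = None) -> dendropy.Tree:
    path = Path(path)
    if schema is None:
        schema = "nexus" if path.suffix.lower() in (".nex", ".nexus", ".nxs") else "newick"
    tree = dendropy.Tree.get(
        path=str(path),
        schema=schema,
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    tree.is_rooted = True
    return tree


def tree_from_string(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(
        data=newick,
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    tree.is_rooted = True
    return tree


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(
        path=str(path),
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def validate_tree(tree: dendropy.Tree) -> None:
    labels = tip_labels(tree)
    if len(labels) != len(set(labels)):
        raise TreeError("tip labels are not unique")
    for node in tree.preorder_node_iter():
        if not node.is_leaf() and len(node.child_nodes()) < 2 and node is not tree.seed_node:
            raise TreeError("internal node with a single child")


def is_binary(tree: dendropy.Tree) -> bool:
    return all(
        len(n.child_nodes()) == 2
        for n in tree.preorder_internal_node_iter()
    )


def resolve_polytomies(tree: dendropy.Tree, seed: int) -> dendropy.Tree:
    """Return a binary copy: each polytomy is resolved by repeatedly joining
    two uniformly chosen child lineages under a new node. Seeded and
    deterministic; a binary input comes back topologically unchanged."""
    rng = random.Random(seed)
    out = tree.clone(depth=1)
    for node in list(out.preorder_internal_node_iter()):
        children = list(node.child_nodes())
        while len(children) > 2:
            i = rng.randrange(len(children))
            a = children.pop(i)
            j = rng.randrange(len(children))
            b = children.pop(j)
            node.remove_child(a)
            node.remove_child(b)
            joint = node.new_child()
            joint.add_child(a)
            joint.add_child(b)
            children.append(joint)
    return out
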