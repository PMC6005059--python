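"""Unordered (Fitch/Hartigan) parsimony on rooted multifurcating trees.

Binary characters (0 = absent, 1 = present), unit cost per state change,
exact on polytomies via the Sankoff-style dynamic program. Beyond the
parsimony length this module computes, exactly and with arbitrary-precision
integer arithmetic:

* the number of most parsimonious reconstructions (MPRs), i.e. internal-node
  labelings achieving the minimum length;
* per-transition-type bounds: the exact minimum and maximum number of gain
  (0->1) and loss (1->0) edges over all MPRs, via a secondary-objective DP
  restricted to minimum-cost sub-labelings (gains and losses sum to the
  length in every MPR, so the loss bounds follow from the gain bounds);
* uniform samples from the MPR set by stochastic backtracking proportional
  to sub-counts.

Tips carry state *sets*: a definite state, both states (polymorphic), or the
empty set (missing). Missing and polymorphic tips cost nothing under either
parent state; only internal nodes are labeled, so tips never multiply the
MPR count.
"""

from __future__ import annotations

import csv
import logging
import random
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import dendropy

from .matrix import FLAG_CONFLICT, POLYMORPHIC, Supermatrix
from .reconciliation import ReconciliationReport
from .trees import resolve_polytomies

logger = logging.getLogger(__name__)

ABSENT, PRESENT = 0, 1
STATES = (ABSENT, PRESENT)
_INF = float("inf")

TipStateMap = dict[str, frozenset[int]]


# ---------------------------------------------------------------------------
# merge: matrix states onto tree tips


_RECODE = {
    "1": frozenset({PRESENT}),
    "2": frozenset({PRESENT}),  # inference-only presence is presence for ASR
    "0": frozenset({ABSENT}),
    "3": frozenset({ABSENT}),
    POLYMORPHIC: frozenset({ABSENT, PRESENT}),
    "?": frozenset(),
}


def merge(
    matrix: Supermatrix,
    tree: dendropy.Tree,
    reconciliation: ReconciliationReport,
    character: str,
) -> TipStateMap:
    """Tip label -> state set for one character, via the reconciliation map.

    Matched tips are recoded ({1,2} -> presence, 0 -> absence, 0&1 -> both
    states, conflict-flagged -> missing, 3 -> absence with a warning);
    unmatched tips are missing.
    """
    taxon_for_tip = {m.tip_label: m.taxon_id for m in reconciliation.matches}
    states: TipStateMap = {}
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        taxon = taxon_for_tip.get(label)
        if taxon is None or taxon not in matrix:
            states[label] = frozenset()
            continue
        cell = matrix.cell(taxon, character)
        if FLAG_CONFLICT in cell.flags:
            states[label] = frozenset()
            continue
        if cell.symbol == "3":
            logger.warning(
                "inferred-only absence merged as absence for %s", taxon
            )
        states[label] = _RECODE[cell.symbol]
    return states


# ---------------------------------------------------------------------------
# the dynamic program


@dataclass
class _DP:
    """Postorder tables for one (tree, states) instance."""

    nodes: list  # postorder; nodes[-1] is the root
    children: list[list[int]]  # child indices per node (empty for tips)
    cost: list[list]  # cost[i][s]: min changes in subtree of i with i in state s
    count: list[list[int]]  # number of min-cost sub-labelings
    gmin: list[list]  # min gain edges within subtree under min cost
    gmax: list[list]  # max gain edges within subtree under min cost
    length: int
    root_states: list[int]  # root states achieving the minimum
    all_missing: bool


def _prepare(tree: dendropy.Tree, states: TipStateMap) -> _DP:
    nodes = []
    index: dict[int, int] = {}
    for node in tree.postorder_node_iter():
        index[id(node)] = len(nodes)
        nodes.append(node)
    n = len(nodes)
    children = [[] for _ in range(n)]
    cost = [[0, 0] for _ in range(n)]
    count = [[1, 1] for _ in range(n)]
    gmin = [[0, 0] for _ in range(n)]
    gmax = [[0, 0] for _ in range(n)]
    all_missing = True
    for i, node in enumerate(nodes):
        if node.is_leaf():
            label = node.taxon.label
            allowed = states.get(label, frozenset())
            if allowed:
                all_missing = False
            else:
                allowed = frozenset(STATES)  # missing: free either way
            for s in STATES:
                if s in allowed:
                    cost[i][s] = 0
                    count[i][s] = 1
                else:
                    cost[i][s] = _INF
                    count[i][s] = 0
        else:
            kids = [index[id(c)] for c in node.child_nodes()]
            children[i] = kids
            for s in STATES:
                tot = 0
                cnt = 1
                gn = 0
                gx = 0
                for k in kids:
                    options = [
                        (cost[k][t] + (0 if s == t else 1), t) for t in STATES
                    ]
                    best = min(o[0] for o in options)
                    tot += best
                    ts = [t for (c_, t) in options if c_ == best]
                    cnt *= sum(count[k][t] for t in ts)
                    gain = lambda t: 1 if (s == ABSENT and t == PRESENT) else 0
                    gn += min(gmin[k][t] + gain(t) for t in ts)
                    gx += max(gmax[k][t] + gain(t) for t in ts)
                cost[i][s] = tot
                count[i][s] = cnt
                gmin[i][s] = gn
                gmax[i][s] = gx
    root = n - 1
    length = min(cost[root])
    root_states = [s for s in STATES if cost[root][s] == length]
    return _DP(nodes, children, cost, count, gmin, gmax, int(length),
               root_states, all_missing)


def parsimony_length(tree: dendropy.Tree, states: TipStateMap) -> int:
    """Minimum number of state changes over all internal labelings."""
    dp = _prepare(tree, states)
    if dp.all_missing:
        logger.warning("all tips missing; parsimony length is 0 by convention")
    return dp.length


def count_mprs(tree: dendropy.Tree, states: TipStateMap) -> int:
    """Exact number of internal labelings achieving the minimum length."""
    dp = _prepare(tree, states)
    root = len(dp.nodes) - 1
    return sum(dp.count[root][s] for s in dp.root_states)


@dataclass(frozen=True)
class ChangeBounds:
    gain_min: int
    gain_max: int
    loss_min: int
    loss_max: int


def change_bounds(tree: dendropy.Tree, states: TipStateMap) -> ChangeBounds:
    """Exact min/max gain and loss edge counts over all MPRs."""
    dp = _prepare(tree, states)
    root = len(dp.nodes) - 1
    gain_min = min(dp.gmin[root][s] for s in dp.root_states)
    gain_max = max(dp.gmax[root][s] for s in dp.root_states)
    return ChangeBounds(
        gain_min=gain_min,
        gain_max=gain_max,
        loss_min=dp.length - gain_max,
        loss_max=dp.length - gain_min,
    )


def sample_mprs(
    tree: dendropy.Tree,
    states: TipStateMap,
    n: int,
    seed: int,
) -> tuple[list[dict[int, int]], list[tuple[int, int]]]:
    """Draw ``n`` labelings uniformly from the MPR set.

    Stochastic backtracking: the root state, then each internal node's state
    given its parent, is drawn with probability proportional to the number of
    minimum-cost sub-labelings it admits. Returns the labelings (postorder
    node index -> state, internal nodes only) and per-sample (gains, losses);
    each sample is verified to achieve the minimum length.
    """
    if n <= 0:
        raise ValueError("sample size must be positive")
    dp = _prepare(tree, states)
    rng = random.Random(seed)
    root = len(dp.nodes) - 1
    total = sum(dp.count[root][s] for s in dp.root_states)
    labelings: list[dict[int, int]] = []
    changes: list[tuple[int, int]] = []
    tip_state: dict[int, frozenset[int]] = {}
    for i, node in enumerate(dp.nodes):
        if node.is_leaf():
            tip_state[i] = states.get(node.taxon.label, frozenset()) or frozenset(STATES)
    for _ in range(n):
        labeling: dict[int, int] = {}
        gains = 0
        losses = 0
        # root
        r = rng.randrange(total)
        for s in dp.root_states:
            if r < dp.count[root][s]:
                labeling[root] = s
                break
            r -= dp.count[root][s]
        # preorder descent
        stack = [root]
        while stack:
            i = stack.pop()
            s = labeling[i]
            for k in dp.children[i]:
                best = min(dp.cost[k][t] + (0 if s == t else 1) for t in STATES)
                ts = [
                    t for t in STATES
                    if dp.cost[k][t] + (0 if s == t else 1) == best
                ]
                if dp.nodes[k].is_leaf():
                    # tips are not labeled; the edge change is determined
                    t = s if s in tip_state[k] else next(iter(tip_state[k]))
                    if t != s:
                        if s == ABSENT:
                            gains += 1
                        else:
                            losses += 1
                    continue
                subtotal = sum(dp.count[k][t] for t in ts)
                r = rng.randrange(subtotal)
                for t in ts:
                    if r < dp.count[k][t]:
                        chosen = t
                        break
                    r -= dp.count[k][t]
                labeling[k] = chosen
                if chosen != s:
                    if s == ABSENT and chosen == PRESENT:
                        gains += 1
                    else:
                        losses += 1
                stack.append(k)
        if gains + losses != dp.length:
            raise AssertionError(
                "sampled labeling does not achieve the parsimony length"
            )
        labelings.append(labeling)
        changes.append((gains, losses))
    return labelings, changes


# ---------------------------------------------------------------------------
# summaries


@dataclass
class MPRSummary:
    """Parsimony length, exact MPR analytics, and sampled change statistics."""

    length: int
    mpr_count: int
    gain_min: int
    gain_max: int
    loss_min: int
    loss_max: int
    sampled_gain_min: Optional[int] = None
    sampled_gain_max: Optional[int] = None
    sampled_gain_mean: Optional[float] = None
    sampled_loss_min: Optional[int] = None
    sampled_loss_max: Optional[int] = None
    sampled_loss_mean: Optional[float] = None
    sample_size: int = 0
    seed: Optional[int] = None


def summarize_mprs(
    tree: dendropy.Tree,
    states: TipStateMap,
    n_samples: int = 1000,
    seed: int = 0,
) -> MPRSummary:
    """Length, MPR count, exact per-type bounds, and a sampled min/max/mean."""
    dp = _prepare(tree, states)
    bounds = change_bounds(tree, states)
    _, changes = sample_mprs(tree, states, n_samples, seed)
    gains = [g for g, _ in changes]
    losses = [l for _, l in changes]
    return MPRSummary(
        length=dp.length,
        mpr_count=count_mprs(tree, states),
        gain_min=bounds.gain_min,
        gain_max=bounds.gain_max,
        loss_min=bounds.loss_min,
        loss_max=bounds.loss_max,
        sampled_gain_min=min(gains),
        sampled_gain_max=max(gains),
        sampled_gain_mean=sum(gains) / len(gains),
        sampled_loss_min=min(losses),
        sampled_loss_max=max(losses),
        sampled_loss_mean=sum(losses) / len(losses),
        sample_size=n_samples,
        seed=seed,
    )


def export_node_states(
    tree: dendropy.Tree,
    labeling: dict[int, int],
    path: str | Path,
) -> None:
    """Write one reconstruction as TSV (node id, state)."""
    nodes = list(tree.postorder_node_iter())
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["node", "state"])
        for i, node in enumerate(nodes):
            if i in labeling:
                name = node.taxon.label if node.taxon else f"node{i}"
                w.writerow([name, labeling[i]])


def min_regains_over_resolutions(
    tree: dendropy.Tree,
    states: TipStateMap,
    n_resolutions: int,
    seed: int,
) -> tuple[int, list[dict], Optional[dendropy.Tree]]:
    """Minimum exact gain count across random polytomy resolutions.

    Each replicate randomly resolves every polytomy (seeded), recomputes the
    exact gain bounds on the binary tree, and records the replicate's minimum
    number of regains (0->1 edges). Returns the overall minimum, the
    per-replicate table, and the argmin topology.
    """
    if n_resolutions <= 0:
        raise ValueError("need at least one resolution replicate")
    best: Optional[int] = None
    best_tree: Optional[dendropy.Tree] = None
    table: list[dict] = []
    for rep in range(n_resolutions):
        rep_seed = seed + rep
        resolved = resolve_polytomies(tree, seed=rep_seed)
        bounds = change_bounds(resolved, states)
        length = parsimony_length(resolved, states)
        table.append(
            {
                "replicate": rep,
                "seed": rep_seed,
                "length": length,
                "gain_min": bounds.gain_min,
                "gain_max": bounds.gain_max,
                "loss_min": bounds.loss_min,
                "loss_max": bounds.loss_max,
            }
        )
        if best is None or bounds.gain_min < best:
            best = bounds.gain_min
            best_tree = resolved
    return best, table, best_tree
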