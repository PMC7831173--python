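"""Ancestral gene-family sizes by Wagner (linear-cost) parsimony.

Family counts at the leaves of a rooted species tree are propagated to
internal nodes so that the summed absolute change along branches is
minimal.  The bottom-up pass computes, per node, the convex piecewise-
linear cost profile over integer counts (equivalently the Farris interval
of optimal states); the top-down pass fixes point estimates: the root
takes the minimum of its optimal interval, every other node the value in
its optimal interval closest to its parent's assigned count.  Per-branch
gains and losses are the positive and negative parts of child - parent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "AncestralCountTree",
    "wagner_parsimony",
    "branch_events",
]


@dataclass
class NodeReconstruction:
    label: str
    count: int
    interval: tuple[int, int]  # optimal-state interval [lo, hi]
    is_leaf: bool
    parent_label: str | None
    delta: int | None  # count - parent count (None at root)


@dataclass
class AncestralCountTree:
    tree: dendropy.Tree
    nodes: dict[str, NodeReconstruction]
    root_label: str
    total_cost: int

    def annotated_newick(self) -> str:
        """Newick with reconstructed counts appended to node labels."""
        t = self.tree.clone(depth=1)
        for node in t.preorder_node_iter():
            label = _node_label(node)
            count = self.nodes[label].count
            if node.is_leaf():
                node.taxon.label = f"{node.taxon.label}_{count}"
            else:
                node.label = f"{label}_{count}"
        return t.as_string(schema="newick").strip()


def _node_label(node: dendropy.Node) -> str:
    if node.is_leaf():
        return node.taxon.label
    return node.label


def _ensure_labels(tree: dendropy.Tree) -> None:
    i = 0
    for node in tree.preorder_node_iter():
        if not node.is_leaf() and not node.label:
            node.label = f"node{i}"
            i += 1


def wagner_parsimony(
    tree: dendropy.Tree, leaf_counts: Mapping[str, int]
) -> AncestralCountTree:
    """Minimum total |change| reconstruction of integer counts on a tree.

    Works on rooted trees, including multifurcating ones, via dynamic
    programming over the integer states 0..max(leaf counts).  Raises if a
    leaf is missing a count or if the tree is explicitly unrooted.
    """
    if getattr(tree, "is_rooted", True) is False:
        raise ValueError("tree is unrooted; root it before reconstruction")
    tree = tree.clone(depth=1)
    tree.is_rooted = True
    _ensure_labels(tree)

    leaves = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    missing = [s for s in leaves if s not in leaf_counts]
    if missing:
        raise ValueError(f"leaf count missing for: {missing}")
    for s in leaves:
        if leaf_counts[s] < 0:
            raise ValueError(f"negative count for leaf '{s}'")

    max_state = max(leaf_counts[s] for s in leaves)
    states = np.arange(max_state + 1)

    # bottom-up: cost[node][x] = minimal subtree cost with node at count x
    cost: dict[dendropy.Node, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            cost[node] = np.abs(states - leaf_counts[node.taxon.label]).astype(float)
        else:
            total = np.zeros_like(states, dtype=float)
            for child in node.child_nodes():
                total += _flatten(cost[child])
            cost[node] = total

    nodes: dict[str, NodeReconstruction] = {}
    assigned: dict[dendropy.Node, int] = {}
    for node in tree.preorder_node_iter():
        c = cost[node]
        optimal = np.flatnonzero(c == c.min())
        lo, hi = int(optimal[0]), int(optimal[-1])
        if node.parent_node is None:
            value = lo  # root tie-break: minimum of its optimal interval
        else:
            parent_value = assigned[node.parent_node]
            value = min(max(parent_value, lo), hi)  # closest point in [lo, hi]
        assigned[node] = value
        label = _node_label(node)
        parent_label = (
            _node_label(node.parent_node) if node.parent_node is not None else None
        )
        nodes[label] = NodeReconstruction(
            label=label,
            count=value,
            interval=(lo, hi),
            is_leaf=node.is_leaf(),
            parent_label=parent_label,
            delta=(value - assigned[node.parent_node])
            if node.parent_node is not None
            else None,
        )

    total_cost = sum(abs(n.delta) for n in nodes.values() if n.delta is not None)
    root_label = _node_label(tree.seed_node)
    expected = int(cost[tree.seed_node].min())
    assert total_cost == expected, (
        f"assignment cost {total_cost} != DP minimum {expected}"
    )
    return AncestralCountTree(tree, nodes, root_label, total_cost)


def _flatten(c: np.ndarray) -> np.ndarray:
    """min_y c[y] + |x - y| for all x, by forward/backward sweeps."""
    out = c.copy()
    for i in range(1, len(out)):
        out[i] = min(out[i], out[i - 1] + 1)
    for i in range(len(out) - 2, -1, -1):
        out[i] = min(out[i], out[i + 1] + 1)
    return out


def branch_events(act: AncestralCountTree) -> pd.DataFrame:
    """Per-branch gains and losses: (max(delta,0), max(-delta,0))."""
    rows = []
    for rec in act.nodes.values():
        if rec.delta is None:
            continue
        rows.append(
            {
                "parent": rec.parent_label,
                "child": rec.label,
                "parent_count": act.nodes[rec.parent_label].count,
                "child_count": rec.count,
                "gain": max(rec.delta, 0),
                "loss": max(-rec.delta, 0),
            }
        )
    return pd.DataFrame(rows)
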