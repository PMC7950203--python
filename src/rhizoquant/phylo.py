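"""Distance-based neighbor-joining trees of mature NCR peptides.

Distances are p-distances on an externally produced peptide alignment
(pairwise gap deletion). Tree inference is classic Saitou-Nei neighbor
joining with deterministic tie-breaking (lexicographically smallest label
pair on equal Q) and negative limb lengths clamped to zero, so repeated runs
on identical input yield byte-identical Newick output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("distance matrix labels must be unique")
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match label count")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("distances must be non-negative")


@dataclass
class TreeNode:
    """A node of an unrooted tree (the root is a trifurcation for n >= 3)."""

    name: str | None = None
    branch_length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def min_leaf_label(self) -> str:
        return min(leaf.name or "" for leaf in self.leaves())


def p_distance(alignment: Sequence[tuple[str, str]]) -> DistanceMatrix:
    """Pairwise p-distances: mismatches over compared (mutually gap-free) columns.

    Columns where either sequence has a gap are ignored for that pair
    (pairwise deletion). A pair with no comparable column is an error.
    """
    if len(alignment) < 2:
        raise ValueError("alignment needs at least 2 sequences")
    labels = tuple(name for name, _ in alignment)
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate sequence labels in alignment")
    seqs = [seq.upper() for _, seq in alignment]
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("ragged alignment: sequences have unequal lengths")
    n = len(seqs)
    d = np.zeros((n, n))
    gaps = "-."
    for i in range(n):
        for j in range(i + 1, n):
            compared = mismatches = 0
            for a, b in zip(seqs[i], seqs[j]):
                if a in gaps or b in gaps:
                    continue
                compared += 1
                if a != b:
                    mismatches += 1
            if compared == 0:
                raise ValueError(
                    f"sequences {labels[i]!r} and {labels[j]!r} share no "
                    "comparable columns"
                )
            d[i, j] = d[j, i] = mismatches / compared
    return DistanceMatrix(labels, d)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining.

    Iteratively joins the pair (i, j) minimising
    Q(i, j) = (n - 2) d(i, j) - sum_k d(i, k) - sum_k d(j, k),
    with limb lengths from the standard formulas (negative values clamped to
    0). Q ties are broken by the lexicographically smallest pair of node
    labels, where an internal node is labelled by its smallest descendant
    leaf. Returns an unrooted tree as a trifurcating root.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=label) for label in dm.labels]
    keys: list[str] = list(dm.labels)
    d = dm.d.astype(float).copy()

    while len(nodes) > 3:
        m = len(nodes)
        row_sums = d.sum(axis=1)
        best: tuple[float, str, str, int, int] | None = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - row_sums[i] - row_sums[j]
                pair = tuple(sorted((keys[i], keys[j])))
                cand = (q, pair[0], pair[1], i, j)
                if best is None or cand[:3] < best[:3]:
                    best = cand
        _, _, _, i, j = best
        li = 0.5 * d[i, j] + (row_sums[i] - row_sums[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        child_i, child_j = nodes[i], nodes[j]
        child_i.branch_length = li
        child_j.branch_length = lj
        parent = TreeNode(children=[child_i, child_j])
        new_d = np.zeros((m - 1, m - 1))
        remaining = [k for k in range(m) if k not in (i, j)]
        for a, ka in enumerate(remaining):
            for b, kb in enumerate(remaining):
                new_d[a, b] = d[ka, kb]
            new_d[a, m - 2] = new_d[m - 2, a] = 0.5 * (d[ka, i] + d[ka, j] - d[i, j])
        nodes = [nodes[k] for k in remaining] + [parent]
        keys = [keys[k] for k in remaining] + [parent.min_leaf_label()]
        d = new_d

    # final trifurcation: limb lengths from the three-taxon closed form
    x = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    y = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    z = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    for node, limb in zip(nodes, (x, y, z)):
        node.branch_length = max(limb, 0.0)
    return TreeNode(children=nodes)


_NEWICK_UNQUOTED_FORBIDDEN = set(" \t\n()[]':;,")


def _format_label(label: str) -> str:
    if any(c in _NEWICK_UNQUOTED_FORBIDDEN for c in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _format_length(value: float) -> str:
    return f"{value:.6g}"


def _subtree_newick(node: TreeNode, with_length: bool = True) -> str:
    if node.is_leaf:
        text = _format_label(node.name or "")
    else:
        ordered = sorted(node.children, key=lambda c: c.min_leaf_label())
        text = "(" + ",".join(_subtree_newick(c) for c in ordered) + ")"
    if with_length:
        text += f":{_format_length(node.branch_length)}"
    return text


def write_newick(tree: TreeNode) -> str:
    """Serialise a tree to Newick with 6-significant-digit branch lengths.

    Child order is deterministic (sorted by smallest descendant leaf label);
    labels requiring it are single-quoted.
    """
    ordered = sorted(tree.children, key=lambda c: c.min_leaf_label())
    body = ",".join(_subtree_newick(c) for c in ordered)
    return f"({body});"


def tree_path_distances(tree: TreeNode) -> dict[tuple[str, str], float]:
    """Leaf-to-leaf path-length distances of a tree (for round-trip checks)."""
    dists: dict[tuple[str, str], float] = {}

    def walk(node: TreeNode) -> dict[str, float]:
        if node.is_leaf:
            return {node.name or "": 0.0}
        below: dict[str, float] = {}
        per_child = []
        for child in node.children:
            sub = {k: v + child.branch_length for k, v in walk(child).items()}
            per_child.append(sub)
        for a in range(len(per_child)):
            for b in range(a + 1, len(per_child)):
                for la, va in per_child[a].items():
                    for lb, vb in per_child[b].items():
                        key = tuple(sorted((la, lb)))
                        dists[key] = va + vb
            below.update(per_child[a])
        below.update(per_child[-1])
        return below

    walk(tree)
    return dists
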