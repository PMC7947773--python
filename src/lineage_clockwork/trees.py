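"""Rooted and unrooted tree structures, neighbor joining, and Newick export.

Trees are binary and rooted everywhere downstream of :func:`UnrootedTree.root_on`;
branch lengths are in expected substitutions per site. The neighbor-joining
implementation is deliberately deterministic: ties in the Q-matrix are broken by
taking the first (row-major, lowest-index) minimum, so identical inputs always
produce identical topologies.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

__all__ = [
    "Node",
    "UnrootedTree",
    "neighbor_joining",
    "postorder",
    "preorder",
    "tips",
    "newick",
    "tree_depths",
    "is_ultrametric",
]


class Node:
    """A node in a rooted tree.

    Attributes
    ----------
    name : str or None
        Tip label (internal nodes are unnamed unless annotated).
    length : float
        Length of the edge above this node (0 for the root).
    children : list of Node
    parent : Node or None
    """

    __slots__ = ("name", "length", "children", "parent")

    def __init__(self, name: str | None = None, length: float = 0.0):
        self.name = name
        self.length = float(length)
        self.children: list[Node] = []
        self.parent: Node | None = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_tip(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "tip" if self.is_tip else f"internal({len(self.children)})"
        return f"<Node {self.name or ''} {kind} len={self.length:.4g}>"


def postorder(root: Node) -> Iterator[Node]:
    """Yield nodes children-first (root last)."""
    stack, out = [root], []
    while stack:
        node = stack.pop()
        out.append(node)
        stack.extend(node.children)
    return iter(reversed(out))


def preorder(root: Node) -> Iterator[Node]:
    stack = [root]
    while stack:
        node = stack.pop()
        yield node
        stack.extend(reversed(node.children))


def tips(root: Node) -> list[Node]:
    return [n for n in postorder(root) if n.is_tip]


def newick(root: Node, digits: int = 10) -> str:
    """Serialize a rooted tree to a Newick string (deterministic formatting)."""

    def fmt(node: Node) -> str:
        if node.is_tip:
            label = node.name or ""
        else:
            label = "(" + ",".join(fmt(c) for c in node.children) + ")"
        if node.parent is None:
            return label
        return f"{label}:{node.length:.{digits}g}"

    return fmt(root) + ";"


def tree_depths(root: Node) -> dict[Node, float]:
    """Root-to-node path lengths."""
    depth: dict[Node, float] = {root: 0.0}
    for node in preorder(root):
        if node.parent is not None:
            depth[node] = depth[node.parent] + node.length
    return depth


def is_ultrametric(root: Node, rel_tol: float = 1e-8) -> bool:
    depth = tree_depths(root)
    d = np.array([depth[t] for t in tips(root)])
    scale = max(d.max(), 1e-300)
    return bool((d.max() - d.min()) / scale < rel_tol)


class UnrootedTree:
    """Adjacency representation of an unrooted tree (NJ output).

    Node ids 0..n_tips-1 are tips in the label order given at construction;
    larger ids are internal.
    """

    def __init__(self, edges: list[tuple[int, int, float]], labels: list[str]):
        self.edges = edges
        self.labels = list(labels)
        self.adj: dict[int, list[tuple[int, float]]] = {}
        for a, b, ln in edges:
            self.adj.setdefault(a, []).append((b, ln))
            self.adj.setdefault(b, []).append((a, ln))

    def root_on(self, tip_label: str) -> Node:
        """Root the tree on the edge leading to ``tip_label``.

        The root is placed at the midpoint of the outgroup's pendant edge. For
        molecular-clock fitting only the topology matters (node heights are
        re-optimized) and for the free model the likelihood is invariant to the
        root position along an edge.
        """
        try:
            tip_id = self.labels.index(tip_label)
        except ValueError:
            raise ValueError(f"outgroup sample {tip_label!r} not among tips") from None
        (nbr, ln), = self.adj[tip_id]
        root = Node()
        out = Node(self.labels[tip_id], ln / 2.0)
        root.add_child(out)
        root.add_child(self._orient(nbr, tip_id, ln / 2.0))
        return root

    def _orient(self, node_id: int, came_from: int, length: float) -> Node:
        name = self.labels[node_id] if node_id < len(self.labels) else None
        node = Node(name, length)
        for nbr, ln in self.adj[node_id]:
            if nbr != came_from:
                node.add_child(self._orient(nbr, node_id, ln))
        # collapse degree-2 pass-through nodes (can arise at the old NJ "root")
        if len(node.children) == 1:
            child = node.children[0]
            child.length += node.length
            child.parent = None
            return child
        return node


def neighbor_joining(dist: np.ndarray, labels: list[str]) -> UnrootedTree:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    Parameters
    ----------
    dist : (n, n) array
        Symmetric distance matrix.
    labels : list of str
        Tip names, one per row of ``dist``.

    Notes
    -----
    Negative branch lengths produced by the NJ formulas are clamped to zero.
    When several pairs minimize the Q criterion the lowest-index pair
    (row-major order of the working matrix) is joined.
    """
    n = len(labels)
    if n < 2:
        raise ValueError("need at least two taxa")
    if dist.shape != (n, n):
        raise ValueError("distance matrix does not match label count")
    cur = np.asarray(dist, dtype=float).copy()
    ids = list(range(n))
    next_id = n
    edges: list[tuple[int, int, float]] = []
    while len(ids) > 2:
        m = len(ids)
        r = cur.sum(axis=1)
        q = (m - 2) * cur - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = divmod(int(np.argmin(q)), m)
        if i > j:
            i, j = j, i
        d_ij = cur[i, j]
        li = 0.5 * d_ij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d_ij - li
        edges.append((ids[i], next_id, max(li, 0.0)))
        edges.append((ids[j], next_id, max(lj, 0.0)))
        dnew = 0.5 * (cur[i, :] + cur[j, :] - d_ij)
        keep = [x for x in range(m) if x not in (i, j)]
        nxt = np.empty((m - 1, m - 1))
        nxt[: m - 2, : m - 2] = cur[np.ix_(keep, keep)]
        nxt[: m - 2, m - 2] = dnew[keep]
        nxt[m - 2, : m - 2] = dnew[keep]
        nxt[m - 2, m - 2] = 0.0
        cur = nxt
        ids = [ids[x] for x in keep] + [next_id]
        next_id += 1
    edges.append((ids[0], ids[1], max(cur[0, 1], 0.0)))
    return UnrootedTree(edges, labels)
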