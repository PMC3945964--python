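"""Phylogenetic trees: neighbour-joining, rooting, and clade queries.

Trees carry the two tree-based identification rules and the screening of
unverified reference sequences.  Construction is classic neighbour joining
(Saitou & Nei agglomeration on the Q criterion); negative branch lengths,
which NJ can produce on non-additive matrices, are clamped to zero with the
deficit moved to the sibling branch so path lengths through the joined node
are preserved.
"""

from __future__ import annotations

import io
from typing import Iterator

import numpy as np
from Bio import Phylo


class Node:
    """A rooted tree node; ``length`` is the edge to the parent."""

    __slots__ = ("name", "length", "children", "parent")

    def __init__(self, name: str | None = None, length: float = 0.0):
        self.name = name
        self.length = float(length)
        self.children: list["Node"] = []
        self.parent: "Node | None" = None

    def add(self, child: "Node") -> None:
        child.parent = self
        self.children.append(child)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["Node"]:
        yield self
        for child in self.children:
            yield from child.walk()

    def leaf_names(self) -> frozenset[str]:
        return frozenset(n.name for n in self.walk() if n.is_leaf)


class PhyloTree:
    """A tree with uniquely named leaves and non-negative branch lengths."""

    def __init__(self, root: Node):
        self.root = root
        names = [n.name for n in root.walk() if n.is_leaf]
        if len(names) != len(set(names)):
            raise ValueError("leaf names are not unique")
        for node in root.walk():
            if not np.isfinite(node.length) or node.length < 0:
                raise ValueError(f"invalid branch length {node.length!r}")
        self._leaves = {n.name: n for n in root.walk() if n.is_leaf}

    @property
    def leaf_names(self) -> frozenset[str]:
        return frozenset(self._leaves)

    def leaf(self, name: str) -> Node:
        try:
            return self._leaves[name]
        except KeyError:
            raise KeyError(f"leaf {name!r} not in tree") from None

    # -- I/O ---------------------------------------------------------------

    def to_newick(self) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.10g}"
            inner = ",".join(fmt(c) for c in node.children)
            return f"({inner}):{node.length:.10g}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        bio = Phylo.read(io.StringIO(text), "newick")

        def convert(clade) -> Node:
            node = Node(clade.name, clade.branch_length or 0.0)
            for sub in clade.clades:
                node.add(convert(sub))
            return node

        return cls(convert(bio.root))

    @classmethod
    def read_newick(cls, path) -> "PhyloTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    # -- queries -----------------------------------------------------------

    def _adjacency(self) -> dict[int, list[tuple[Node, float]]]:
        adj: dict[int, list[tuple[Node, float]]] = {}
        for node in self.root.walk():
            adj.setdefault(id(node), [])
            for child in node.children:
                adj[id(node)].append((child, child.length))
                adj.setdefault(id(child), []).append((node, child.length))
        return adj

    def _distances_from(self, start: Node):
        """Distance and predecessor maps from one node over the whole tree."""
        adj = self._adjacency()
        dist = {id(start): 0.0}
        prev: dict[int, Node] = {}
        nodes = {id(start): start}
        stack = [start]
        while stack:
            node = stack.pop()
            for nbr, length in adj[id(node)]:
                if id(nbr) not in dist:
                    dist[id(nbr)] = dist[id(node)] + length
                    prev[id(nbr)] = node
                    nodes[id(nbr)] = nbr
                    stack.append(nbr)
        return dist, prev, nodes

    def leaf_distance_matrix(self) -> tuple[list[str], np.ndarray]:
        """Cophenetic (path-length) distances between all leaves."""
        names = sorted(self._leaves)
        out = np.zeros((len(names), len(names)))
        for i, name in enumerate(names):
            dist, _, _ = self._distances_from(self._leaves[name])
            for j, other in enumerate(names):
                out[i, j] = dist[id(self._leaves[other])]
        return names, out

    def sibling_directions(self, leaf_name: str) -> list[frozenset[str]]:
        """Leaf sets of each direction away from a leaf's attachment node.

        In an unrooted reading of the tree, the leaf's attachment node has
        one or two other directions; each is returned as the set of leaf
        names reachable that way.  These are the candidate sister clades of
        the leaf under every possible rooting.
        """
        leaf = self.leaf(leaf_name)
        v = leaf.parent
        if v is None:
            raise ValueError("tree has a single node")
        directions = [c.leaf_names() for c in v.children if c is not leaf]
        if v.parent is not None:
            rest = self.leaf_names - v.leaf_names()
            if rest:
                directions.append(frozenset(rest))
        return directions

    def ancestor_leaf_sets(self, leaf_name: str) -> list[frozenset[str]]:
        """Nested leaf sets of the leaf's ancestors, smallest first."""
        node = self.leaf(leaf_name).parent
        out = []
        while node is not None:
            out.append(node.leaf_names())
            node = node.parent
        return out

    # -- rooting -----------------------------------------------------------

    def midpoint_rooted(self) -> "PhyloTree":
        """Reroot at the midpoint of the longest leaf-to-leaf path."""
        leaves = list(self._leaves.values())
        if len(leaves) < 2:
            return PhyloTree(_copy_subtree(self.root, None, self._adjacency()))
        dist, _, _ = self._distances_from(leaves[0])
        far_a = max(leaves, key=lambda lf: dist[id(lf)])
        dist_a, prev_a, _ = self._distances_from(far_a)
        far_b = max(leaves, key=lambda lf: dist_a[id(lf)])
        total = dist_a[id(far_b)]
        half = total / 2.0

        # path from far_b back to far_a
        path = [far_b]
        while id(path[-1]) in prev_a:
            path.append(prev_a[id(path[-1])])
        path.reverse()  # far_a .. far_b

        adj = self._adjacency()
        cum = 0.0
        for u, v in zip(path, path[1:]):
            edge = next(l for nbr, l in adj[id(u)] if nbr is v)
            if cum + edge >= half - 1e-12:
                offset = half - cum
                root = Node()
                root.add(_copy_subtree(u, v, adj, length=max(offset, 0.0)))
                root.add(_copy_subtree(v, u, adj, length=max(edge - offset, 0.0)))
                return PhyloTree(root)
            cum += edge
        # degenerate (zero-length tree): root above the last node
        root = Node()
        root.add(_copy_subtree(path[-1], None, adj, length=0.0))
        return PhyloTree(root)


def _copy_subtree(node: Node, came_from: Node | None, adj, length: float = 0.0) -> Node:
    new = Node(node.name, length)
    for nbr, edge in adj[id(node)]:
        if nbr is not came_from:
            new.add(_copy_subtree(nbr, node, adj, length=edge))
    return new


def neighbor_joining(ids: list[str], matrix: np.ndarray) -> PhyloTree:
    """Neighbour-joining tree from a complete symmetric distance matrix.

    Requires >= 3 taxa.  Joins minimize the Q criterion; index-order ties
    resolve to the first (row-major) minimum for determinism.
    """
    n = len(ids)
    if n < 3:
        raise ValueError("neighbour joining requires at least 3 taxa")
    D = np.asarray(matrix, dtype=float).copy()
    if D.shape != (n, n):
        raise ValueError("matrix shape does not match ids")
    if not np.all(np.isfinite(D)):
        raise ValueError("matrix contains non-finite entries; impute first")
    nodes: list[Node] = [Node(name) for name in ids]

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = np.unravel_index(np.argmin(Q), Q.shape)
        if i > j:
            i, j = j, i
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        # clamp negatives, moving the deficit to the sibling branch
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = Node()
        child_i, child_j = nodes[i], nodes[j]
        child_i.length, child_j.length = li, lj
        parent.add(child_i)
        parent.add(child_j)
        dk = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        newD = np.empty((m - 1, m - 1))
        newD[:-1, :-1] = D[np.ix_(keep, keep)]
        newD[-1, :-1] = newD[:-1, -1] = dk[keep]
        newD[-1, -1] = 0.0
        nodes = [nodes[k] for k in keep] + [parent]
        D = newD

    # final trifurcation
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    lengths = [
        0.5 * (d01 + d02 - d12),
        0.5 * (d01 + d12 - d02),
        0.5 * (d02 + d12 - d01),
    ]
    root = Node()
    for node, length in zip(nodes, lengths):
        node.length = max(length, 0.0)
        root.add(node)
    return PhyloTree(root)
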