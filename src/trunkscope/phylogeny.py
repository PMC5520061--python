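"""Region phylogeny from binary mutation profiles.

Each tumor region is represented by the 0/1 vector of its presence-matrix
column; the matched germline is an all-zero outgroup (somatic mutations are by
definition absent from it). Pairwise distances are Hamming counts (or,
optionally, the p-distance, which rescales branch lengths but cannot change
the topology), the tree is built with the canonical neighbor-joining
algorithm, and the root is placed at the midpoint of the outgroup's pendant
edge.

Neighbor joining is consistent on additive distances: if the input matrix
equals the path lengths of some tree, that tree (topology and branch lengths)
is recovered exactly. Ties in the Q criterion are broken toward the
lexicographically first pair under the current node ordering, making the
output deterministic; negative branch lengths are clamped to zero with the
deficit moved to the sibling edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .classify import PresenceMatrix

OUTGROUP_LABEL = "germline"


@dataclass
class BinaryProfileSet:
    """Per-taxon boolean mutation profiles over an ordered site list."""

    taxa: list[str]
    profiles: np.ndarray  # bool, shape (n_taxa, n_sites)
    site_keys: list[tuple]

    def __post_init__(self) -> None:
        self.profiles = np.asarray(self.profiles, dtype=bool)
        if self.profiles.shape != (len(self.taxa), len(self.site_keys)):
            raise ValueError("profile matrix shape does not match taxa x sites")


def binary_profiles(
    m: PresenceMatrix, include_outgroup: bool = True
) -> BinaryProfileSet:
    """Region columns as profiles, plus an all-zero germline outgroup."""
    taxa = list(m.regions)
    profiles = m.values.T.copy()
    if include_outgroup:
        taxa.append(OUTGROUP_LABEL)
        profiles = np.vstack([profiles, np.zeros((1, m.n_sites), dtype=bool)])
    return BinaryProfileSet(taxa=taxa, profiles=profiles, site_keys=m.site_keys())


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray  # symmetric, nonnegative, zero diagonal

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match taxa")


def hamming_distance_matrix(
    p: BinaryProfileSet, metric: str = "count"
) -> DistanceMatrix:
    """Pairwise profile distances: absolute mismatch count or p-distance."""
    if metric not in ("count", "pdist"):
        raise ValueError(f"metric must be 'count' or 'pdist', got {metric!r}")
    x = p.profiles.astype(np.int64)
    # mismatches = x(1-y) + (1-x)y summed over sites
    d = (x[:, None, :] != x[None, :, :]).sum(axis=2).astype(float)
    if metric == "pdist":
        n_sites = max(1, x.shape[1])
        d = d / n_sites
    return DistanceMatrix(taxa=list(p.taxa), d=d)


@dataclass
class TreeNode:
    name: Optional[str] = None
    branch_length: Optional[float] = None
    children: list["TreeNode"] = field(default_factory=list)
    parent: Optional["TreeNode"] = None

    def add_child(self, child: "TreeNode", length: Optional[float]) -> None:
        child.parent = self
        child.branch_length = length
        self.children.append(child)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def copy(self) -> "TreeNode":
        node = TreeNode(name=self.name, branch_length=self.branch_length)
        for c in self.children:
            node.add_child(c.copy(), c.branch_length)
        return node


@dataclass
class PhyloTree:
    """Rooted representation of a (possibly unrooted) tree with branch lengths."""

    root: TreeNode

    def leaves(self) -> list[TreeNode]:
        return self.root.leaves()

    def leaf_names(self) -> list[str]:
        return [n.name or "" for n in self.leaves()]

    def find_leaf(self, name: str) -> TreeNode:
        for leaf in self.leaves():
            if leaf.name == name:
                return leaf
        raise KeyError(f"leaf {name!r} not found; have {self.leaf_names()}")

    def splits(self) -> set[frozenset]:
        """Bipartitions of the leaf set induced by internal edges.

        Each split is a frozenset of the two leaf-name frozensets, so the
        representation is rooting-invariant; trivial splits (single leaf vs
        rest) are excluded.
        """
        all_leaves = frozenset(self.leaf_names())
        out: set[frozenset] = set()

        def walk(node: TreeNode) -> frozenset:
            if node.is_leaf():
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c in node.children))
            if node.parent is not None and 1 < len(below) < len(all_leaves) - 1:
                out.add(frozenset([below, all_leaves - below]))
            return below

        walk(self.root)
        return out

    def copy(self) -> "PhyloTree":
        return PhyloTree(root=self.root.copy())


def _validate_distances(D: DistanceMatrix) -> np.ndarray:
    d = D.d
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    off = d[~np.eye(len(D.taxa), dtype=bool)]
    if (off < 0).any():
        raise ValueError("off-diagonal distances must be nonnegative")
    return d.astype(float).copy()


def neighbor_joining(D: DistanceMatrix) -> PhyloTree:
    """Canonical neighbor joining; deterministic under lexicographic tie-break."""
    n = len(D.taxa)
    if n < 2:
        raise ValueError("neighbor joining requires >= 2 taxa")
    d = _validate_distances(D)
    nodes: list[TreeNode] = [TreeNode(name=t) for t in D.taxa]

    if n == 2:
        root = TreeNode()
        root.add_child(nodes[0], d[0, 1] / 2.0)
        root.add_child(nodes[1], d[0, 1] / 2.0)
        return PhyloTree(root=root)

    active = list(range(n))
    dist = {(i, j): d[i, j] for i in range(n) for j in range(n) if i < j}

    def get(i: int, j: int) -> float:
        return dist[(i, j) if i < j else (j, i)]

    next_id = n
    while len(active) > 3:
        m = len(active)
        r = {i: sum(get(i, k) for k in active if k != i) for i in active}
        best: tuple[float, int, int] | None = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * get(i, j) - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, ai, aj)
        assert best is not None
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = get(i, j)
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:  # clamp, moving the deficit to the sibling edge
            li, lj = 0.0, dij
        elif lj < 0:
            li, lj = dij, 0.0
        new = TreeNode()
        new.add_child(nodes[i], li)
        new.add_child(nodes[j], lj)
        nodes.append(new)
        u = next_id
        next_id += 1
        for k in active:
            if k in (i, j):
                continue
            dist[(min(k, u), max(k, u))] = 0.5 * (get(i, k) + get(j, k) - dij)
        active = [k for k in active if k not in (i, j)] + [u]

    i, j, k = active
    a = 0.5 * (get(i, j) + get(i, k) - get(j, k))
    b = 0.5 * (get(i, j) + get(j, k) - get(i, k))
    c = 0.5 * (get(i, k) + get(j, k) - get(i, j))
    root = TreeNode()
    root.add_child(nodes[i], max(0.0, a))
    root.add_child(nodes[j], max(0.0, b))
    root.add_child(nodes[k], max(0.0, c))
    return PhyloTree(root=root)


def _reroot_at(node: TreeNode) -> TreeNode:
    """Reverse parent links so ``node`` becomes the root; splices a leftover
    degree-2 old root."""
    path = []
    cur = node
    while cur is not None:
        path.append(cur)
        cur = cur.parent
    # lengths of the edges path[i] -> path[i+1], captured before any rewiring
    orig_lengths = [child.branch_length for child in path[:-1]]
    for child, parent in zip(path, path[1:]):
        parent.children.remove(child)
    for (child, parent), length in zip(zip(path, path[1:]), orig_lengths):
        child.add_child(parent, length)
    node.parent = None
    node.branch_length = None
    old_root = path[-1]
    if old_root is not node and len(old_root.children) == 1:
        only = old_root.children[0]
        grand = old_root.parent
        assert grand is not None
        grand.children.remove(old_root)
        combined = (old_root.branch_length or 0.0) + (only.branch_length or 0.0)
        grand.add_child(only, combined)
    return node


def root_on_outgroup(t: PhyloTree, outgroup: str = OUTGROUP_LABEL) -> PhyloTree:
    """Root at the midpoint of the outgroup's pendant edge (input untouched)."""
    t = t.copy()
    leaf = t.find_leaf(outgroup)
    parent = leaf.parent
    if parent is None:
        raise ValueError("cannot root a single-leaf tree on its only leaf")
    b = leaf.branch_length or 0.0
    parent.children.remove(leaf)
    new_parent_root = _reroot_at(parent)
    ingroup_length = b / 2.0
    # splice a unary node left behind when the outgroup hung off a bifurcation
    if len(new_parent_root.children) == 1 and new_parent_root.name is None:
        only = new_parent_root.children[0]
        ingroup_length += only.branch_length or 0.0
        only.parent = None
        new_parent_root = only
    root = TreeNode()
    root.add_child(leaf, b / 2.0)
    root.add_child(new_parent_root, ingroup_length)
    return PhyloTree(root=root)


def unroot(t: PhyloTree) -> PhyloTree:
    """Suppress a degree-2 root by merging its two edges."""
    t = t.copy()
    root = t.root
    if len(root.children) != 2:
        return t
    a, b = root.children
    if a.is_leaf() and b.is_leaf():
        return t  # two-taxon tree stays as is
    keep, move = (a, b) if not a.is_leaf() else (b, a)
    combined = (a.branch_length or 0.0) + (b.branch_length or 0.0)
    keep.parent = None
    keep.branch_length = None
    keep.add_child(move, combined)
    return PhyloTree(root=keep)


def region_tree(
    m: PresenceMatrix,
    metric: str = "count",
    include_outgroup: bool = True,
    root: bool = True,
) -> PhyloTree:
    """Convenience composition: profiles -> distances -> NJ -> outgroup rooting."""
    profiles = binary_profiles(m, include_outgroup=include_outgroup)
    D = hamming_distance_matrix(profiles, metric=metric)
    tree = neighbor_joining(D)
    if root and include_outgroup:
        tree = root_on_outgroup(tree, OUTGROUP_LABEL)
    return tree


def ascii_tree(t: PhyloTree) -> str:
    """Small indented rendering for logs and reports."""
    lines: list[str] = []

    def walk(node: TreeNode, depth: int) -> None:
        label = node.name or "*"
        length = (
            f":{node.branch_length:.4g}" if node.branch_length is not None else ""
        )
        lines.append("  " * depth + label + length)
        for c in node.children:
            walk(c, depth + 1)

    walk(t.root, 0)
    return "\n".join(lines)
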