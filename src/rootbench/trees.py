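"""Tree data model, newick I/O, rerooting, and Robinson-Foulds machinery.

Two in-memory containers are used throughout the package:

* :class:`RootedTree` -- a rooted binary tree with branch lengths, used both
  for true (simulated) gene trees and for the output of rooting methods.
* :class:`UnrootedGeneTree` -- an unrooted binary tree (every internal node
  has degree 3) stored as an adjacency map; the object every rooting method
  consumes.

The rooted RF distance here is the clade-based count: half the size of the
symmetric difference between the two trees' clade sets.  For two rootings of
the *same* unrooted tree this equals the number of intermediate nodes on the
path between the two root edges, which is what makes the rooted RF a natural
measure of rooting error; :func:`root_path_distance` computes that node count
directly so the equivalence can be tested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional, Union

import dendropy

__all__ = [
    "TreeError",
    "NewickParseError",
    "TreeNode",
    "RootedTree",
    "UnrootedGeneTree",
    "RootPosition",
    "parse_newick",
    "write_newick",
    "root_at",
    "unroot",
    "rf_rooted",
    "rf_unrooted",
    "root_path_distance",
]


class TreeError(ValueError):
    """Invalid tree structure or operation."""


class NewickParseError(TreeError):
    """Malformed newick input."""


class TreeNode:
    """Node of a rooted tree; ``length`` is the branch above the node."""

    __slots__ = ("label", "length", "children", "parent", "time")

    def __init__(self, label: Optional[str] = None, length: float = 0.0):
        self.label = label
        self.length = float(length)
        self.children: list["TreeNode"] = []
        self.parent: Optional["TreeNode"] = None
        self.time: Optional[float] = None  # node age used by the simulator

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children


class RootedTree:
    """Rooted binary tree: every internal node, including the root, has
    exactly two children; leaf labels are unique strings."""

    def __init__(self, root: TreeNode, validate: bool = True):
        self.root = root
        if validate:
            self.validate()

    # -- traversal ---------------------------------------------------------

    def postorder(self) -> Iterator[TreeNode]:
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    # -- structure ---------------------------------------------------------

    def validate(self) -> None:
        labels = []
        for node in self.postorder():
            if node.is_leaf:
                if node.label is None:
                    raise TreeError("unlabeled leaf")
                labels.append(node.label)
            elif len(node.children) != 2:
                raise TreeError(
                    f"internal node has {len(node.children)} children; "
                    "trees must be binary"
                )
            if node.length < 0:
                raise TreeError("negative branch length")
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate leaf labels: {dup}")

    def copy(self) -> "RootedTree":
        def rec(node: TreeNode) -> TreeNode:
            new = TreeNode(node.label, node.length)
            new.time = node.time
            for c in node.children:
                new.add_child(rec(c))
            return new

        return RootedTree(rec(self.root), validate=False)

    def total_length(self) -> float:
        return sum(n.length for n in self.postorder() if n is not self.root)

    def clades(self) -> set[frozenset]:
        """Leaf-label sets below each internal node (root included)."""
        below: dict[TreeNode, frozenset] = {}
        out = set()
        for node in self.postorder():
            if node.is_leaf:
                below[node] = frozenset([node.label])
            else:
                below[node] = frozenset().union(*(below[c] for c in node.children))
                out.add(below[node])
        return out

    def splits(self) -> set[frozenset]:
        """Nontrivial bipartitions of the underlying unrooted topology,
        canonicalized as the side not containing the smallest leaf label."""
        labels = frozenset(self.leaf_labels())
        ref = min(labels)
        n = len(labels)
        out = set()
        below: dict[TreeNode, frozenset] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[node] = frozenset([node.label])
            else:
                below[node] = frozenset().union(*(below[c] for c in node.children))
                if node is not self.root:
                    side = below[node]
                    if 2 <= len(side) <= n - 2:
                        out.add(labels - side if ref in side else side)
        return out

    def __repr__(self) -> str:
        return f"<RootedTree with {self.n_leaves} leaves>"


@dataclass(frozen=True)
class RootPosition:
    """A point on an edge of an :class:`UnrootedGeneTree` where a root may be
    placed.  ``edge`` is canonicalized with the smaller node id first and
    ``fraction`` (in the open interval (0, 1)) is measured from that first
    endpoint.  ``topology_only`` marks positions produced by methods that
    ignore branch lengths (DTL and random rooting), for which the fraction is
    an arbitrary placeholder."""

    edge: tuple[int, int]
    fraction: float = 0.5
    topology_only: bool = False

    def __post_init__(self):
        u, v = self.edge
        if u > v:
            object.__setattr__(self, "edge", (v, u))
            object.__setattr__(self, "fraction", 1.0 - self.fraction)
        if not (0.0 < self.fraction < 1.0):
            raise TreeError(f"root fraction must be in (0,1), got {self.fraction}")


class UnrootedGeneTree:
    """Unrooted binary tree stored as an adjacency map.

    ``adj`` maps node id -> list of (neighbour id, branch length); ``labels``
    maps leaf node ids to their labels.  Internal nodes have degree exactly 3
    and leaves degree 1; at least 3 leaves are required.
    """

    def __init__(
        self,
        adj: dict[int, list[tuple[int, float]]],
        labels: dict[int, str],
        validate: bool = True,
    ):
        self.adj = adj
        self.labels = labels
        if validate:
            self.validate()

    def validate(self) -> None:
        n_nodes = len(self.adj)
        n_edges = sum(len(v) for v in self.adj.values())
        if n_edges % 2 != 0:
            raise TreeError("asymmetric adjacency")
        n_edges //= 2
        if n_edges != n_nodes - 1:
            raise TreeError("not a tree (edge count mismatch)")
        # connectivity
        seen = set()
        stack = [next(iter(self.adj))]
        while stack:
            u = stack.pop()
            if u in seen:
                continue
            seen.add(u)
            stack.extend(v for v, _ in self.adj[u] if v not in seen)
        if len(seen) != n_nodes:
            raise TreeError("tree is not connected")
        n_leaves = 0
        for u, nbrs in self.adj.items():
            deg = len(nbrs)
            if deg == 1:
                n_leaves += 1
                if u not in self.labels:
                    raise TreeError(f"leaf node {u} has no label")
            elif deg != 3:
                raise TreeError(f"internal node {u} has degree {deg}, expected 3")
            for _, length in nbrs:
                if length < 0:
                    raise TreeError("negative branch length")
        if n_leaves < 3:
            raise TreeError("unrooted trees need at least 3 leaves")
        if len(set(self.labels.values())) != len(self.labels):
            raise TreeError("duplicate leaf labels")

    # -- accessors ---------------------------------------------------------

    def nodes(self) -> list[int]:
        return sorted(self.adj)

    def leaf_ids(self) -> list[int]:
        return sorted(self.labels)

    def leaf_labels(self) -> list[str]:
        return [self.labels[i] for i in self.leaf_ids()]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def edges(self) -> list[tuple[int, int]]:
        """Edges as (u, v) pairs with u < v, sorted."""
        out = []
        for u, nbrs in self.adj.items():
            for v, _ in nbrs:
                if u < v:
                    out.append((u, v))
        return sorted(out)

    def edge_length(self, u: int, v: int) -> float:
        for w, length in self.adj[u]:
            if w == v:
                return length
        raise TreeError(f"edge ({u},{v}) not in tree")

    def has_edge(self, u: int, v: int) -> bool:
        return any(w == v for w, _ in self.adj.get(u, ()))

    def total_length(self) -> float:
        return sum(l for u, nbrs in self.adj.items() for v, l in nbrs if u < v)

    def splits(self) -> set[frozenset]:
        """Nontrivial bipartitions, canonicalized as in RootedTree.splits."""
        labels = frozenset(self.labels.values())
        ref = min(labels)
        n = len(labels)
        out = set()
        for (u, v) in self.edges():
            side = self.side_leaves(u, v)
            if 2 <= len(side) <= n - 2:
                out.add(labels - side if ref in side else side)
        return out

    def side_leaves(self, u: int, v: int) -> frozenset:
        """Labels of the leaves on the u side of edge (u, v)."""
        if not self.has_edge(u, v):
            raise TreeError(f"edge ({u},{v}) not in tree")
        seen = {v, u}
        stack = [u]
        out = []
        while stack:
            w = stack.pop()
            if w in self.labels:
                out.append(self.labels[w])
            for x, _ in self.adj[w]:
                if x not in seen:
                    seen.add(x)
                    stack.append(x)
        return frozenset(out)

    def __repr__(self) -> str:
        return f"<UnrootedGeneTree with {self.n_leaves} leaves>"


# ---------------------------------------------------------------------------
# newick I/O (parsing delegated to dendropy; strict binary trees only)
# ---------------------------------------------------------------------------


def _dendropy_to_node(dnode, default_length: float = 1.0) -> TreeNode:
    label = None
    if dnode.taxon is not None:
        label = dnode.taxon.label
    elif dnode.label is not None and not dnode.child_nodes():
        label = dnode.label
    length = dnode.edge.length
    node = TreeNode(label, default_length if length is None else length)
    for c in dnode.child_nodes():
        node.add_child(_dendropy_to_node(c, default_length))
    return node


def parse_newick(
    text: str, rooted_hint: Optional[bool] = None
) -> Union[RootedTree, UnrootedGeneTree]:
    """Parse a newick string into a tree.

    A basal bifurcation parses as a :class:`RootedTree`; a basal trifurcation
    parses as an :class:`UnrootedGeneTree`.  ``rooted_hint`` overrides the
    inference for bifurcating input: ``rooted_hint=False`` unroots a
    bifurcating tree.  All other multifurcations are rejected.  Missing branch
    lengths default to 1.0.  Underscores in unquoted labels are preserved
    verbatim.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        offset = getattr(exc, "column", None)
        loc = f" (near column {offset})" if offset is not None else ""
        raise NewickParseError(f"malformed newick{loc}: {exc}") from exc

    root = _dendropy_to_node(dtree.seed_node)
    root.length = 0.0
    ndeg = len(root.children)
    # reject multifurcations below the base
    for node in RootedTree(root, validate=False).postorder():
        if node is not root and node.children and len(node.children) != 2:
            raise TreeError("multifurcation; only binary trees are supported")

    labels = [n.label for n in RootedTree(root, validate=False).postorder() if n.is_leaf]
    if any(l is None for l in labels):
        raise NewickParseError("unlabeled leaf in newick input")
    if len(set(labels)) != len(labels):
        dup = sorted({l for l in labels if labels.count(l) > 1})
        raise TreeError(f"duplicate leaf labels: {dup}")

    if ndeg == 2:
        rtree = RootedTree(root)
        if rooted_hint is False:
            return unroot(rtree)
        return rtree
    if ndeg == 3:
        if rooted_hint is True:
            raise TreeError("basal trifurcation cannot be read as a rooted tree")
        return _unrooted_from_hub(root)
    raise TreeError(f"base of tree has degree {ndeg}; expected 2 or 3")


def _unrooted_from_hub(hub: TreeNode) -> UnrootedGeneTree:
    """Build adjacency from a rooted representation whose base node (degree 3)
    is an ordinary internal node of the unrooted tree."""
    adj: dict[int, list[tuple[int, float]]] = {}
    labels: dict[int, str] = {}
    counter = iter(range(10**9))

    def new_id() -> int:
        return next(counter)

    ids: dict[int, int] = {}

    def visit(node: TreeNode) -> int:
        nid = new_id()
        ids[id(node)] = nid
        adj[nid] = []
        if node.is_leaf:
            labels[nid] = node.label
        for c in node.children:
            cid = visit(c)
            adj[nid].append((cid, c.length))
            adj[cid].append((nid, c.length))
        return nid

    visit(hub)
    return UnrootedGeneTree(adj, labels)


def _format_length(x: float) -> str:
    return f"{x:.12g}"


_SAFE_LABEL = set("abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789_.-")


def _quote_label(label: str) -> str:
    if label and all(ch in _SAFE_LABEL for ch in label):
        return label
    return "'" + label.replace("'", "''") + "'"


def write_newick(tree: Union[RootedTree, UnrootedGeneTree]) -> str:
    """Serialize a tree to newick.  Rooted trees get a basal bifurcation,
    unrooted trees a basal trifurcation; round-trips through
    :func:`parse_newick`."""
    if isinstance(tree, RootedTree):

        def rec(node: TreeNode, top: bool = False) -> str:
            if node.is_leaf:
                body = _quote_label(node.label)
            else:
                body = "(" + ",".join(rec(c) for c in node.children) + ")"
            if top:
                return body
            return f"{body}:{_format_length(node.length)}"

        return rec(tree.root, top=True) + ";"

    if isinstance(tree, UnrootedGeneTree):
        return _write_unrooted(tree)

    raise TypeError(f"cannot serialize {type(tree).__name__}")


def _write_unrooted(tree: UnrootedGeneTree) -> str:
    hub = min(u for u, nbrs in tree.adj.items() if len(nbrs) == 3)

    def urec(u: int, parent: int, length: float) -> str:
        nbrs = [(v, l) for v, l in tree.adj[u] if v != parent]
        if not nbrs:
            body = _quote_label(tree.labels[u])
        else:
            body = "(" + ",".join(urec(v, u, l) for v, l in nbrs) + ")"
        return f"{body}:{_format_length(length)}"

    parts = [urec(v, hub, l) for v, l in tree.adj[hub]]
    return "(" + ",".join(parts) + ");"


# ---------------------------------------------------------------------------
# rerooting
# ---------------------------------------------------------------------------


def root_at(tree: UnrootedGeneTree, pos: RootPosition) -> RootedTree:
    """Root an unrooted tree by subdividing ``pos.edge`` at ``pos.fraction``.

    The two branch lengths incident to the new root sum to the original edge
    length; all other branch lengths and the leaf set are unchanged.
    """
    u, v = pos.edge
    if not tree.has_edge(u, v):
        raise TreeError(f"edge ({u},{v}) not in tree")
    ell = tree.edge_length(u, v)

    def build(node_id: int, come_from: int, length: float) -> TreeNode:
        node = TreeNode(tree.labels.get(node_id), length)
        for w, l in tree.adj[node_id]:
            if w != come_from:
                node.add_child(build(w, node_id, l))
        return node

    root = TreeNode(None, 0.0)
    root.add_child(build(u, v, pos.fraction * ell))
    root.add_child(build(v, u, (1.0 - pos.fraction) * ell))
    return RootedTree(root)


def unroot(
    tree: Union[RootedTree, UnrootedGeneTree],
    return_root_position: bool = False,
):
    """Suppress the root of a rooted tree, merging its two incident branches
    into a single edge.  Unrooted input is returned unchanged (a no-op).

    With ``return_root_position=True`` also returns the :class:`RootPosition`
    on the merged edge where the original root sat (fraction proportional to
    the two merged branch lengths; 0.5 if both are zero).
    """
    if isinstance(tree, UnrootedGeneTree):
        return (tree, None) if return_root_position else tree
    if tree.n_leaves < 3:
        raise TreeError("cannot unroot a tree with fewer than 3 leaves")

    counter = iter(range(10**9))
    adj: dict[int, list[tuple[int, float]]] = {}
    labels: dict[int, str] = {}

    def visit(node: TreeNode) -> int:
        nid = next(counter)
        adj[nid] = []
        if node.is_leaf:
            labels[nid] = node.label
        for c in node.children:
            cid = visit(c)
            adj[nid].append((cid, c.length))
            adj[cid].append((nid, c.length))
        return nid

    c1, c2 = tree.root.children
    id1 = visit(c1)
    id2 = visit(c2)
    merged = c1.length + c2.length
    adj[id1].append((id2, merged))
    adj[id2].append((id1, merged))
    utree = UnrootedGeneTree(adj, labels)
    if not return_root_position:
        return utree
    frac = 0.5 if merged == 0 else c1.length / merged
    lo, hi = (id1, id2) if id1 < id2 else (id2, id1)
    frac = frac if lo == id1 else 1.0 - frac
    frac = min(max(frac, 1e-12), 1.0 - 1e-12)
    return utree, RootPosition((lo, hi), frac)


# ---------------------------------------------------------------------------
# Robinson-Foulds distances
# ---------------------------------------------------------------------------


def _check_same_leaves(s1, s2) -> None:
    if s1 != s2:
        raise TreeError(
            "trees have differing leaf sets: "
            f"{sorted(s1 ^ s2)[:6]}{'...' if len(s1 ^ s2) > 6 else ''}"
        )


def rf_rooted(t1: RootedTree, t2: RootedTree) -> int:
    """Clade-based rooted RF distance: half the symmetric difference between
    the trees' clade sets.  Zero iff identical rooted topologies."""
    _check_same_leaves(frozenset(t1.leaf_labels()), frozenset(t2.leaf_labels()))
    diff = t1.clades() ^ t2.clades()
    assert len(diff) % 2 == 0
    return len(diff) // 2


def rf_unrooted(
    t1: Union[RootedTree, UnrootedGeneTree], t2: Union[RootedTree, UnrootedGeneTree]
) -> int:
    """Unrooted RF distance: half the symmetric difference between the trees'
    nontrivial bipartition sets."""

    def lset(t):
        return frozenset(t.leaf_labels())

    _check_same_leaves(lset(t1), lset(t2))
    diff = t1.splits() ^ t2.splits()
    assert len(diff) % 2 == 0
    return len(diff) // 2


def _bfs_path(tree: UnrootedGeneTree, src: int, dst: int) -> list[int]:
    prev = {src: None}
    stack = [src]
    while stack:
        u = stack.pop()
        if u == dst:
            break
        for v, _ in tree.adj[u]:
            if v not in prev:
                prev[v] = u
                stack.append(v)
    path = [dst]
    while prev[path[-1]] is not None:
        path.append(prev[path[-1]])
    return path[::-1]


def root_path_distance(
    tree: UnrootedGeneTree, e1: tuple[int, int], e2: tuple[int, int]
) -> int:
    """Number of intermediate nodes on the path between the farthest endpoints
    of the two edges.  This equals the rooted RF distance between the two
    rootings of ``tree`` placed on ``e1`` and ``e2``; zero iff e1 == e2."""
    e1 = tuple(sorted(e1))
    e2 = tuple(sorted(e2))
    for (u, v) in (e1, e2):
        if not tree.has_edge(u, v):
            raise TreeError(f"edge ({u},{v}) not in tree")
    if e1 == e2:
        return 0
    best = 0
    for a in e1:
        for b in e2:
            path = _bfs_path(tree, a, b)
            best = max(best, len(path))
    return best - 2
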