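"""Root-inference procedures for unrooted gene trees.

Five methods are provided:

* :func:`midpoint_root` -- root at the midpoint of the longest leaf-to-leaf
  path.
* :func:`mad_root` -- minimal ancestor deviation: minimize the root-mean-square
  relative deviation from a strict molecular clock over all leaf pairs.
* :func:`mv_root` -- minimum variance: minimize the variance of root-to-leaf
  distances.
* :func:`dtl_root` -- parsimonious duplication-transfer-loss reconciliation
  against a rooted (undated) species tree: root on the edge minimizing the
  reconciliation cost.
* :func:`random_root` -- a uniformly random edge; the baseline any serious
  method must beat.

Midpoint, MAD, and MV read branch lengths; DTL and random rooting use the
topology only.  MAD and MV scores restricted to a single edge are quadratic
in the root position, so the within-edge optimum is found in closed form and
the global optimum by scanning edges; ties within a relative tolerance of
1e-9 are all reported.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass

import numpy as np

from .trees import (
    RootPosition,
    RootedTree,
    TreeError,
    UnrootedGeneTree,
)

__all__ = [
    "EventCosts",
    "RootingResult",
    "midpoint_root",
    "mad_root",
    "mv_root",
    "dtl_reconciliation_cost",
    "dtl_root",
    "random_root",
]

_TIE_RTOL = 1e-9
_FRAC_EPS = 1e-12


@dataclass(frozen=True)
class EventCosts:
    """Unit costs for the parsimony DTL reconciliation.  The defaults
    <loss=1, duplication=2, transfer=3> are the standard choice for undated
    reconciliation."""

    loss_cost: float = 1.0
    duplication_cost: float = 2.0
    transfer_cost: float = 3.0

    def __post_init__(self):
        if min(self.loss_cost, self.duplication_cost, self.transfer_cost) < 0:
            raise ValueError("event costs must be nonnegative")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.loss_cost, self.duplication_cost, self.transfer_cost)


@dataclass
class RootingResult:
    """Optimal root positions found by one method on one tree.

    All listed positions achieve ``score`` (the method's objective at the
    optimum; ``None`` for random rooting, which has no objective)."""

    method: str
    positions: list[RootPosition]
    score: float | None = None

    def __post_init__(self):
        if not self.positions:
            raise ValueError("a RootingResult needs at least one position")
        self.positions = sorted(self.positions, key=lambda p: (p.edge, p.fraction))

    @property
    def tie_count(self) -> int:
        return len(self.positions)

    def pick(self, seed: int = 0) -> RootPosition:
        """Seeded arbitrary choice among tied optima (the convention used for
        simulated-data scoring)."""
        if len(self.positions) == 1:
            return self.positions[0]
        return random.Random(seed).choice(self.positions)


# ---------------------------------------------------------------------------
# shared geometry: leaf distances and per-edge side partitions
# ---------------------------------------------------------------------------


class _TreeGeometry:
    """Distances from every node to every leaf, the leaf-leaf distance matrix,
    and boolean leaf-side masks for each directed edge."""

    def __init__(self, tree: UnrootedGeneTree):
        self.tree = tree
        self.leaf_ids = tree.leaf_ids()
        self.n = len(self.leaf_ids)
        self.leaf_pos = {lid: i for i, lid in enumerate(self.leaf_ids)}
        nodes = tree.nodes()
        self.dist = {u: np.zeros(self.n) for u in nodes}
        for i, lid in enumerate(self.leaf_ids):
            seen = {lid}
            stack = [(lid, 0.0)]
            while stack:
                u, d = stack.pop()
                self.dist[u][i] = d
                for v, l in tree.adj[u]:
                    if v not in seen:
                        seen.add(v)
                        stack.append((v, d + l))
        self.D = np.vstack([self.dist[lid] for lid in self.leaf_ids])
        self._side: dict[tuple[int, int], np.ndarray] = {}

    def side_mask(self, u: int, v: int) -> np.ndarray:
        """Boolean mask (over leaf order) of leaves on the u side of (u,v)."""
        key = (u, v)
        if key not in self._side:
            mask = np.zeros(self.n, dtype=bool)
            seen = {v, u}
            stack = [u]
            while stack:
                w = stack.pop()
                if w in self.leaf_pos:
                    mask[self.leaf_pos[w]] = True
                for x, _ in self.tree.adj[w]:
                    if x not in seen:
                        seen.add(x)
                        stack.append(x)
            self._side[key] = mask
        return self._side[key]


def _clamp_fraction(f: float) -> float:
    return min(max(f, _FRAC_EPS), 1.0 - _FRAC_EPS)


def _canonical_position(u: int, v: int, frac_from_u: float) -> RootPosition:
    if u < v:
        return RootPosition((u, v), _clamp_fraction(frac_from_u))
    return RootPosition((v, u), _clamp_fraction(1.0 - frac_from_u))


def _collect_ties(
    per_edge: list[tuple[float, RootPosition]], method: str
) -> RootingResult:
    best = min(s for s, _ in per_edge)
    tol = _TIE_RTOL * max(abs(best), 1.0)
    positions = [p for s, p in per_edge if s <= best + tol]
    return RootingResult(method=method, positions=positions, score=best)


# ---------------------------------------------------------------------------
# midpoint rooting
# ---------------------------------------------------------------------------


def midpoint_root(tree: UnrootedGeneTree) -> RootingResult:
    """Root at the midpoint of a maximum-length leaf-to-leaf path.

    The returned score is half the diameter (the root-to-farthest-leaf
    distance).  If every branch has length zero the diameter is zero and all
    edges tie.  If several leaf pairs achieve the diameter, every distinct
    midpoint position is reported as a tie."""
    geo = _TreeGeometry(tree)
    D = geo.D
    diam = float(D.max())
    if diam <= 0.0:
        positions = [RootPosition(e, 0.5) for e in tree.edges()]
        return RootingResult("midpoint", positions, score=0.0)

    tol = _TIE_RTOL * diam
    pairs = np.argwhere(D >= diam - tol)
    positions: dict[tuple, RootPosition] = {}
    for bi, ci in pairs:
        if bi >= ci:
            continue
        b, c = geo.leaf_ids[bi], geo.leaf_ids[ci]
        path = _node_path(tree, b, c)
        target = D[bi, ci] / 2.0
        cum = 0.0
        for a, bnode in zip(path, path[1:]):
            l = tree.edge_length(a, bnode)
            if cum + l >= target - tol * 0.5 and l >= 0:
                frac = 0.5 if l == 0 else (target - cum) / l
                pos = _canonical_position(a, bnode, frac)
                key = (pos.edge, round(pos.fraction, 9))
                positions.setdefault(key, pos)
                break
            cum += l
    return RootingResult("midpoint", list(positions.values()), score=diam / 2.0)


def _node_path(tree: UnrootedGeneTree, src: int, dst: int) -> list[int]:
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


# ---------------------------------------------------------------------------
# MAD rooting
# ---------------------------------------------------------------------------


def mad_root(tree: UnrootedGeneTree) -> RootingResult:
    """Minimal ancestor deviation rooting.

    For a candidate root r and a leaf pair (b, c) whose paths to r diverge at
    the node alpha, the pair's relative deviation from a clock is
    ``|2 d(alpha,b)/d(b,c) - 1|``.  The candidate score is the
    root-mean-square deviation over all leaf pairs; pairs with d(b,c) = 0 are
    skipped (their deviation is undefined).  For pairs spanning the candidate
    edge the deviation depends on the root position rho, and the sum of their
    squared deviations is quadratic in rho, so the within-edge minimum is
    closed-form (clamped to the edge); pairs on one side of the edge
    contribute a rho-independent term.  The tree is rooted on the edge (and
    position) of global minimum score, with ties reported."""
    if tree.total_length() <= 0.0:
        raise TreeError("MAD rooting is undefined when all branch lengths are zero")
    geo = _TreeGeometry(tree)
    n = geo.n
    D = geo.D
    zero_pairs = int(((D <= 0).sum() - n) // 2)
    if zero_pairs:
        warnings.warn(
            f"MAD: skipping {zero_pairs} leaf pair(s) with zero path length",
            stacklevel=2,
        )

    # rho-independent same-side contribution for each directed edge side
    def same_side_ss(anchor: int, mask: np.ndarray) -> tuple[float, int]:
        idx = np.flatnonzero(mask)
        if len(idx) < 2:
            return 0.0, 0
        d = geo.dist[anchor][idx]
        Dsub = D[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), k=1)
        dbc = Dsub[iu]
        valid = dbc > 0
        dev = (d[:, None] - d[None, :])[iu][valid] / dbc[valid]
        return float(np.sum(dev * dev)), int(valid.sum())

    per_edge: list[tuple[float, RootPosition]] = []
    for (u, v) in tree.edges():
        ell = tree.edge_length(u, v)
        mask_u = geo.side_mask(u, v)
        mask_v = ~mask_u
        ss_u, n_u = same_side_ss(u, mask_u)
        ss_v, n_v = same_side_ss(v, mask_v)

        db = geo.dist[u][mask_u]
        dc = geo.dist[v][mask_v]
        dbc = db[:, None] + ell + dc[None, :]
        valid = dbc > 0
        p = np.where(valid, 2.0 * db[:, None] / np.where(valid, dbc, 1.0), 0.0)
        q = np.where(valid, 2.0 * ell / np.where(valid, dbc, 1.0), 0.0)
        den = float(np.sum(q * q))
        if den > 0:
            rho = float(np.sum(q * (1.0 - p)) / den)
            rho = min(max(rho, 0.0), 1.0)
        else:
            rho = 0.5
        resid = np.where(valid, p + rho * q - 1.0, 0.0)
        ss_span = float(np.sum(resid * resid))
        n_span = int(valid.sum())

        count = n_u + n_v + n_span
        score = float(np.sqrt((ss_u + ss_v + ss_span) / count))
        per_edge.append((score, _canonical_position(u, v, rho)))

    return _collect_ties(per_edge, "mad")


# ---------------------------------------------------------------------------
# MV rooting
# ---------------------------------------------------------------------------


def mv_root(tree: UnrootedGeneTree) -> RootingResult:
    """Minimum variance rooting: minimize the (population) variance of the
    distances from the root to all leaves.  On each edge the variance is
    quadratic in the root position, minimized in closed form and clamped."""
    geo = _TreeGeometry(tree)
    per_edge: list[tuple[float, RootPosition]] = []
    for (u, v) in tree.edges():
        ell = tree.edge_length(u, v)
        mask_u = geo.side_mask(u, v)
        base = np.where(mask_u, geo.dist[u], geo.dist[v] + ell)
        sign = np.where(mask_u, 1.0, -1.0)
        var_s = float(np.var(sign))
        cov = float(np.mean(base * sign) - np.mean(base) * np.mean(sign))
        if var_s > 0:
            x = min(max(-cov / var_s, 0.0), ell)
        else:  # cannot happen for a proper edge, kept for safety
            x = ell / 2.0
        score = float(np.var(base + sign * x))
        frac = 0.5 if ell == 0 else x / ell
        per_edge.append((score, _canonical_position(u, v, frac)))
    return _collect_ties(per_edge, "mv")


# ---------------------------------------------------------------------------
# random rooting
# ---------------------------------------------------------------------------


def random_root(tree: UnrootedGeneTree, seed: int) -> RootingResult:
    """Root at a uniformly random edge (fraction 0.5); deterministic per
    seed.  The baseline against which real methods are compared."""
    rng = random.Random(seed)
    edge = rng.choice(tree.edges())
    return RootingResult(
        "random", [RootPosition(edge, 0.5, topology_only=True)], score=None
    )


# ---------------------------------------------------------------------------
# DTL reconciliation
# ---------------------------------------------------------------------------


class _SpeciesIndex:
    """Postorder-indexed arrays over the species tree used by the DTL dynamic
    program, with nodes grouped into levels so the "best in subtree" and
    "best at incomparable nodes" passes vectorize."""

    def __init__(self, stree: RootedTree):
        self.post = list(stree.postorder())
        self.S = len(self.post)
        idx = {id(n): i for i, n in enumerate(self.post)}
        self.left = np.full(self.S, -1, dtype=np.int64)
        self.right = np.full(self.S, -1, dtype=np.int64)
        parent = np.full(self.S, -1, dtype=np.int64)
        sib = np.full(self.S, -1, dtype=np.int64)
        self.leaf_index: dict[str, int] = {}
        height = np.zeros(self.S, dtype=np.int64)
        for i, node in enumerate(self.post):
            if node.is_leaf:
                self.leaf_index[node.label] = i
            else:
                l, r = (idx[id(c)] for c in node.children)
                self.left[i], self.right[i] = l, r
                parent[l] = parent[r] = i
                sib[l], sib[r] = r, l
                height[i] = 1 + max(height[l], height[r])
        self.internal = np.flatnonzero(self.left >= 0)
        # bottom-up levels for the in/min passes
        self.levels_up: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
        for h in range(1, int(height.max()) + 1 if self.S > 1 else 1):
            ii = np.flatnonzero(height == h)
            self.levels_up.append((ii, self.left[ii], self.right[ii]))
        # top-down levels for the out pass
        depth = np.zeros(self.S, dtype=np.int64)
        root = self.S - 1
        order = [root]
        for i in reversed(range(self.S)):  # preorder works in reverse postorder
            if parent[i] >= 0:
                depth[i] = depth[parent[i]] + 1
        self.levels_down: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
        for d in range(1, int(depth.max()) + 1 if self.S > 1 else 1):
            ii = np.flatnonzero(depth == d)
            self.levels_down.append((ii, parent[ii], sib[ii]))


class _DTLTables:
    __slots__ = ("inn", "out")

    def __init__(self, inn: np.ndarray, out: np.ndarray):
        self.inn = inn
        self.out = out


class _DTLEngine:
    """Dynamic program for the undated DTL reconciliation cost.

    For a gene subtree g and species node s the recurrence takes the cheapest
    of speciation (children sent into the two distinct child subtrees of s,
    one loss per species edge skipped), duplication (both children at or
    below s), and transfer (one child at or below s, the other at any species
    node incomparable to s).  ``inn[g][s]`` is the best cost with g mapped at
    or below s (losses charged along the way); ``out[g][s]`` the best cost of
    mapping g anywhere incomparable to s.  Tables for directed gene subtrees
    are shared between the rootings on different edges, so evaluating every
    rooting costs about as much as four single rootings."""

    def __init__(self, stree: RootedTree, costs: EventCosts):
        self.sp = _SpeciesIndex(stree)
        self.costs = costs

    # -- per-subtree table construction ------------------------------------

    def _finish(self, c: np.ndarray) -> _DTLTables:
        sp, lc = self.sp, self.costs.loss_cost
        inn = c.copy()
        m = c.copy()
        for ii, l, r in sp.levels_up:
            inn[ii] = np.minimum(c[ii], np.minimum(inn[l], inn[r]) + lc)
            m[ii] = np.minimum(c[ii], np.minimum(m[l], m[r]))
        out = np.full(sp.S, np.inf)
        for ii, par, s in sp.levels_down:
            out[ii] = np.minimum(out[par], m[s])
        return _DTLTables(inn, out)

    def leaf_tables(self, species_label: str) -> _DTLTables:
        try:
            si = self.sp.leaf_index[species_label]
        except KeyError:
            raise TreeError(
                f"species {species_label!r} is not a leaf of the species tree"
            ) from None
        c = np.full(self.sp.S, np.inf)
        c[si] = 0.0
        return self._finish(c)

    def combine(self, a: _DTLTables, b: _DTLTables) -> np.ndarray:
        """Cost vector (over species nodes) for a gene node whose two child
        subtrees have tables ``a`` and ``b``."""
        sp = self.sp
        dup = self.costs.duplication_cost + a.inn + b.inn
        tr = self.costs.transfer_cost + np.minimum(a.inn + b.out, b.inn + a.out)
        c = np.minimum(dup, tr)
        ii = sp.internal
        l, r = sp.left[ii], sp.right[ii]
        spec = np.minimum(a.inn[l] + b.inn[r], a.inn[r] + b.inn[l])
        c[ii] = np.minimum(c[ii], spec)
        return c

    def subtree_tables(self, c: np.ndarray) -> _DTLTables:
        return self._finish(c)

    # -- rooted cost -------------------------------------------------------

    def cost_rooted(self, gtree: RootedTree, mapping: dict[str, str]) -> float:
        tables: dict[int, _DTLTables] = {}
        for node in gtree.postorder():
            if node.is_leaf:
                if node.label not in mapping:
                    raise TreeError(f"gene leaf {node.label!r} has no species mapping")
                t = self.leaf_tables(mapping[node.label])
            else:
                ca, cb = node.children
                t = self.subtree_tables(
                    self.combine(tables[id(ca)], tables[id(cb)])
                )
            tables[id(node)] = t
        root = gtree.root
        ca, cb = root.children
        c_root = self.combine(tables[id(ca)], tables[id(cb)])
        best = float(c_root.min())
        if not np.isfinite(best):
            raise TreeError("infeasible leaf mapping: no reconciliation exists")
        return best

    # -- all rootings ------------------------------------------------------

    def all_edge_costs(
        self, utree: UnrootedGeneTree, mapping: dict[str, str]
    ) -> dict[tuple[int, int], float]:
        """Minimum reconciliation cost of the rooting on each edge."""
        for lid, label in utree.labels.items():
            if label not in mapping:
                raise TreeError(f"gene leaf {label!r} has no species mapping")

        # order directed edges (u away from v) by subtree size
        size: dict[tuple[int, int], int] = {}

        def subtree_size(u: int, v: int) -> int:
            key = (u, v)
            if key not in size:
                stack = [(u, v, False)]
                while stack:
                    uu, vv, done = stack.pop()
                    kk = (uu, vv)
                    kids = [(w, uu) for w, _ in utree.adj[uu] if w != vv]
                    if done or not kids:
                        size[kk] = 1 + sum(size[k] for k in kids)
                    else:
                        stack.append((uu, vv, True))
                        stack.extend((w, p, False) for w, p in kids if (w, p) not in size)
            return size[key]

        for u, v in utree.edges():
            subtree_size(u, v)
            subtree_size(v, u)

        tables: dict[tuple[int, int], _DTLTables] = {}
        for key in sorted(size, key=lambda k: size[k]):
            u, v = key
            kids = [(w, u) for w, _ in utree.adj[u] if w != v]
            if not kids:
                tables[key] = self.leaf_tables(mapping[utree.labels[u]])
            else:
                (k1, k2) = kids
                tables[key] = self.subtree_tables(
                    self.combine(tables[k1], tables[k2])
                )

        out: dict[tuple[int, int], float] = {}
        for (u, v) in utree.edges():
            c = self.combine(tables[(u, v)], tables[(v, u)])
            best = float(c.min())
            if not np.isfinite(best):
                raise TreeError("infeasible leaf mapping: no reconciliation exists")
            out[(u, v)] = best
        return out


def dtl_reconciliation_cost(
    gtree: RootedTree,
    stree: RootedTree,
    mapping: dict[str, str],
    costs: EventCosts = EventCosts(),
) -> float:
    """Minimum duplication-transfer-loss reconciliation cost of a rooted gene
    tree against a rooted species tree used as topology only (undated model:
    a transfer recipient must be incomparable to the donor -- neither its
    ancestor nor its descendant).  ``mapping`` sends each gene leaf label to a
    species leaf label."""
    return _DTLEngine(stree, costs).cost_rooted(gtree, mapping)


def dtl_root(
    gtree: UnrootedGeneTree,
    stree: RootedTree,
    mapping: dict[str, str],
    costs: EventCosts = EventCosts(),
) -> RootingResult:
    """Evaluate the DTL reconciliation cost of the rooting on every edge of
    the gene tree and return all cost-minimizing edges (topology-only
    positions).  Costs are compared exactly when all unit costs are integers,
    else within a relative tolerance of 1e-9."""
    engine = _DTLEngine(stree, costs)
    per_edge = engine.all_edge_costs(gtree, mapping)
    best = min(per_edge.values())
    integral = all(float(x).is_integer() for x in costs.as_tuple())
    tol = 0.0 if integral else _TIE_RTOL * max(abs(best), 1.0)
    positions = [
        RootPosition(e, 0.5, topology_only=True)
        for e, c in sorted(per_edge.items())
        if c <= best + tol
    ]
    return RootingResult("dtl", positions, score=best)
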