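"""Independent oracles used by the test suite.

These deliberately avoid the implementation's code paths: the DTL oracle
enumerates every assignment of gene nodes to species nodes from the event
definitions; the MAD/MV oracles minimize by dense grid search instead of the
closed form; RF oracles go through dendropy.
"""

from __future__ import annotations

import numpy as np

from rootbench.rooting import EventCosts
from rootbench.trees import RootedTree, UnrootedGeneTree


# ---------------------------------------------------------------------------
# brute-force DTL reconciliation by full mapping enumeration
# ---------------------------------------------------------------------------


def brute_force_dtl_cost(
    gtree: RootedTree,
    stree: RootedTree,
    mapping: dict[str, str],
    costs: EventCosts,
) -> float:
    """Minimum reconciliation cost by enumerating every mapping of internal
    gene nodes to species nodes and charging each gene node the cheapest
    feasible event (speciation / duplication / transfer) given its own and
    its children's assignments.  Exponential; for tiny instances only."""
    post = list(stree.postorder())
    S = len(post)
    idx = {id(n): i for i, n in enumerate(post)}
    # ancestry and downward edge-distance tables from first principles
    anc = np.zeros((S, S), dtype=bool)
    dist = np.full((S, S), np.inf)
    for i, node in enumerate(post):
        stack = [(node, 0)]
        while stack:
            cur, d = stack.pop()
            j = idx[id(cur)]
            anc[i, j] = True
            dist[i, j] = d
            for c in cur.children:
                stack.append((c, d + 1))
    incomp = ~anc & ~anc.T

    lc, dc, tc = costs.loss_cost, costs.duplication_cost, costs.transfer_cost
    L = np.full((S, S, S), np.inf)
    for s, snode in enumerate(post):
        for sa in range(S):
            for sb in range(S):
                opts = []
                if snode.children:
                    l, r = (idx[id(c)] for c in snode.children)
                    if anc[l, sa] and anc[r, sb]:
                        opts.append(lc * (dist[l, sa] + dist[r, sb]))
                    if anc[l, sb] and anc[r, sa]:
                        opts.append(lc * (dist[l, sb] + dist[r, sa]))
                if anc[s, sa] and anc[s, sb]:
                    opts.append(dc + lc * (dist[s, sa] + dist[s, sb]))
                if anc[s, sa] and incomp[s, sb]:
                    opts.append(tc + lc * dist[s, sa])
                if anc[s, sb] and incomp[s, sa]:
                    opts.append(tc + lc * dist[s, sb])
                if opts:
                    L[s, sa, sb] = min(opts)

    leaf_index = {n.label: idx[id(n)] for n in post if n.is_leaf}
    gpost = list(gtree.postorder())
    internals = [g for g in gpost if not g.is_leaf]
    axis = {id(g): a for a, g in enumerate(internals)}
    k = len(internals)
    shape = (S,) * k

    def node_index(g, a_self):
        """Index array (broadcastable over the mapping grid) for node g."""
        if g.is_leaf:
            return np.full((1,) * k, leaf_index[mapping[g.label]])
        ax = axis[id(g)]
        sh = [1] * k
        sh[ax] = S
        return np.arange(S).reshape(sh)

    total = np.zeros(shape)
    for g in internals:
        a, b = g.children
        ig = node_index(g, None)
        ia = node_index(a, None)
        ib = node_index(b, None)
        total = total + L[ig, ia, ib]
    return float(total.min())


# ---------------------------------------------------------------------------
# grid-search scorers for MAD and MV
# ---------------------------------------------------------------------------


def _distances(tree: UnrootedGeneTree):
    leaf_ids = tree.leaf_ids()
    pos = {l: i for i, l in enumerate(leaf_ids)}
    n = len(leaf_ids)
    dist = {}
    for u in tree.nodes():
        seen = {u}
        stack = [(u, 0.0)]
        row = np.zeros(n)
        while stack:
            w, d = stack.pop()
            if w in pos:
                row[pos[w]] = d
            for x, l in tree.adj[w]:
                if x not in seen:
                    seen.add(x)
                    stack.append((x, d + l))
        dist[u] = row
    return leaf_ids, pos, dist


def _pair_divergence_toward(tree, b, c, anchor):
    """The node on the b..c path closest to ``anchor`` (their divergence
    point when the root lies beyond ``anchor``)."""
    prev = {b: None}
    stack = [b]
    while stack:
        u = stack.pop()
        for v, _ in tree.adj[u]:
            if v not in prev:
                prev[v] = u
                stack.append(v)
    path = [c]
    while prev[path[-1]] is not None:
        path.append(prev[path[-1]])
    # distances from anchor to every node
    dd = {anchor: 0.0}
    stack = [(anchor, 0.0)]
    seen = {anchor}
    while stack:
        u, d = stack.pop()
        for v, l in tree.adj[u]:
            if v not in seen:
                seen.add(v)
                dd[v] = d + l
                stack.append((v, d + l))
    return min(path, key=lambda nd: dd[nd])


def mad_grid_search(tree: UnrootedGeneTree, edge, n_grid: int = 10000):
    """(best_rho, best_score) for the MAD objective on one edge, by dense
    evaluation of the definition at n_grid+1 equally spaced positions."""
    u, v = edge
    ell = tree.edge_length(u, v)
    leaf_ids, pos, dist = _distances(tree)
    mask_u = np.zeros(len(leaf_ids), dtype=bool)
    side = tree.side_leaves(u, v)
    labels = {i: tree.labels[i] for i in leaf_ids}
    for lid in leaf_ids:
        mask_u[pos[lid]] = labels[lid] in side

    rhos = np.linspace(0.0, 1.0, n_grid + 1)
    sq_sum = np.zeros_like(rhos)
    count = 0
    n = len(leaf_ids)
    for i in range(n):
        for j in range(i + 1, n):
            bi, ci = leaf_ids[i], leaf_ids[j]
            dbc = dist[bi][pos[ci]]
            if dbc <= 0:
                continue
            count += 1
            if mask_u[pos[bi]] != mask_u[pos[ci]]:
                # spanning pair: ancestor is the candidate root point
                b_on_u = mask_u[pos[bi]]
                db = dist[u][pos[bi]] if b_on_u else dist[u][pos[ci]]
                dev = np.abs(2.0 * (db + rhos * ell) / dbc - 1.0)
            else:
                anchor = u if mask_u[pos[bi]] else v
                alpha = _pair_divergence_toward(tree, bi, ci, anchor)
                dev = np.full_like(rhos, abs(2.0 * dist[alpha][pos[bi]] / dbc - 1.0))
            sq_sum = sq_sum + dev * dev
    scores = np.sqrt(sq_sum / count)
    best = int(np.argmin(scores))
    return float(rhos[best]), float(scores[best])


def mv_grid_search(tree: UnrootedGeneTree, edge, n_grid: int = 10000):
    """(best_rho, best_score) for the root-to-leaf distance variance on one
    edge by dense grid evaluation."""
    u, v = edge
    ell = tree.edge_length(u, v)
    leaf_ids, pos, dist = _distances(tree)
    side = tree.side_leaves(u, v)
    labels = {i: tree.labels[i] for i in leaf_ids}
    on_u = np.array([labels[l] in side for l in leaf_ids])
    du = dist[u]
    dv = dist[v]
    rhos = np.linspace(0.0, 1.0, n_grid + 1)
    d = np.where(on_u[None, :], du[None, :] + rhos[:, None] * ell,
                 dv[None, :] + (1.0 - rhos[:, None]) * ell)
    scores = d.var(axis=1)
    best = int(np.argmin(scores))
    return float(rhos[best]), float(scores[best])


# ---------------------------------------------------------------------------
# dendropy RF oracle
# ---------------------------------------------------------------------------


def dendropy_rf(newick1: str, newick2: str, rooted: bool) -> int:
    import dendropy
    from dendropy.calculate import treecompare

    tns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=newick1, schema="newick", taxon_namespace=tns,
                           preserve_underscores=True)
    t2 = dendropy.Tree.get(data=newick2, schema="newick", taxon_namespace=tns,
                           preserve_underscores=True)
    t1.is_rooted = rooted
    t2.is_rooted = rooted
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    sd = treecompare.symmetric_difference(t1, t2)
    assert sd % 2 == 0
    return sd // 2
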