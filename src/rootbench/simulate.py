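"""Synthetic gene-family generator.

Gene families evolve inside a rooted ultrametric species tree (height 1)
produced by a birth-death process conditioned on the number of extant taxa.
A single gene lineage enters at the species root and evolves along species
branches; duplication, transfer, and loss events arrive as a Poisson process
whose rates are expressed per unit branch length (equivalently per unit time,
since the species tree has height 1).  A duplication bifurcates the lineage in
place, a loss terminates it, and a transfer copies it onto a contemporaneous
recipient species branch chosen uniformly among branches alive at the event
time (the donor excluded).  A transfer is *additive* with probability
``additive_fraction`` and otherwise *replacing* (xenologous gene
displacement): a replacing transfer removes one uniformly chosen gene
lineage present in the recipient branch at the event time.  Because a
replacement requires a homolog to displace, the default recipient choice for
replacing transfers (``replacing_rule="occupied"``) is uniform over the
contemporaneous branches that carry at least one gene copy, the event
lapsing when no branch does; the alternative rules ``"degrade"`` (an empty
recipient turns the transfer additive) and ``"skip"`` (an empty recipient
cancels the event) sample recipients over all contemporaneous branches.
Lineages split at speciation nodes; at time 1 surviving lineages become the
extant gene copies.  Dead subtrees are pruned, degree-2 nodes suppressed, and
the surviving rooted gene tree -- ultrametric with all leaves at time 1 --
is returned together with an event log.

The loss rate is tied to the gain rates as
``0.8 * (duplication_rate + additive_fraction * transfer_rate_total)``,
modelling slowly expanding gene families.

Simulation is event-driven in global time order, which is what makes
replacing transfers well-defined (the victim must be drawn from the gene
copies actually present in the recipient at the moment of transfer).
"""

from __future__ import annotations

import heapq
import math
import random
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .trees import RootPosition, RootedTree, TreeError, TreeNode, UnrootedGeneTree, root_at, unroot

try:  # dendropy's simulator lives in a submodule
    from dendropy.simulate import treesim
except ImportError:  # pragma: no cover
    treesim = None

__all__ = [
    "EventRates",
    "ScalingScheme",
    "SpeciesTreeTimed",
    "GeneEvent",
    "GeneFamilyHistory",
    "simulate_species_tree",
    "simulate_gene_history",
    "scale_branches",
    "perturb_topology",
    "summarize_families",
    "SUMMARY_COLUMNS",
]

SUMMARY_COLUMNS = [
    "Leaves",
    "Duplications",
    "Losses",
    "Additive Transfers",
    "Replacing Transfers",
]


@dataclass(frozen=True)
class EventRates:
    """Per-unit-branch-length event rates for the gene family process, plus
    the birth/death rates of the species-tree process.

    ``loss_rate`` is derived, not free:
    ``0.8 * (duplication_rate + additive_fraction * transfer_rate_total)``.
    """

    duplication_rate: float
    transfer_rate_total: float
    additive_fraction: float = 0.3
    birth_rate: float = 5.0
    death_rate: float = 1.0
    replacing_rule: str = "occupied"

    def __post_init__(self):
        if self.duplication_rate < 0 or self.transfer_rate_total < 0:
            raise ValueError("rates must be nonnegative")
        if not (0.0 <= self.additive_fraction <= 1.0):
            raise ValueError("additive_fraction must be in [0,1]")
        if self.replacing_rule not in ("occupied", "degrade", "skip"):
            raise ValueError(
                "replacing_rule must be 'occupied', 'degrade', or 'skip'"
            )

    @property
    def additive_rate(self) -> float:
        return self.additive_fraction * self.transfer_rate_total

    @property
    def replacing_rate(self) -> float:
        return (1.0 - self.additive_fraction) * self.transfer_rate_total

    @property
    def loss_rate(self) -> float:
        return 0.8 * (self.duplication_rate + self.additive_rate)

    @property
    def total_rate(self) -> float:
        return self.duplication_rate + self.transfer_rate_total + self.loss_rate


@dataclass(frozen=True)
class ScalingScheme:
    """Branch-scaling scheme applied to true gene trees to emulate
    substitution-rate variation.

    ``uniform``: each branch multiplied by an independent Uniform[lo, hi]
    draw.  ``autocorrelated``: the Rannala-Yang lognormal relaxed clock --
    the root carries ``start_rate``; each child node's rate is a lognormal
    step around its parent's rate with variance ``sigma2 * dt`` on the log
    scale (mean-preserving, offset ``-sigma2*dt/2``), where ``dt`` is the
    time separating the two nodes; each branch is multiplied by its child
    node's rate.  ``time_scaled=False`` switches to a constant per-edge
    variance of ``sigma2`` regardless of branch duration.
    """

    kind: str = "none"  # none | uniform | autocorrelated
    lo: float = 1.0
    hi: float = 1.0
    start_rate: float = 1.0
    sigma2: float = 0.0
    time_scaled: bool = True

    def __post_init__(self):
        if self.kind not in ("none", "uniform", "autocorrelated"):
            raise ValueError(f"unknown scaling scheme kind {self.kind!r}")
        if self.kind == "uniform" and not (0 < self.lo <= self.hi):
            raise ValueError("uniform scaling needs 0 < lo <= hi")
        if self.kind == "autocorrelated" and (self.sigma2 < 0 or self.start_rate <= 0):
            raise ValueError("autocorrelated scaling needs sigma2 >= 0, start_rate > 0")

    @property
    def name(self) -> str:
        if self.kind == "uniform":
            return f"uniform[{self.lo:g},{self.hi:g}]"
        if self.kind == "autocorrelated":
            return f"auto[{self.start_rate:g},{self.sigma2:g}]"
        return "none"


class SpeciesTreeTimed:
    """Rooted ultrametric species tree with node times: root at time 0, all
    leaves at time 1."""

    def __init__(self, tree: RootedTree):
        self.tree = tree
        self._index()
        self.validate()

    def _index(self):
        self.nodes = list(self.tree.postorder())
        self.index = {id(n): i for i, n in enumerate(self.nodes)}
        self.parent = [
            self.index[id(n.parent)] if n.parent is not None else -1
            for n in self.nodes
        ]

    def validate(self):
        for n in self.nodes:
            if n.time is None:
                raise TreeError("species tree nodes must carry times")
        root = self.tree.root
        if abs(root.time) > 1e-9:
            raise TreeError("species tree root must be at time 0")
        for leaf in self.tree.leaves():
            if abs(leaf.time - 1.0) > 1e-9:
                raise TreeError("species tree must have height exactly 1")
        for n in self.nodes:
            if n.parent is not None and n.time < n.parent.time - 1e-12:
                raise TreeError("species node times must increase from the root")

    @property
    def n_leaves(self) -> int:
        return self.tree.n_leaves

    def leaf_labels(self) -> list[str]:
        return self.tree.leaf_labels()


@dataclass
class GeneEvent:
    """One event of the gene family process.  ``donor``/``recipient`` are
    species-node postorder indices (the species branch above that node);
    ``surviving`` marks events visible on the pruned gene tree."""

    kind: str  # duplication | additive_transfer | replacing_transfer | loss
    time: float
    donor: int
    recipient: Optional[int] = None
    surviving: bool = False


@dataclass
class GeneFamilyHistory:
    """A simulated gene family: the pruned true rooted gene tree (ultrametric,
    leaves at time 1), its event log, the gene-leaf -> species-leaf map, and
    surviving-event counts."""

    tree: Optional[RootedTree]
    events: list[GeneEvent]
    leaf_map: dict[str, str]
    counts: dict[str, int]
    extinct: bool
    n_leaves: int
    degraded_transfers: int = 0

    def true_root_position(self) -> tuple[UnrootedGeneTree, RootPosition]:
        """Unroot the true tree, returning the unrooted tree and the position
        of the true root on it."""
        return unroot(self.tree, return_root_position=True)


# ---------------------------------------------------------------------------
# species tree simulation
# ---------------------------------------------------------------------------


def simulate_species_tree(
    n: int,
    birth: float = 5.0,
    death: float = 1.0,
    seed: int = 0,
    max_retries: int = 100,
) -> SpeciesTreeTimed:
    """Simulate a birth-death species tree conditioned on exactly ``n`` extant
    leaves, prune extinct lineages, and rescale node times so the height is
    exactly 1.  Deterministic given ``seed``.  Leaves are labelled S1..Sn."""
    if n < 2:
        raise ValueError("need at least 2 species")
    if not (birth > death >= 0):
        raise ValueError("need birth > death >= 0")
    rng = random.Random(seed)
    last_error = None
    for attempt in range(max_retries):
        try:
            # GSA conditioning: grow well past n tips and sample uniformly
            # over the interval during which exactly n lineages exist; this
            # avoids the stop-at-the-nth-birth artifact of zero-length
            # youngest branches
            dtree = treesim.birth_death_tree(
                birth_rate=birth,
                death_rate=death,
                num_extant_tips=n,
                gsa_ntax=2 * n,
                rng=rng,
                is_retain_extinct_tips=False,
            )
            break
        except Exception as exc:  # simulated tree went extinct; retry
            last_error = exc
    else:
        raise RuntimeError(
            f"species tree simulation failed after {max_retries} retries: {last_error}"
        )

    def convert(dnode) -> TreeNode:
        node = TreeNode(None, dnode.edge.length or 0.0)
        kids = dnode.child_nodes()
        while len(kids) == 1:  # suppress unifurcations defensively
            child = kids[0]
            node.length += child.edge.length or 0.0
            kids = child.child_nodes()
            dnode = child
        for c in kids:
            node.add_child(convert(c))
        return node

    root = convert(dtree.seed_node)
    root.length = 0.0

    # depths -> times normalized to height 1, leaves snapped to exactly 1
    rt = RootedTree(root, validate=False)
    depth = {id(root): 0.0}
    height = 0.0
    for node in rt.preorder():
        if node is not root:
            depth[id(node)] = depth[id(node.parent)] + node.length
            if node.is_leaf:
                height = max(height, depth[id(node)])
    if height <= 0:
        raise RuntimeError("degenerate species tree with zero height")
    counter = 0
    for node in rt.preorder():
        node.time = depth[id(node)] / height
        if node.is_leaf:
            node.time = 1.0
            counter += 1
            node.label = f"S{counter}"
    for node in rt.preorder():
        if node is not root:
            node.length = node.time - node.parent.time
            if node.length < 0:  # float fuzz from snapping leaves to 1
                node.length = 0.0
                node.time = node.parent.time
    rt.validate()
    return SpeciesTreeTimed(rt)


# ---------------------------------------------------------------------------
# gene family simulation
# ---------------------------------------------------------------------------


class _GNode:
    __slots__ = ("kind", "time", "children", "species", "event")

    def __init__(self, kind: str, time: float, species: int = -1, n_slots: int = 0):
        self.kind = kind  # root|spec|dup|transfer|loss|kill|leaf
        self.time = time
        # fixed child slots; for transfer nodes slot 0 is the donor
        # continuation and slot 1 the transferred copy
        self.children: list[Optional["_GNode"]] = [None] * n_slots
        self.species = species  # species node index (leaf index for 'leaf')
        self.event: Optional[GeneEvent] = None


class _Lineage:
    __slots__ = ("id", "parent", "slot", "branch", "birth", "alive")

    def __init__(self, lid: int, parent: _GNode, slot: int, branch: int, birth: float):
        self.id = lid
        self.parent = parent
        self.slot = slot
        self.branch = branch
        self.birth = birth
        self.alive = True


_MAX_LIVE = 100_000


def simulate_gene_history(
    stree: SpeciesTreeTimed, rates: EventRates, seed: int = 0
) -> GeneFamilyHistory:
    """Evolve one gene family inside ``stree`` under ``rates``; deterministic
    given ``seed``.  Families surviving with fewer than 3 leaves are returned
    with ``extinct=True`` (rooting is undefined below 3 leaves); callers
    resimulate with a fresh seed."""
    rng = random.Random(seed)
    nodes = stree.nodes
    parent_idx = stree.parent
    times = [n.time for n in nodes]
    root_idx = stree.index[id(stree.tree.root)]
    children_idx = [
        [stree.index[id(c)] for c in n.children] for n in nodes
    ]
    is_leaf = [not n.children for n in nodes]
    branch_ids = [i for i in range(len(nodes)) if i != root_idx]

    R = rates.total_rate
    d_rate, t_rate, l_rate = (
        rates.duplication_rate,
        rates.transfer_rate_total,
        rates.loss_rate,
    )

    heap: list[tuple[float, int, int, str]] = []
    seq = 0
    lineages: dict[int, _Lineage] = {}
    live: dict[int, set[int]] = {b: set() for b in branch_ids}
    events: list[GeneEvent] = []
    degraded = 0

    def schedule(lin: _Lineage, t: float) -> None:
        nonlocal seq
        t_end = times[lin.branch]
        te = t + rng.expovariate(R) if R > 0 else math.inf
        if te < t_end:
            heapq.heappush(heap, (te, seq, lin.id, "evt"))
        else:
            heapq.heappush(heap, (t_end, seq, lin.id, "end"))
        seq += 1

    def spawn(parent: _GNode, slot: int, branch: int, t: float) -> None:
        lid = len(lineages)
        lin = _Lineage(lid, parent, slot, branch, t)
        lineages[lid] = lin
        live[branch].add(lid)
        if len(lineages) > _MAX_LIVE:
            raise RuntimeError("gene family exploded beyond the lineage cap")
        schedule(lin, t)

    def terminate(lin: _Lineage, gnode: _GNode) -> None:
        lin.alive = False
        live[lin.branch].discard(lin.id)
        lin.parent.children[lin.slot] = gnode

    g0 = _GNode("root", 0.0, root_idx, n_slots=len(children_idx[root_idx]))
    for slot, c in enumerate(children_idx[root_idx]):
        spawn(g0, slot, c, 0.0)

    while heap:
        t, _, lid, what = heapq.heappop(heap)
        lin = lineages[lid]
        if not lin.alive:
            continue
        if what == "end":
            s = lin.branch
            if is_leaf[s]:
                terminate(lin, _GNode("leaf", 1.0, s))
            else:
                node = _GNode("spec", times[s], s, n_slots=len(children_idx[s]))
                terminate(lin, node)
                for slot, c in enumerate(children_idx[s]):
                    spawn(node, slot, c, times[s])
            continue
        # a duplication, transfer, or loss at time t on branch lin.branch
        u = rng.random() * R
        if u < d_rate:
            node = _GNode("dup", t, lin.branch, n_slots=2)
            node.event = GeneEvent("duplication", t, lin.branch)
            events.append(node.event)
            terminate(lin, node)
            spawn(node, 0, lin.branch, t)
            spawn(node, 1, lin.branch, t)
        elif u < d_rate + l_rate:
            node = _GNode("loss", t, lin.branch)
            node.event = GeneEvent("loss", t, lin.branch)
            events.append(node.event)
            terminate(lin, node)
        else:
            alive_branches = [
                b
                for b in branch_ids
                if b != lin.branch and times[parent_idx[b]] <= t < times[b]
            ]
            if not alive_branches:  # only possible on pathological trees
                schedule(lin, t)
                continue
            additive = rng.random() < rates.additive_fraction
            if additive:
                recipient = rng.choice(alive_branches)
            elif rates.replacing_rule == "occupied":
                # a replacing transfer displaces an existing homolog, so the
                # recipient is drawn among branches actually carrying a copy;
                # with no such branch the event lapses
                occupied = [b for b in alive_branches if live[b]]
                if not occupied:
                    degraded += 1
                    schedule(lin, t)
                    continue
                recipient = rng.choice(occupied)
                victim = lineages[rng.choice(sorted(live[recipient]))]
                terminate(victim, _GNode("kill", t, recipient))
            else:
                recipient = rng.choice(alive_branches)
                victims = sorted(live[recipient])
                if victims:
                    victim = lineages[rng.choice(victims)]
                    terminate(victim, _GNode("kill", t, recipient))
                elif rates.replacing_rule == "degrade":
                    additive = True
                    degraded += 1
                else:  # skip: the event lapses
                    degraded += 1
                    schedule(lin, t)
                    continue
            ev = GeneEvent(
                "additive_transfer" if additive else "replacing_transfer",
                t,
                lin.branch,
                recipient,
            )
            events.append(ev)
            node = _GNode("transfer", t, lin.branch, n_slots=2)
            node.event = ev
            terminate(lin, node)
            spawn(node, 0, lin.branch, t)  # donor copy continues
            spawn(node, 1, recipient, t)  # transferred copy

    return _prune_and_count(stree, g0, events, degraded)


def _prune_and_count(
    stree: SpeciesTreeTimed,
    g0: _GNode,
    events: list[GeneEvent],
    degraded: int,
) -> GeneFamilyHistory:
    # survival flags, iterative postorder
    surv: dict[int, bool] = {}
    order: list[_GNode] = []
    stack = [g0]
    while stack:
        node = stack.pop()
        order.append(node)
        stack.extend(node.children)
    for node in reversed(order):
        if node.kind == "leaf":
            surv[id(node)] = True
        else:
            surv[id(node)] = any(surv[id(c)] for c in node.children)

    n_leaves = sum(1 for node in order if node.kind == "leaf")
    if not surv[id(g0)] or n_leaves < 3:
        return GeneFamilyHistory(
            tree=None,
            events=events,
            leaf_map={},
            counts={c: 0 for c in SUMMARY_COLUMNS[1:]},
            extinct=True,
            n_leaves=n_leaves,
            degraded_transfers=degraded,
        )

    # surviving-event counts: events attached to the pruned tree.
    #  - a duplication counts when both its child copies left descendants
    #  - a transfer counts when the transferred copy left descendants
    #  - one loss is counted per maximal dead subtree hanging off a surviving
    #    lineage, provided the subtree actually ends in a loss (a subtree
    #    removed purely by replacing-transfer kills is already accounted for
    #    by the replacing-transfer count)
    counts = {
        "Duplications": 0,
        "Losses": 0,
        "Additive Transfers": 0,
        "Replacing Transfers": 0,
    }
    for node in order:
        live_kids = [c for c in node.children if surv[id(c)]]
        if not live_kids:
            continue
        if node.kind == "dup" and len(live_kids) == 2:
            counts["Duplications"] += 1
            node.event.surviving = True
        if node.kind == "transfer" and surv[id(node.children[1])]:
            key = (
                "Additive Transfers"
                if node.event.kind == "additive_transfer"
                else "Replacing Transfers"
            )
            counts[key] += 1
            node.event.surviving = True
        for c in node.children:
            if not surv[id(c)]:
                loss_node = _find_loss(c)
                if loss_node is not None:
                    counts["Losses"] += 1
                    loss_node.event.surviving = True

    # build the pruned rooted tree
    top = g0
    while True:
        live_kids = [c for c in top.children if surv[id(c)]]
        if len(live_kids) != 1:
            break
        top = live_kids[0]

    species_labels = [n.label for n in stree.nodes]
    copy_counter: dict[str, int] = {}
    leaf_map: dict[str, str] = {}

    def build(gnode: _GNode) -> TreeNode:
        while True:
            live_kids = [c for c in gnode.children if surv[id(c)]]
            if gnode.kind == "leaf":
                sp = species_labels[gnode.species]
                copy_counter[sp] = copy_counter.get(sp, 0) + 1
                label = f"{sp}_{copy_counter[sp]}"
                leaf_map[label] = sp
                node = TreeNode(label)
                node.time = 1.0
                return node
            if len(live_kids) == 1:
                gnode = live_kids[0]
                continue
            node = TreeNode()
            node.time = gnode.time
            for c in live_kids:
                node.add_child(build(c))
            return node

    root_node = build(top)
    rt = RootedTree(root_node, validate=False)
    for node in rt.preorder():
        if node is not rt.root:
            node.length = node.time - node.parent.time
    rt.root.length = 0.0
    rt.validate()

    return GeneFamilyHistory(
        tree=rt,
        events=events,
        leaf_map=leaf_map,
        counts=counts,
        extinct=False,
        n_leaves=rt.n_leaves,
        degraded_transfers=degraded,
    )


def _find_loss(node: _GNode) -> Optional[_GNode]:
    """First loss-terminated tip inside a dead subtree, if any."""
    stack = [node]
    while stack:
        n = stack.pop()
        if n.kind == "loss":
            return n
        stack.extend(n.children)
    return None


# ---------------------------------------------------------------------------
# branch scaling and topology perturbation
# ---------------------------------------------------------------------------


def scale_branches(gtree: RootedTree, scheme: ScalingScheme, seed: int = 0) -> RootedTree:
    """Return a copy of ``gtree`` with branch lengths rescaled under
    ``scheme``; the topology is unchanged.  Deterministic given ``seed``."""
    out = gtree.copy()
    rng = random.Random(seed)
    if scheme.kind == "none":
        return out
    if scheme.kind == "uniform":
        for node in out.preorder():
            if node is not out.root:
                node.length *= rng.uniform(scheme.lo, scheme.hi)
            node.time = None
        return out
    # autocorrelated lognormal rates, mean-preserving on the natural scale;
    # the input tree is in time units, so the branch length doubles as the
    # time separating child from parent when the variance is time-scaled
    rate: dict[int, float] = {id(out.root): scheme.start_rate}
    for node in out.preorder():
        if node is not out.root:
            parent_rate = rate[id(node.parent)]
            var = scheme.sigma2 * (node.length if scheme.time_scaled else 1.0)
            if var > 0:
                r = math.exp(rng.gauss(math.log(parent_rate) - var / 2.0, math.sqrt(var)))
            else:
                r = parent_rate
            rate[id(node)] = r
            node.length *= r
        node.time = None
    return out


def perturb_topology(gtree: RootedTree, k: int, seed: int = 0) -> RootedTree:
    """Apply ``k`` random nearest-neighbour-interchange moves to the unrooted
    topology of ``gtree`` and reroot at a random edge.  A stand-in for
    phylogenetic reconstruction error: each NNI changes at most one
    bipartition, so the unrooted RF distance to the input is at most ``k``."""
    if k < 0:
        raise ValueError("k must be >= 0")
    rng = random.Random(seed)
    utree = unroot(gtree)
    adj = {u: list(nbrs) for u, nbrs in utree.adj.items()}

    def replace(node: int, old: int, new: int, length: float) -> None:
        adj[node] = [(new, length) if w == old else (w, l) for w, l in adj[node]]

    for _ in range(k):
        internal_edges = [
            (u, v)
            for (u, v) in sorted(
                (u, v) for u in adj for v, _ in adj[u] if u < v
            )
            if len(adj[u]) == 3 and len(adj[v]) == 3
        ]
        if not internal_edges:
            break
        u, v = rng.choice(internal_edges)
        u_nbrs = [w for w, _ in adj[u] if w != v]
        v_nbrs = [w for w, _ in adj[v] if w != u]
        x = rng.choice(u_nbrs)
        y = rng.choice(v_nbrs)
        lx = next(l for w, l in adj[u] if w == x)
        ly = next(l for w, l in adj[v] if w == y)
        # swap subtrees x and y across edge (u, v)
        replace(u, x, y, ly)
        replace(v, y, x, lx)
        replace(x, u, v, lx)
        replace(y, v, u, ly)

    perturbed = UnrootedGeneTree(adj, dict(utree.labels))
    edge = rng.choice(perturbed.edges())
    return root_at(perturbed, RootPosition(edge, 0.5))


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def summarize_families(histories: list[GeneFamilyHistory]) -> pd.DataFrame:
    """Per-set means of leaf counts and surviving event counts, one row, with
    the canonical column order (Leaves, Duplications, Losses, Additive
    Transfers, Replacing Transfers)."""
    if not histories:
        raise ValueError("need at least one gene family history")
    rows = []
    for h in histories:
        row = {"Leaves": h.n_leaves}
        row.update(h.counts)
        rows.append(row)
    df = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    return df.mean().to_frame().T[SUMMARY_COLUMNS]
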