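import random
from collections import Counter

import numpy as np
import pytest

from rootbench.rooting import (
    EventCosts,
    dtl_reconciliation_cost,
    dtl_root,
    mad_root,
    midpoint_root,
    mv_root,
    random_root,
)
from rootbench.simulate import EventRates, simulate_gene_history, simulate_species_tree
from rootbench.trees import (
    RootPosition,
    TreeError,
    parse_newick,
    rf_rooted,
    root_at,
    unroot,
)

from conftest import random_rooted_tree, random_unrooted_tree
from oracles import brute_force_dtl_cost, mad_grid_search, mv_grid_search


def ultrametric_family(seed, n_taxa=12, rates=EventRates(0.2, 0.4)):
    stree = simulate_species_tree(n_taxa, seed=seed)
    s = seed
    while True:
        hist = simulate_gene_history(stree, rates, seed=s)
        if not hist.extinct:
            return stree, hist
        s += 1


class TestMidpoint:
    def test_three_leaf_star_arithmetic(self):
        # pendant lengths 1, 2, 5: longest path B-C of length 7, midpoint
        # 3.5 from each end, i.e. 1.5 into C's pendant edge from the hub
        u = parse_newick("(A:1,B:2,C:5);")
        res = midpoint_root(u)
        assert res.score == pytest.approx(3.5)
        (pos,) = res.positions
        c_id = next(i for i, lab in u.labels.items() if lab == "C")
        assert c_id in pos.edge
        dist_from_c = (
            pos.fraction if pos.edge[0] == c_id else (1 - pos.fraction)
        ) * 5.0
        # root sits 3.5 from C along its pendant edge
        assert dist_from_c == pytest.approx(3.5)

    def test_recovers_clock_root(self, rng):
        for seed in range(5):
            _, hist = ultrametric_family(seed)
            u = unroot(hist.tree)
            res = midpoint_root(u)
            inferred = root_at(u, res.pick(0))
            assert rf_rooted(hist.tree, inferred) == 0

    def test_balanced_root_distances(self, rng):
        # max root-to-leaf distance equals half the diameter on both sides
        for _ in range(100):
            u = random_unrooted_tree(rng.randint(4, 14), rng)
            res = midpoint_root(u)
            t = root_at(u, res.positions[0])
            # the deepest leaf under each root child is equidistant from the
            # root (the defining property of the midpoint)
            sides = []
            for c in t.root.children:
                best = 0.0
                stack = [(c, c.length)]
                while stack:
                    node, d = stack.pop()
                    if node.is_leaf:
                        best = max(best, d)
                    for k in node.children:
                        stack.append((k, d + k.length))
                sides.append(best)
            assert sides[0] == pytest.approx(sides[1], abs=1e-9)

    def test_all_zero_lengths_ties_everywhere(self):
        u = random_unrooted_tree(5, random.Random(0), length_range=(0.0, 0.0))
        res = midpoint_root(u)
        assert res.score == 0.0
        assert res.tie_count == len(u.edges())


class TestMAD:
    def test_zero_score_at_clock_root(self):
        _, hist = ultrametric_family(3)
        u = unroot(hist.tree)
        res = mad_root(u)
        assert res.score == pytest.approx(0.0, abs=1e-9)
        inferred = root_at(u, res.pick(0))
        assert rf_rooted(hist.tree, inferred) == 0

    def test_closed_form_matches_grid_search(self, rng):
        mismatches = 0
        for _ in range(30):
            u = random_unrooted_tree(rng.randint(4, 8), rng)
            res = mad_root(u)
            best_grid = min(
                mad_grid_search(u, e, n_grid=2000)[1] for e in u.edges()
            )
            assert res.score <= best_grid + 1e-9
            assert res.score == pytest.approx(best_grid, rel=1e-4)

    def test_all_zero_lengths_rejected(self):
        u = random_unrooted_tree(5, random.Random(0), length_range=(0.0, 0.0))
        with pytest.raises(TreeError):
            mad_root(u)

    def test_zero_distance_pair_warns_and_skips(self):
        u = parse_newick("((A:0,B:0):1,C:1,D:2);")
        with pytest.warns(UserWarning, match="zero path length"):
            res = mad_root(u)
        assert np.isfinite(res.score)


class TestMV:
    def test_zero_variance_at_clock_root(self):
        _, hist = ultrametric_family(4)
        u = unroot(hist.tree)
        res = mv_root(u)
        assert res.score == pytest.approx(0.0, abs=1e-12)
        inferred = root_at(u, res.pick(0))
        assert rf_rooted(hist.tree, inferred) == 0

    def test_closed_form_matches_grid_search(self, rng):
        for _ in range(30):
            u = random_unrooted_tree(rng.randint(4, 8), rng)
            res = mv_root(u)
            best_grid = min(mv_grid_search(u, e, n_grid=2000)[1] for e in u.edges())
            assert res.score <= best_grid + 1e-12
            assert res.score == pytest.approx(best_grid, rel=1e-4, abs=1e-12)

    def test_symmetric_star_ties_at_hub(self):
        u = parse_newick("(A:1,B:1,C:1);")
        res = mv_root(u)
        assert res.score == pytest.approx(0.0, abs=1e-12)
        assert res.tie_count == 3  # the hub end of each pendant edge


class TestDTL:
    def test_congruent_tree_costs_zero(self):
        stree = parse_newick("(((A:1,B:1):1,C:2):1,D:3);")
        gtree = parse_newick("(((A_1:1,B_1:1):1,C_1:2):1,D_1:3);")
        mapping = {l: l[:-2] for l in gtree.leaf_labels()}
        assert dtl_reconciliation_cost(gtree, stree, mapping) == 0.0

    def test_single_transfer_instance(self):
        # S = ((A,B),C) with G = ((a,c),b): one transfer explains it
        stree = parse_newick("((A:1,B:1):1,C:2);")
        gtree = parse_newick("((a_1:1,c_1:1):1,b_1:2);")
        mapping = {"a_1": "A", "b_1": "B", "c_1": "C"}
        cost = dtl_reconciliation_cost(gtree, stree, mapping)
        assert cost == 3.0
        assert cost == brute_force_dtl_cost(gtree, stree, mapping, EventCosts())

    def test_dp_matches_brute_force_random_instances(self, rng):
        for _ in range(60):
            n_sp = rng.randint(2, 5)
            n_g = rng.randint(3, 6)
            stree = random_rooted_tree(n_sp, rng, labels=[f"S{i}" for i in range(n_sp)])
            gtree = random_rooted_tree(n_g, rng, labels=[f"g{i}" for i in range(n_g)])
            mapping = {f"g{i}": f"S{rng.randrange(n_sp)}" for i in range(n_g)}
            costs = EventCosts(
                rng.randint(1, 5), rng.randint(1, 5), rng.randint(1, 5)
            )
            dp = dtl_reconciliation_cost(gtree, stree, mapping, costs)
            bf = brute_force_dtl_cost(gtree, stree, mapping, costs)
            assert dp == bf

    def test_root_search_consistent_with_per_edge_costs(self, rng):
        for trial in range(10):
            n_sp, n_g = 4, 6
            stree = random_rooted_tree(n_sp, rng, labels=[f"S{i}" for i in range(n_sp)])
            gtree = random_unrooted_tree(n_g, rng, labels=[f"g{i}" for i in range(n_g)])
            mapping = {f"g{i}": f"S{rng.randrange(n_sp)}" for i in range(n_g)}
            res = dtl_root(gtree, stree, mapping)
            recomputed = {
                e: dtl_reconciliation_cost(
                    root_at(gtree, RootPosition(e, 0.5)), stree, mapping
                )
                for e in gtree.edges()
            }
            assert res.score == min(recomputed.values())
            opt_edges = {e for e, c in recomputed.items() if c == res.score}
            assert {p.edge for p in res.positions} == opt_edges

    def test_congruent_family_recovers_species_root(self):
        stree, hist = ultrametric_family(11, rates=EventRates(0.0, 0.0))
        u = unroot(hist.tree)
        res = dtl_root(u, stree.tree, hist.leaf_map)
        assert res.score == 0.0
        inferred = root_at(u, res.pick(0))
        assert rf_rooted(hist.tree, inferred) == 0

    def test_symmetric_duplication_tie_set_fixed_by_oracle(self):
        # S = (A,B); G unrooted ((a1,b1),(a2,b2)): the reported optimum set
        # must coincide exactly with a per-edge brute-force evaluation (here
        # the central edge -- a single root duplication -- is the unique
        # optimum, cost 2)
        stree = parse_newick("(A:1,B:1);")
        g = parse_newick("((a1:1,b1:1):1,(a2:1,b2:1):1);", rooted_hint=False)
        mapping = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        res = dtl_root(g, stree, mapping)
        per_edge = {
            e: brute_force_dtl_cost(
                root_at(g, RootPosition(e, 0.5)), stree, mapping, EventCosts()
            )
            for e in g.edges()
        }
        assert res.score == min(per_edge.values()) == 2.0
        assert {p.edge for p in res.positions} == {
            e for e, c in per_edge.items() if c == res.score
        }

    def test_tied_optima_all_reported(self, rng):
        # scan random instances for one with genuinely tied optimal edges and
        # check the full tie set against independent per-edge recomputation
        found = 0
        for trial in range(200):
            local = random.Random(trial)
            n_sp, n_g = 3, 5
            stree = random_rooted_tree(n_sp, local, labels=[f"S{i}" for i in range(n_sp)])
            gtree = random_unrooted_tree(n_g, local, labels=[f"g{i}" for i in range(n_g)])
            mapping = {f"g{i}": f"S{local.randrange(n_sp)}" for i in range(n_g)}
            res = dtl_root(gtree, stree, mapping)
            if res.tie_count > 1:
                found += 1
                per_edge = {
                    e: dtl_reconciliation_cost(
                        root_at(gtree, RootPosition(e, 0.5)), stree, mapping
                    )
                    for e in gtree.edges()
                }
                assert {p.edge for p in res.positions} == {
                    e for e, c in per_edge.items() if c == res.score
                }
                if found >= 5:
                    break
        assert found >= 1

    def test_cost_monotone_in_unit_costs(self, rng):
        for _ in range(10):
            n_sp, n_g = 4, 6
            stree = random_rooted_tree(n_sp, rng, labels=[f"S{i}" for i in range(n_sp)])
            gtree = random_unrooted_tree(n_g, rng, labels=[f"g{i}" for i in range(n_g)])
            mapping = {f"g{i}": f"S{rng.randrange(n_sp)}" for i in range(n_g)}
            base = dtl_root(gtree, stree, mapping, EventCosts(1, 2, 3)).score
            higher = dtl_root(gtree, stree, mapping, EventCosts(1, 2, 5)).score
            assert higher >= base

    def test_unmapped_leaf_raises(self):
        stree = parse_newick("((A:1,B:1):1,C:2);")
        g = parse_newick("(a_1:1,b_1:1,c_1:1);")
        with pytest.raises(TreeError):
            dtl_root(g, stree, {"a_1": "A", "b_1": "B"})


class TestRandomRoot:
    def test_deterministic_per_seed(self, rng):
        u = random_unrooted_tree(10, rng)
        assert random_root(u, 42).positions == random_root(u, 42).positions

    def test_uniform_over_edges(self, rng):
        from scipy.stats import chisquare

        u = random_unrooted_tree(3, rng)
        counts = Counter(random_root(u, s).positions[0].edge for s in range(3000))
        assert set(counts) == set(u.edges())
        _, p = chisquare(list(counts.values()))
        assert p > 0.01
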