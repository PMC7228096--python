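import random

import pytest

from rootbench.simulate import (
    EventRates,
    ScalingScheme,
    simulate_gene_history,
    simulate_species_tree,
    summarize_families,
    perturb_topology,
    scale_branches,
    SUMMARY_COLUMNS,
)
from rootbench.trees import rf_rooted, rf_unrooted, unroot, write_newick

from conftest import random_rooted_tree


def depths(tree):
    out = {}
    stack = [(tree.root, 0.0)]
    while stack:
        node, d = stack.pop()
        if node.is_leaf:
            out[node.label] = d
        for c in node.children:
            stack.append((c, d + c.length))
    return out


class TestSpeciesTree:
    def test_leaf_count_height_and_ultrametricity(self):
        st = simulate_species_tree(100, seed=7)
        assert st.n_leaves == 100
        dd = depths(st.tree)
        assert all(abs(d - 1.0) < 1e-9 for d in dd.values())
        assert sorted(dd) == sorted(f"S{i}" for i in range(1, 101))

    def test_two_species_cherry(self):
        st = simulate_species_tree(2, seed=1)
        assert st.n_leaves == 2
        assert all(c.length == pytest.approx(1.0) for c in st.tree.root.children)

    def test_determinism_and_seed_sensitivity(self):
        a = write_newick(simulate_species_tree(20, seed=5).tree)
        b = write_newick(simulate_species_tree(20, seed=5).tree)
        assert a == b
        others = {
            write_newick(simulate_species_tree(20, seed=s).tree) for s in range(6, 12)
        }
        assert a not in others

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            simulate_species_tree(10, birth=1.0, death=2.0)
        with pytest.raises(ValueError):
            simulate_species_tree(1)


class TestEventRates:
    @pytest.mark.parametrize(
        "dup,transfer,af,expected",
        [
            (0.13, 0.27, 0.3, 0.1688),  # low preset
            (0.3, 0.6, 0.3, 0.384),  # medium preset
            (0.6, 1.2, 0.3, 0.768),  # high preset
            (0.13, 0.27, 1.0, 0.32),  # additive collection
            (0.6, 4.0, 0.3, 1.44),  # very-high-4 preset
        ],
    )
    def test_loss_rate_derivation(self, dup, transfer, af, expected):
        r = EventRates(dup, transfer, additive_fraction=af)
        assert r.loss_rate == pytest.approx(expected)

    def test_validation(self):
        with pytest.raises(ValueError):
            EventRates(-0.1, 0.2)
        with pytest.raises(ValueError):
            EventRates(0.1, 0.2, additive_fraction=1.5)
        with pytest.raises(ValueError):
            EventRates(0.1, 0.2, replacing_rule="bogus")


class TestGeneHistory:
    def test_zero_rates_reproduce_species_tree(self):
        st = simulate_species_tree(30, seed=3)
        hist = simulate_gene_history(st, EventRates(0.0, 0.0), seed=0)
        assert not hist.extinct
        assert hist.n_leaves == 30
        assert all(v == 0 for v in hist.counts.values())
        # one copy per species, same topology, same root
        relabeled = hist.tree.copy()
        for leaf in relabeled.leaves():
            leaf.label = hist.leaf_map[leaf.label]
        assert rf_rooted(relabeled, st.tree) == 0

    def test_unscaled_tree_is_ultrametric_at_height_one(self):
        st = simulate_species_tree(40, seed=9)
        hist = simulate_gene_history(st, EventRates(0.3, 0.6), seed=4)
        dd = depths(hist.tree)
        root_time = hist.tree.root.time
        assert all(
            abs(d - (1.0 - root_time)) < 1e-9 for d in dd.values()
        )

    def test_determinism(self):
        st = simulate_species_tree(25, seed=2)
        h1 = simulate_gene_history(st, EventRates(0.3, 0.6), seed=11)
        h2 = simulate_gene_history(st, EventRates(0.3, 0.6), seed=11)
        assert write_newick(h1.tree) == write_newick(h2.tree)
        assert h1.counts == h2.counts

    def test_every_leaf_maps_to_a_species(self):
        st = simulate_species_tree(20, seed=8)
        hist = simulate_gene_history(st, EventRates(0.6, 1.2), seed=1)
        species = set(st.leaf_labels())
        assert set(hist.leaf_map) == set(hist.tree.leaf_labels())
        assert set(hist.leaf_map.values()) <= species

    def test_surviving_event_flags_match_counts(self):
        st = simulate_species_tree(30, seed=4)
        hist = simulate_gene_history(st, EventRates(0.6, 1.2), seed=2)
        by_kind = {
            "duplication": "Duplications",
            "loss": "Losses",
            "additive_transfer": "Additive Transfers",
            "replacing_transfer": "Replacing Transfers",
        }
        for kind, col in by_kind.items():
            flagged = sum(1 for e in hist.events if e.kind == kind and e.surviving)
            assert flagged == hist.counts[col]

    def test_transfer_rate_monotonicity(self):
        # very-high presets: raising the transfer rate raises surviving
        # replacing-transfer counts (cf. the 2.0 < 3.0 < 4.0 ordering)
        means = []
        for total in (2.0, 3.0, 4.0):
            tot = 0
            k = 0
            s = 0
            while k < 12:
                st = simulate_species_tree(50, seed=100 + k)
                h = simulate_gene_history(
                    st, EventRates(0.6, total), seed=s
                )
                s += 1
                if h.extinct:
                    continue
                k += 1
                tot += h.counts["Replacing Transfers"]
            means.append(tot / k)
        assert means[0] < means[1] < means[2]


class TestScaling:
    def test_uniform_identity_bounds(self, rng):
        t = random_rooted_tree(10, rng)
        same = scale_branches(t, ScalingScheme("uniform", lo=1.0, hi=1.0), seed=0)
        for a, b in zip(t.postorder(), same.postorder()):
            assert a.length == pytest.approx(b.length)

    def test_uniform_respects_bounds(self, rng):
        scheme = ScalingScheme("uniform", lo=0.3, hi=3.0)
        for trial in range(50):
            t = random_rooted_tree(8, rng)
            s = scale_branches(t, scheme, seed=trial)
            for a, b in zip(t.postorder(), s.postorder()):
                if a.parent is None:
                    continue
                assert 0.3 * a.length - 1e-12 <= b.length <= 3.0 * a.length + 1e-12

    def test_autocorrelated_sigma_zero_scales_exactly(self, rng):
        t = random_rooted_tree(10, rng)
        s = scale_branches(
            t, ScalingScheme("autocorrelated", start_rate=2.0, sigma2=0.0), seed=0
        )
        for a, b in zip(t.postorder(), s.postorder()):
            if a.parent is not None:
                assert b.length == pytest.approx(2.0 * a.length)

    def test_invalid_schemes_rejected(self):
        with pytest.raises(ValueError):
            ScalingScheme("uniform", lo=0.0, hi=1.0)
        with pytest.raises(ValueError):
            ScalingScheme("autocorrelated", sigma2=-0.1)
        with pytest.raises(ValueError):
            ScalingScheme("twisted")


class TestPerturbation:
    def test_zero_moves_keeps_topology(self, rng):
        t = random_rooted_tree(12, rng)
        p = perturb_topology(t, 0, seed=1)
        assert rf_unrooted(t, p) == 0

    def test_single_move_changes_at_most_one_split(self, rng):
        for trial in range(30):
            t = random_rooted_tree(10, rng)
            p = perturb_topology(t, 1, seed=trial)
            assert rf_unrooted(t, p) in (0, 1)

    def test_rf_bounded_by_move_count(self, rng):
        for trial in range(100):
            k = rng.randint(0, 6)
            t = random_rooted_tree(rng.randint(6, 15), rng)
            p = perturb_topology(t, k, seed=trial)
            assert rf_unrooted(t, p) <= k
            assert sorted(p.leaf_labels()) == sorted(t.leaf_labels())


class TestSummaries:
    def test_zero_event_family_summary(self):
        st = simulate_species_tree(100, seed=13)
        hist = simulate_gene_history(st, EventRates(0.0, 0.0), seed=0)
        df = summarize_families([hist])
        assert list(df.columns) == SUMMARY_COLUMNS
        row = df.iloc[0]
        assert row["Leaves"] == 100
        assert all(row[c] == 0 for c in SUMMARY_COLUMNS[1:])

    def test_handbuilt_two_family_means(self):
        st = simulate_species_tree(20, seed=3)
        h1 = simulate_gene_history(st, EventRates(0.3, 0.6), seed=5)
        h2 = simulate_gene_history(st, EventRates(0.3, 0.6), seed=6)
        assert not h1.extinct and not h2.extinct
        df = summarize_families([h1, h2])
        assert df.iloc[0]["Leaves"] == pytest.approx(
            (h1.n_leaves + h2.n_leaves) / 2
        )
        for col in SUMMARY_COLUMNS[1:]:
            assert df.iloc[0][col] == pytest.approx(
                (h1.counts[col] + h2.counts[col]) / 2
            )
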