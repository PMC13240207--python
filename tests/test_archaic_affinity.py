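import itertools

import numpy as np
import pytest

from archintro import archaic_affinity as aff
from archintro.core_io import ANCESTRAL, ARCHAIC, MODERN_CARRIER, MODERN_NONCARRIER

from conftest import make_panel, make_site


class TestPairwiseDifferences:
    def test_identical(self):
        h = np.array([0, 1, 1, 0])
        assert aff.pairwise_differences(h, h) == 0

    def test_complementary_75_sites(self):
        a = np.zeros(75, dtype=np.int8)
        assert aff.pairwise_differences(a, 1 - a) == 75

    def test_random_pair_matches_loop_oracle(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 2, 100)
        b = rng.integers(0, 2, 100)
        oracle = sum(1 for x, y in zip(a, b) if x != y)
        assert aff.pairwise_differences(a, b) == oracle

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            aff.pairwise_differences([0, 1], [0, 1, 1])


class TestDistanceMatrix:
    def test_matches_pairwise_loop(self):
        rng = np.random.default_rng(1)
        X = rng.integers(0, 2, size=(6, 40)).astype(np.int8)
        dm = aff.distance_matrix(X, [f"t{i}" for i in range(6)])
        for i, j in itertools.combinations(range(6), 2):
            assert dm.values[i, j] == aff.pairwise_differences(X[i], X[j])

    def test_triangle_inequality(self):
        rng = np.random.default_rng(2)
        X = rng.integers(0, 2, size=(8, 30)).astype(np.int8)
        D = aff.distance_matrix(X, [f"t{i}" for i in range(8)]).values
        for i, j, k in itertools.permutations(range(8), 3):
            assert D[i, k] <= D[i, j] + D[j, k]

    def test_per_site_normalization(self):
        X = np.array([[0, 0, 1], [1, 1, 1]], dtype=np.int8)
        dm = aff.distance_matrix(X, ["a", "b"]).per_site(3)
        assert dm.values[0, 1] == pytest.approx(2 / 3)


class TestDedup:
    def test_two_identical_of_four(self):
        panel = make_panel([[0, 1], [0, 1], [1, 0], [1, 1]])
        unique, mult = aff.dedup_haplotypes(panel)
        assert unique.n_haplotypes == 3
        assert sorted(mult.values()) == [1, 1, 2]
        assert sum(mult.values()) == 4

    def test_all_distinct_identity(self):
        panel = make_panel([[0, 0], [0, 1], [1, 0]])
        unique, mult = aff.dedup_haplotypes(panel)
        assert unique.n_haplotypes == 3
        assert all(v == 1 for v in mult.values())

    def test_all_identical(self):
        panel = make_panel(np.ones((10, 4), dtype=np.int8))
        unique, mult = aff.dedup_haplotypes(panel)
        assert unique.n_haplotypes == 1
        assert list(mult.values()) == [10]

    def test_first_occurrence_kept(self):
        panel = make_panel([[0, 1], [1, 0], [0, 1]])
        unique, _ = aff.dedup_haplotypes(panel)
        assert unique.haplotype_ids[0] == panel.haplotype_ids[0]


class TestNearestArchaic:
    def test_exact_match(self):
        q = np.array([0, 1, 1])
        res = aff.nearest_archaic(q, {"a1": np.array([0, 1, 1]), "a2": np.array([1, 1, 1])})
        assert res.labels == ("a1",)
        assert res.count == 0

    def test_tie_reported_as_set(self):
        q = np.array([0, 0, 0, 0])
        res = aff.nearest_archaic(
            q, {"a1": np.array([1, 0, 0, 0]), "a2": np.array([0, 1, 0, 0])}
        )
        assert res.labels == ("a1", "a2")
        assert res.count == 1

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            aff.nearest_archaic(np.array([0, 1]), {})


class TestAlleleSharing:
    def test_archaic_identical_to_group_a(self):
        A = np.array(
            [[1, 0, 1], [1, 0, 1], [0, 1, 0], [0, 1, 0], [1, 0, 1]], dtype=np.int8
        )
        panel = make_panel(
            A, groups=[MODERN_CARRIER] * 2 + [MODERN_NONCARRIER] * 2 + [ARCHAIC]
        )
        track = aff.allele_sharing_track(
            panel, panel.haplotype_ids[:2], panel.haplotype_ids[2:4], "arch0"
        )
        assert track["shared_with_a"].all()
        assert not track["shared_with_b"].any()

    def test_single_site_both_groups_match(self):
        A = np.array([[1], [1], [1]], dtype=np.int8)
        panel = make_panel(A, groups=[MODERN_CARRIER, MODERN_NONCARRIER, ARCHAIC])
        track = aff.allele_sharing_track(
            panel, [panel.haplotype_ids[0]], [panel.haplotype_ids[1]], "arch0"
        )
        assert bool(track["shared_with_a"].iloc[0])
        assert bool(track["shared_with_b"].iloc[0])

    def test_tie_flagged_not_broken(self):
        A = np.array([[1, 0], [0, 1], [1, 1], [1, 0]], dtype=np.int8)
        panel = make_panel(
            A, groups=[MODERN_CARRIER] * 2 + [MODERN_NONCARRIER, ARCHAIC]
        )
        track = aff.allele_sharing_track(
            panel, panel.haplotype_ids[:2], [panel.haplotype_ids[2]], "arch0"
        )
        assert track["tie_a"].all()
        assert track["shared_with_a"].isna().all()

    def test_overlapping_groups_rejected(self):
        panel = make_panel([[0, 1], [1, 0], [1, 1]], groups=[MODERN_CARRIER, MODERN_NONCARRIER, ARCHAIC])
        with pytest.raises(ValueError, match="disjoint"):
            aff.allele_sharing_track(panel, [panel.haplotype_ids[0]], [panel.haplotype_ids[0]], "arch0")

    def test_enrichment_inside_planted_tract(self):
        from archintro.core_io import filter_sites
        from archintro.synthetic_data import SimulationConfig, simulate_panel

        sim = simulate_panel(SimulationConfig(seed=8, carrier_fraction=0.2))
        panel = sim.panel.with_groups(
            {h: MODERN_CARRIER for h in sim.truth.carrier_haplotypes}
        )
        panel = filter_sites(panel, sim.mask)
        carriers = [h for h, g in zip(panel.haplotype_ids, panel.group_labels) if g == MODERN_CARRIER]
        noncarriers = [h for h, g in zip(panel.haplotype_ids, panel.group_labels) if g == MODERN_NONCARRIER]
        track = aff.allele_sharing_track(panel, carriers, noncarriers, sim.truth.source_archaic)
        inside = (track["pos"] >= sim.truth.tract_start) & (track["pos"] <= sim.truth.tract_end)
        # restrict to sites where the archaic carries the derived allele
        informative = track["archaic_allele"] == 1
        rate_in = track.loc[inside & informative, "shared_with_a"].mean()
        rate_out = track.loc[~inside & informative, "shared_with_a"].mean()
        assert rate_in > rate_out


def _path_lengths(root):
    """Leaf-to-leaf path lengths of a TreeNode tree."""
    dists = {}

    def gather(node):
        if node.is_leaf:
            return {node.name: 0.0}
        out = {}
        subs = [gather(c) for c in node.children]
        for c, sub in zip(node.children, subs):
            for leaf, d in sub.items():
                out[leaf] = d + c.length
        for (c1, s1), (c2, s2) in itertools.combinations(zip(node.children, subs), 2):
            for l1, d1 in s1.items():
                for l2, d2 in s2.items():
                    key = tuple(sorted((l1, l2)))
                    dists[key] = d1 + c1.length + d2 + c2.length
        return out

    gather(root)
    return dists


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        D = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], dtype=float)
        dm = aff.DistanceMatrix(["a", "b", "c"], D)
        root = aff.neighbor_joining(dm)
        dists = _path_lengths(root)
        # three-point formulas: la=(dab+dac-dbc)/2 etc. => pairwise paths
        # reproduce the input exactly
        assert dists[("a", "b")] == pytest.approx(5.0)
        assert dists[("a", "c")] == pytest.approx(9.0)
        assert dists[("b", "c")] == pytest.approx(10.0)

    def test_four_taxon_additive_recovery(self):
        # tree ((A:2,B:3):1,(C:4,D:5)) -> additive matrix
        D = np.array(
            [
                [0, 5, 7, 8],
                [5, 0, 8, 9],
                [7, 8, 0, 9],
                [8, 9, 9, 0],
            ],
            dtype=float,
        )
        labels = ["A", "B", "C", "D"]
        dm = aff.DistanceMatrix(labels, D)
        root = aff.neighbor_joining(dm)
        dists = _path_lengths(root)
        for i, j in itertools.combinations(range(4), 2):
            assert dists[tuple(sorted((labels[i], labels[j])))] == pytest.approx(D[i, j])
        assert frozenset("AB") in aff._splits(root) or frozenset("CD") in aff._splits(root)

    def test_two_identical_taxa_zero_cherry(self):
        X = np.array([[0, 0, 1], [0, 0, 1], [1, 1, 0], [1, 0, 0]], dtype=np.int8)
        dm = aff.distance_matrix(X, ["a", "b", "c", "d"])
        root = aff.neighbor_joining(dm)
        dists = _path_lengths(root)
        assert dists[("a", "b")] == pytest.approx(0.0)

    def test_fewer_than_three_taxa_errors(self):
        dm = aff.DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError):
            aff.neighbor_joining(dm)

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(12)
        X = rng.integers(0, 2, size=(7, 60)).astype(np.int8)
        labels = [f"t{i}" for i in range(7)]
        dm = aff.distance_matrix(X, labels)
        splits1 = aff._splits(aff.neighbor_joining(dm))
        perm = rng.permutation(7)
        dm2 = aff.distance_matrix(X[perm], [labels[i] for i in perm])
        splits2 = aff._splits(aff.neighbor_joining(dm2))
        assert splits1 == splits2

    def test_negative_branch_lengths_clamped(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            X = rng.integers(0, 2, size=(6, 15)).astype(np.int8)
            dm = aff.distance_matrix(X, [f"t{i}" for i in range(6)])
            root = aff.neighbor_joining(dm)
            stack = [root]
            while stack:
                node = stack.pop()
                assert node.length >= 0
                stack.extend(node.children)


class TestRootedTree:
    def _panel(self, seed=0, n=8, sites=50):
        rng = np.random.default_rng(seed)
        X = rng.integers(0, 2, size=(n, sites)).astype(np.int8)
        return make_panel(X, positions=list(range(10, 10 * (sites + 1), 10)))

    def test_rooted_on_outgroup(self):
        panel = self._panel()
        dm = aff.panel_distance_matrix(panel)
        res = aff.nj_tree(dm, panel.haplotype_ids[0])
        names = [c.name for c in res.root.children if c.is_leaf]
        assert panel.haplotype_ids[0] in names

    def test_leafset_preserved_and_path_lengths_unchanged_by_rerooting(self):
        panel = self._panel(seed=5)
        dm = aff.panel_distance_matrix(panel)
        unrooted = aff.neighbor_joining(dm)
        before = _path_lengths(unrooted)
        # rebuild (neighbor_joining mutates nothing, but reroot does)
        rooted = aff.reroot(aff.neighbor_joining(dm), panel.haplotype_ids[3])
        after = _path_lengths(rooted)
        assert rooted.leaf_names() == frozenset(panel.haplotype_ids)
        for key, d in before.items():
            assert after[key] == pytest.approx(d, abs=1e-9)

    def test_bootstrap_reproducible(self):
        panel = self._panel(seed=2)
        dm = aff.panel_distance_matrix(panel)
        t1 = aff.nj_tree(dm, panel.haplotype_ids[0], bootstrap=25, seed=99, alleles=panel.alleles)
        t2 = aff.nj_tree(dm, panel.haplotype_ids[0], bootstrap=25, seed=99, alleles=panel.alleles)
        assert t1.support == t2.support
        assert t1.newick == t2.newick

    def test_support_in_unit_interval(self):
        panel = self._panel(seed=4)
        dm = aff.panel_distance_matrix(panel)
        res = aff.nj_tree(dm, panel.haplotype_ids[0], bootstrap=30, seed=1, alleles=panel.alleles)
        assert res.support
        assert all(0.0 <= v <= 1.0 for v in res.support.values())

    def test_newick_parses_with_dendropy(self):
        import dendropy

        panel = self._panel(seed=6)
        dm = aff.panel_distance_matrix(panel)
        res = aff.nj_tree(dm, panel.haplotype_ids[0], bootstrap=10, seed=0, alleles=panel.alleles)
        tree = dendropy.Tree.get(data=res.newick, schema="newick")
        assert len(tree.leaf_nodes()) == panel.n_haplotypes


class TestAncestralOutgroup:
    def test_unknown_ancestral_sites_dropped(self):
        sites = [
            make_site(100, ancestral_state="ref"),
            make_site(200, ancestral_state="unknown"),
            make_site(300, ancestral_state="alt"),
        ]
        panel = make_panel([[0, 1, 0], [1, 0, 1]], sites=sites)
        out = aff.panel_with_ancestral(panel)
        assert [s.pos for s in out.sites] == [100, 300]
        assert out.haplotype_ids[-1] == "ancestral"
        assert out.group_labels[-1] == ANCESTRAL
        np.testing.assert_array_equal(out.alleles[-1], [0, 1])
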