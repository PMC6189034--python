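"""Clade definitions, overlaps, competition index, evolution rates."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from nichediv import clade_metrics as cm
from nichediv import synthdata
from nichediv.geo import cross_distance_deg
from nichediv.trees import TimeTree


class TestTimeSliceClades:
    def test_slice_above_cherry_split_yields_one_clade_of_two(self):
        tree = TimeTree.from_newick("((A:1,B:1):3,C:4);")
        part = cm.clades_by_time_slice(tree, slice_age=2.0)
        assert part.sizes() == {"clade_1": 2}
        assert part.clades["clade_1"] == ["A", "B"]
        assert part.dropped_tips == ["C"]

    def test_singletons_dropped_and_reported(self):
        # slice at 2.5: lineages {A,B} (split 1.5), {C} singleton, {D,E} (split 2)
        tree = TimeTree.from_newick(
            "(((A:1.5,B:1.5):2.5,C:4):1,(D:2,E:2):3);"
        )
        part = cm.clades_by_time_slice(tree, slice_age=2.5)
        assert sorted(len(t) for t in part.clades.values()) == [2, 2]
        assert part.dropped_tips == ["C"]

    def test_clades_are_monophyletic_and_partition_tips(self, yule_tree):
        part = cm.clades_by_time_slice(yule_tree, slice_age=30.0)
        seen = []
        for tips in part.clades.values():
            idx = yule_tree.tip_index(tips)
            assert yule_tree.is_monophyletic(idx)
            seen.extend(tips)
        assert len(seen) == len(set(seen))
        assert len(seen) + len(part.dropped_tips) == yule_tree.n_tips

    def test_slice_older_than_root_raises(self, yule_tree):
        with pytest.raises(ValueError):
            cm.clades_by_time_slice(yule_tree, slice_age=1000.0)


class TestCladeAge:
    def test_cherry_age(self):
        tree = TimeTree.from_newick("((A:5,B:5):1,C:6);")
        assert cm.clade_age(tree, ["A", "B"]) == pytest.approx(5.0)

    def test_whole_tree_age_is_crown_age(self, yule_tree):
        assert cm.clade_age(yule_tree, yule_tree.tip_labels) == pytest.approx(
            yule_tree.crown_age
        )

    def test_equals_half_max_patristic_distance(self, yule_tree):
        part = cm.clades_by_time_slice(yule_tree, slice_age=30.0)
        V = yule_tree.vcv()
        for tips in part.clades.values():
            idx = yule_tree.tip_index(tips)
            dmax = max(
                V[a, a] + V[b, b] - 2 * V[a, b] for a, b in combinations(idx, 2)
            )
            assert cm.clade_age(yule_tree, tips) == pytest.approx(dmax / 2, rel=1e-9)

    def test_non_monophyletic_raises(self, yule_tree):
        part = cm.clades_by_time_slice(yule_tree, slice_age=30.0)
        clades = list(part.clades.values())
        mixed = [clades[0][0], clades[1][0]]
        if not yule_tree.is_monophyletic(yule_tree.tip_index(mixed)):
            with pytest.raises(ValueError):
                cm.clade_age(yule_tree, mixed)


_NS_RNG = np.random.default_rng(5)
_NS_SPECIES = [f"s{i}" for i in range(4)]
_NS_OCC = {s: _NS_RNG.uniform(size=30) < 0.4 for s in _NS_SPECIES}


class TestCladeNicheSize:
    species = _NS_SPECIES
    occ = _NS_OCC

    def test_full_subsample_is_exact_union(self):
        union = np.any(np.vstack(list(self.occ.values())), axis=0).sum()
        assert cm.clade_niche_size(self.occ, self.species, m=4) == union

    def test_identical_ranges_give_constant_size(self):
        shared = self.occ["s0"]
        occ = {s: shared for s in self.species}
        for m in (1, 2, 3):
            assert cm.clade_niche_size(occ, self.species, m=m) == shared.sum()

    def test_monte_carlo_matches_exhaustive_enumeration(self):
        exact = cm.clade_niche_size(self.occ, self.species, m=2)  # 6 pairs
        mc = cm.clade_niche_size(
            self.occ, self.species, m=2, reps=20000, seed=9, exhaustive_limit=0
        )
        assert abs(mc - exact) < 0.15

    def test_subsample_larger_than_clade_raises(self):
        with pytest.raises(ValueError):
            cm.clade_niche_size(self.occ, self.species, m=5)

    def test_mean_size_non_decreasing_in_m(self):
        sizes = [cm.clade_niche_size(self.occ, self.species, m=m) for m in (1, 2, 3, 4)]
        assert np.all(np.diff(sizes) >= 0)


class TestOverlaps:
    def test_schoener_identical_and_disjoint(self):
        a = np.array([0.2, 0.5, 0.3])
        assert cm.schoener_overlap(a, 2 * a) == pytest.approx(1.0)
        assert cm.schoener_overlap(
            np.array([1.0, 0.0]), np.array([0.0, 3.0])
        ) == pytest.approx(0.0)

    def test_schoener_hand_case(self):
        a = np.array([0.5, 0.5, 0.0])
        b = np.array([0.0, 0.5, 0.5])
        assert cm.schoener_overlap(a, b) == pytest.approx(0.5)

    def test_schoener_mismatched_grids_raise(self):
        with pytest.raises(ValueError):
            cm.schoener_overlap(np.ones(3), np.ones(4))

    def test_geographic_overlap_endpoints_and_symmetry(self):
        occs = {
            "near1": pd.DataFrame({"lon": [0.0], "lat": [0.0]}),
            "near2": pd.DataFrame({"lon": [0.0], "lat": [0.0]}),
            "far": pd.DataFrame({"lon": [90.0], "lat": [0.0]}),
        }
        G = cm.geographic_overlap(occs)
        assert G.loc["near1", "near2"] == pytest.approx(1.0)
        assert G.loc["near1", "far"] == pytest.approx(0.0)
        assert np.allclose(G.to_numpy(), G.to_numpy().T)

    def test_geographic_overlap_hand_computed_means(self):
        occs = {
            "a": pd.DataFrame({"lon": [0.0, 1.0], "lat": [0.0, 0.0]}),
            "b": pd.DataFrame({"lon": [2.0, 3.0], "lat": [1.0, -1.0]}),
            "c": pd.DataFrame({"lon": [10.0, 11.0], "lat": [5.0, 6.0]}),
        }
        mean_d = {}
        names = list(occs)
        for i, j in combinations(range(3), 2):
            d = cross_distance_deg(
                occs[names[i]][["lon", "lat"]].to_numpy(),
                occs[names[j]][["lon", "lat"]].to_numpy(),
            )
            mean_d[(names[i], names[j])] = d.mean()
        lo = min(mean_d.values())
        hi = max(mean_d.values())
        G = cm.geographic_overlap(occs)
        for (a, b), d in mean_d.items():
            assert G.loc[a, b] == pytest.approx(1 - (d - lo) / (hi - lo))

    def test_empty_species_raises(self):
        occs = {"a": pd.DataFrame({"lon": [0.0], "lat": [0.0]}),
                "b": pd.DataFrame({"lon": [], "lat": []})}
        with pytest.raises(ValueError, match="b"):
            cm.geographic_overlap(occs)


class TestCompetitionIndex:
    def test_two_species_clade_is_single_product(self, toy_overlaps):
        comp = toy_overlaps.competition()
        s = toy_overlaps.species[:2]
        assert cm.clade_competition_index(toy_overlaps, s) == pytest.approx(
            comp.loc[s[0], s[1]]
        )

    def test_equal_products_give_that_value(self):
        n = 5
        names = [f"s{i}" for i in range(n)]
        ones = pd.DataFrame(np.ones((n, n)), index=names, columns=names)
        half = pd.DataFrame(np.full((n, n), 0.5), index=names, columns=names)
        ov = cm.OverlapMatrices(ones, ones, half)
        for k in (2, 3, 5):
            assert cm.clade_competition_index(ov, names[:k]) == pytest.approx(0.5)

    def test_random_assignment_expectation_is_global_mean(self, toy_overlaps):
        comp = toy_overlaps.competition().to_numpy()
        n = comp.shape[0]
        iu = np.triu_indices(n, k=1)
        global_mean = comp[iu].mean()
        rng = np.random.default_rng(4)
        vals = []
        for _ in range(4000):
            pick = rng.permutation(n)[:4]
            sub = comp[np.ix_(pick, pick)]
            vals.append(sub[np.triu_indices(4, k=1)].mean())
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - global_mean) < 3 * se

    def test_order_invariance(self, toy_overlaps):
        s = toy_overlaps.species[:5]
        a = cm.clade_competition_index(toy_overlaps, s)
        b = cm.clade_competition_index(toy_overlaps, s[::-1])
        assert a == pytest.approx(b)


class TestPermutationBiasTest:
    def test_identical_overlaps_give_zero_slope(self):
        n = 10
        names = [f"s{i}" for i in range(n)]
        ones = pd.DataFrame(np.ones((n, n)), index=names, columns=names)
        ov = cm.OverlapMatrices(ones, ones, ones)
        res = cm.permutation_bias_test(ov, [2, 3, 5], reps=50, seed=0)
        assert res["slope"] == 0.0

    def test_null_means_equal_global_mean_within_mc_error(self, toy_overlaps):
        res = cm.permutation_bias_test(toy_overlaps, [2, 3, 3, 4], reps=3000, seed=1)
        for mu, se in zip(res["null_mean"], res["null_se"]):
            assert abs(mu - res["global_mean"]) < 3 * se

    def test_oversized_partition_raises(self, toy_overlaps):
        with pytest.raises(ValueError):
            cm.permutation_bias_test(toy_overlaps, [10, 10], reps=10, seed=0)


class TestEvolutionRate:
    def test_cherry_with_equal_values_has_zero_rate(self):
        tree = TimeTree.from_newick("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")
        traits = pd.DataFrame({"t": [3.0, 3.0, 1.0, 2.0]}, index=list("ABCD"))
        r = cm.niche_evolution_rate(tree, ["A", "B"], traits, mode="univariate")
        assert r == pytest.approx(0.0)

    def test_trace_recovery_on_simulated_bm(self, big_tree):
        """Summed diagonal rates (2 + 1) recovered within 15%."""
        R = np.diag([2.0, 1.0]) / 100.0  # per Myr on a 100 Myr tree
        traces = []
        for r in range(60):
            traits = synthdata.simulate_bm_traits(big_tree, R, seed=300 + r)
            traces.append(
                cm.niche_evolution_rate(
                    big_tree, big_tree.tip_labels, traits, mode="multivariate"
                )
            )
        assert abs(np.mean(traces) - 0.03) / 0.03 < 0.15

    def test_univariate_uses_requested_trait(self, yule_tree):
        traits = synthdata.simulate_bm_traits(yule_tree, np.eye(2), seed=4)
        traits["flat"] = 1.0
        traits.loc[traits.index[0], "flat"] = 1.0  # keep exactly constant
        r = cm.niche_evolution_rate(
            yule_tree, yule_tree.tip_labels, traits, mode="univariate",
            top_trait="flat",
        )
        assert r == pytest.approx(0.0)

    def test_small_clade_falls_back_to_univariate(self, yule_tree):
        traits = synthdata.simulate_bm_traits(yule_tree, np.eye(5), seed=6)
        tips = yule_tree.tip_labels[:3]
        sub = yule_tree.extract_subtree(tips)
        with pytest.warns(UserWarning, match="univariate"):
            r = cm.niche_evolution_rate(yule_tree, tips, traits, mode="multivariate")
        assert r > 0
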