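"""Generators: birth-death trees, BM traits, environments, occurrences,
path-model datasets."""

import numpy as np
import pytest
from scipy import stats

from nichediv import path_model, synthdata
from nichediv.comparative import pic_rate
from nichediv.trees import TimeTree


# ----------------------------------------------------------------------
# birth-death trees
# ----------------------------------------------------------------------
class TestBirthDeathTree:
    def test_two_tip_tree_is_a_cherry(self):
        t = synthdata.simulate_bd_tree(2, birth=0.5, seed=3)
        assert t.n_tips == 2
        assert t.n_nodes == 3
        d = t.depths()[:2]
        assert np.isclose(d[0], d[1])

    def test_tip_and_node_counts(self):
        t = synthdata.simulate_bd_tree(55, birth=0.1, seed=5)
        assert t.n_tips == 55
        assert t.n_nodes == 2 * 55 - 1  # binary
        assert t.is_ultrametric(1e-8)
        assert np.all(t.edge_length[np.arange(t.n_nodes) != t.root] > 0)

    @pytest.mark.parametrize(
        "kwargs", [dict(n_tips=1, birth=1.0), dict(n_tips=5, birth=0.1, death=0.2)]
    )
    def test_invalid_parameters_raise(self, kwargs):
        with pytest.raises(ValueError):
            synthdata.simulate_bd_tree(seed=0, **kwargs)

    def test_reproducible(self):
        a = synthdata.simulate_bd_tree(20, birth=0.2, death=0.05, seed=9)
        b = synthdata.simulate_bd_tree(20, birth=0.2, death=0.05, seed=9)
        assert a.to_newick() == b.to_newick()

    def test_branching_times_match_independent_yule_oracle(self):
        """GSA-conditioned Yule branching times vs a hand-rolled
        count-trajectory simulator (two-sample KS)."""
        n, lam, reps = 20, 1.0, 300
        sim_times = []
        for r in range(reps):
            t = synthdata.simulate_bd_tree(n, birth=lam, seed=1000 + r)
            # ages measured back from the present
            sim_times.extend(t.branching_times().tolist())

        # oracle: forward pure-birth event times, observation time uniform
        # in the window with exactly n lineages (no genealogy needed)
        rng = np.random.default_rng(77)
        oracle_times = []
        for _ in range(reps):
            t_events = []
            t_now, k = 0.0, 2  # crown start: 2 lineages
            while k < 2 * n:
                t_now += rng.exponential(1.0 / (lam * k))
                t_events.append(t_now)
                k += 1
            # event index n-2 is the birth of the (n+1)-th lineage
            t_lo = t_events[n - 3] if n > 2 else 0.0
            t_hi = t_events[n - 2]
            t_obs = rng.uniform(t_lo, t_hi)
            ages = [t_obs] + [t_obs - te for te in t_events[: n - 2]]
            oracle_times.extend(ages)
        ks = stats.ks_2samp(sim_times, oracle_times)
        assert ks.pvalue > 0.01


# ----------------------------------------------------------------------
# BM traits
# ----------------------------------------------------------------------
class TestBMTraits:
    def test_zero_rate_matrix_fixes_tips_at_root(self, yule_tree):
        tr = synthdata.simulate_bm_traits(
            yule_tree, np.zeros((3, 3)), root_state=[1.0, -2.0, 0.5], seed=0
        )
        assert np.allclose(tr.to_numpy(), np.array([1.0, -2.0, 0.5]))
        assert tr.shape == (50, 3)

    def test_eleven_trait_table(self, yule_tree):
        tr = synthdata.simulate_bm_traits(yule_tree, np.eye(11), seed=1)
        assert tr.shape[1] == 11
        assert list(tr.index) == yule_tree.tip_labels

    def test_non_psd_matrix_raises(self, yule_tree):
        R = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        with pytest.raises(ValueError):
            synthdata.simulate_bm_traits(yule_tree, R, seed=0)

    def test_pic_recovers_generating_rate(self, yule_tree):
        """Mean PIC rate estimate within 5% of sigma^2 = 2 over replicates."""
        ests = [
            pic_rate(yule_tree, synthdata.simulate_bm_traits(
                yule_tree, np.array([[2.0 / 100.0]]), seed=r))[0, 0]
            for r in range(400)
        ]
        assert abs(np.mean(ests) - 0.02) / 0.02 < 0.05

    def test_star_tree_tips_are_independent(self):
        star = TimeTree.from_newick("(A:1,B:1,C:1);")
        vals = np.array(
            [
                synthdata.simulate_bm_traits(star, np.array([[1.0]]), seed=r)
                .to_numpy()
                .ravel()
                for r in range(4000)
            ]
        )
        corr = np.corrcoef(vals, rowvar=False)
        off = corr[~np.eye(3, dtype=bool)]
        assert np.all(np.abs(off) < 0.05)

    def test_reproducible(self, yule_tree):
        a = synthdata.simulate_bm_traits(yule_tree, np.eye(2), seed=4)
        b = synthdata.simulate_bm_traits(yule_tree, np.eye(2), seed=4)
        assert a.equals(b)


# ----------------------------------------------------------------------
# environments
# ----------------------------------------------------------------------
class TestEnvironment:
    def test_layer_structure_and_ordering(self, small_grid):
        assert len(small_grid.layers) == 6
        for var, layer in small_grid.layers.items():
            assert layer.shape == (12, 12, 12)
        assert np.all(small_grid.layers["tmin"] <= small_grid.layers["tmean"] + 1e-9)
        assert np.all(small_grid.layers["tmean"] <= small_grid.layers["tmax"] + 1e-9)
        assert small_grid.feature_matrix().shape == (144, 72)

    def test_infinite_range_gives_constant_layers(self):
        g = synthdata.simulate_environment(5, 5, autocorr_range=np.inf, seed=2)
        for var, layer in g.layers.items():
            for m in range(12):
                assert np.ptp(layer[m]) < 1e-9, var

    def test_semivariogram_increases_with_distance(self, small_grid):
        """Empirical semivariogram of a layer rises out to the range."""
        layer = small_grid.layers["tmean"][0]
        rng = np.random.default_rng(3)
        n_rows, n_cols = layer.shape
        dists, gammas = [], []
        for _ in range(500):
            r1, c1, r2, c2 = rng.integers(0, n_rows, 4)
            d = np.hypot(r1 - r2, c1 - c2)
            if 0 < d <= 3.0:  # autocorrelation range of the fixture
                dists.append(d)
                gammas.append(0.5 * (layer[r1, c1] - layer[r2, c2]) ** 2)
        rho = stats.spearmanr(dists, gammas).statistic
        assert rho > 0

    def test_grid_dims_validated(self):
        with pytest.raises(ValueError):
            synthdata.simulate_environment(1, 5, seed=0)

    def test_csv_round_trip(self, small_grid, tmp_path):
        small_grid.to_csv_dir(tmp_path / "env")
        from nichediv.env import EnvGrid

        again = EnvGrid.from_csv_dir(tmp_path / "env")
        assert np.allclose(again.layers["soil_n"], small_grid.layers["soil_n"], atol=1e-4)
        assert np.allclose(again.lon, small_grid.lon)


# ----------------------------------------------------------------------
# occurrences from suitability
# ----------------------------------------------------------------------
class TestOccurrences:
    def test_uniform_suitability_samples_uniformly(self):
        g = synthdata.simulate_environment(4, 5, autocorr_range=np.inf, seed=6)
        params = synthdata.example_species_params(g, seed=0)
        occ = synthdata.simulate_occurrences(params, g, 10000, seed=1)
        cells = g.cell_index(occ["lon"].to_numpy(), occ["lat"].to_numpy())
        counts = np.bincount(cells, minlength=g.n_cells)
        chi = stats.chisquare(counts)
        assert chi.pvalue > 0.01

    def test_sampled_cells_are_more_suitable_than_average(self, small_grid):
        from nichediv.ttr_sdm import predict_probability

        params = synthdata.example_species_params(small_grid, seed=2, breadth=0.4)
        occ = synthdata.simulate_occurrences(params, small_grid, 300, seed=3)
        p = predict_probability(
            params, small_grid.forcings_at(np.arange(small_grid.n_cells)),
            max_years=120,
        )
        cells = small_grid.cell_index(occ["lon"].to_numpy(), occ["lat"].to_numpy())
        assert p[cells].mean() > p.mean()

    def test_schema(self, small_grid):
        params = synthdata.example_species_params(small_grid, seed=2)
        occ = synthdata.simulate_occurrences(params, small_grid, 5, seed=3, species="x")
        assert list(occ.columns) == ["species", "lon", "lat", "altitude"]
        assert (occ["species"] == "x").all()

    def test_zero_suitability_raises(self, small_grid):
        from nichediv.ttr_sdm import LimitationCurve, TTRParameters

        params = synthdata.example_species_params(small_grid, seed=2)
        curves = dict(params.curves)
        curves["c_tmean"] = LimitationCurve("trap", (1e5, 2e5, 3e5, 4e5))
        dead = TTRParameters(curves, b0=-30.0, b1=0.5)
        with pytest.raises(ValueError, match="habitable"):
            synthdata.simulate_occurrences(dead, small_grid, 5, seed=0)


# ----------------------------------------------------------------------
# path-model scenarios
# ----------------------------------------------------------------------
class TestPathScenario:
    def test_default_coefficients_imply_reported_totals(self):
        te = path_model.total_effect_matrix(synthdata.DEFAULT_PATH_COEFFICIENTS)
        assert np.isclose(te["cci"], -0.85, atol=1e-10)
        assert np.isclose(te["evo"], 0.61, atol=1e-10)
        assert np.isclose(te["age"], -0.21, atol=1e-10)
        assert te["size"] < 0

    def test_zero_residuals_identity_v_is_exactly_linear(self):
        star = TimeTree.from_newick("(" + ",".join(f"c{i}:1" for i in range(8)) + ");")
        scen = synthdata.PathScenario(
            n_clades=8,
            coefficients=dict(synthdata.DEFAULT_PATH_COEFFICIENTS),
            residual_sd={v: 1e-12 for v in ("evo", "size", "rich")},
            tree=star,
            seed=5,
        )
        design, truth = synthdata.simulate_path_dataset(scen)
        c = scen.coefficients
        evo = c[("cci", "evo")] * design["cci"]
        assert np.allclose(design["evo"], evo, atol=1e-9)
        rich = (
            c[("age", "rich")] * design["age"]
            + c[("cci", "rich")] * design["cci"]
            + c[("evo", "rich")] * design["evo"]
            + c[("size", "rich")] * design["size"]
        )
        assert np.allclose(design["rich"], rich, atol=1e-9)

    def test_richness_variance_matches_law_of_total_variance(self):
        scen = synthdata.make_path_scenario(n_clades=200, seed=2)
        implied = scen and synthdata.implied_covariance(scen)["rich"]
        sq = []
        for r in range(200):
            design, _ = synthdata.simulate_path_dataset(scen, seed=r)
            sq.append(np.mean(design["rich"].to_numpy() ** 2))
        assert abs(np.mean(sq) - implied) / implied < 0.10

    def test_coefficient_set_must_cover_dag(self):
        scen_tree = synthdata.simulate_bd_tree(5, birth=0.1, seed=0)
        bad = {("cci", "evo"): 0.1}
        with pytest.raises(ValueError):
            synthdata.PathScenario(
                n_clades=5,
                coefficients=bad,
                residual_sd={"evo": 0.4, "size": 0.4, "rich": 0.4},
                tree=scen_tree,
            )
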