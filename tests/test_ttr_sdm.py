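"""Limitation curves, growth recursion, likelihood and DE fitting."""

import numpy as np
import pytest

from nichediv import synthdata
from nichediv.env import VARIABLES
from nichediv.ttr_sdm import (
    CURVE_SPECS,
    LimitationCurve,
    TTRConfig,
    TTRParameters,
    PlantState,
    confusion,
    equilibrium_biomass,
    fit_ttr,
    limitation,
    neg_log_likelihood,
    occ_probability,
    theta_to_params,
    ttr_step,
)

TRAP = LimitationCurve("trap", (0.0, 10.0, 20.0, 30.0))


def _flat_params(c_mult=1.0, n_mult=1.0, g_mult=1.0, soil_n_curve=None, **kw):
    """Parameters whose multipliers are constants on a wide plateau."""
    curves = {}
    for name, var, kind, nbp in CURVE_SPECS:
        lo, hi = -1e6, 1e6
        if kind == "inc":
            curves[name] = LimitationCurve("inc", (lo, lo + 1))
        elif kind == "dec":
            curves[name] = LimitationCurve("dec", (hi - 1, hi))
        else:
            curves[name] = LimitationCurve("trap", (lo, lo + 1, hi - 1, hi))
    if soil_n_curve is not None:
        curves["n_soil_n"] = soil_n_curve
    return TTRParameters(curves, **kw)


def _constant_forcings(n_sites=1, **values):
    out = {}
    for var in VARIABLES:
        out[var] = np.full((n_sites, 12), values.get(var, 10.0))
    return out


class TestLimitation:
    @pytest.mark.parametrize(
        "x,expected",
        [(-5.0, 0.0), (5.0, 0.5), (15.0, 1.0), (25.0, 0.5), (35.0, 0.0)],
    )
    def test_trapezoid_values(self, x, expected):
        assert limitation(x, TRAP) == pytest.approx(expected)

    def test_step_curves(self):
        inc = LimitationCurve("inc", (0.0, 4.0))
        dec = LimitationCurve("dec", (0.0, 4.0))
        x = np.array([-1.0, 2.0, 9.0])
        assert np.allclose(limitation(x, inc), [0.0, 0.5, 1.0])
        assert np.allclose(limitation(x, dec), [1.0, 0.5, 0.0])

    def test_continuous_piecewise_linear_in_unit_interval(self):
        x = np.linspace(-10, 40, 5001)
        y = limitation(x, TRAP)
        assert np.all((y >= 0) & (y <= 1))
        # continuity: neighbouring values differ by at most slope * dx
        assert np.max(np.abs(np.diff(y))) <= 0.1 * (x[1] - x[0]) + 1e-12

    def test_unordered_breakpoints_raise(self):
        with pytest.raises(ValueError):
            LimitationCurve("trap", (0.0, 10.0, 5.0, 30.0))


class TestGrowthRecursion:
    def test_zero_uptake_makes_pools_non_increasing(self):
        params = _flat_params()
        # forcings below every curve's support except growth temperature
        curves = dict(params.curves)
        curves["c_tmean"] = LimitationCurve("trap", (1e7, 2e7, 3e7, 4e7))
        curves["n_tmean"] = LimitationCurve("inc", (1e7, 2e7))
        params = TTRParameters(curves)
        state = PlantState.initial((3,))
        forcing = {v: np.full(3, 10.0) for v in VARIABLES}
        prev_c, prev_n = state.biomass.copy(), state.total_n.copy()
        for _ in range(24):
            state = ttr_step(state, forcing, params)
            assert np.all(state.biomass <= prev_c + 1e-12)
            assert np.all(state.total_n <= prev_n + 1e-12)
            prev_c, prev_n = state.biomass.copy(), state.total_n.copy()

    def test_one_equilibrium_year_equals_twelve_steps(self):
        params = _flat_params()
        forc = _constant_forcings(2)
        b = equilibrium_biomass(params, forc, max_years=1, tol=0.0)
        state = PlantState.initial((2,))
        for m in range(12):
            state = ttr_step(state, {v: forc[v][:, m] for v in VARIABLES}, params)
        assert np.allclose(b, state.biomass)

    def test_missing_forcing_names_variable(self):
        params = _flat_params()
        state = PlantState.initial((1,))
        forcing = {v: np.array([10.0]) for v in VARIABLES if v != "soil_n"}
        with pytest.raises(KeyError, match="soil_n"):
            ttr_step(state, forcing, params)


class TestEquilibrium:
    def test_no_uptake_site_decays_to_zero(self):
        params = _flat_params()
        curves = dict(params.curves)
        curves["c_tmean"] = LimitationCurve("trap", (1e7, 2e7, 3e7, 4e7))
        curves["n_soil_n"] = LimitationCurve("inc", (1e7, 2e7))
        params = TTRParameters(curves)
        b = equilibrium_biomass(params, _constant_forcings(), max_years=200)
        assert b[0] == pytest.approx(0.0, abs=1e-6)

    def test_monotone_in_soil_nitrogen(self):
        """With all other multipliers saturated, more soil N never hurts."""
        curve = LimitationCurve("inc", (0.0, 8.0))
        params = _flat_params(soil_n_curve=curve)
        biomasses = []
        for soil_n in np.linspace(0.5, 8.0, 8):
            forc = _constant_forcings(soil_n=soil_n)
            biomasses.append(equilibrium_biomass(params, forc, max_years=150)[0])
        assert np.all(np.diff(biomasses) >= -1e-9)
        assert biomasses[-1] > biomasses[0]

    def test_wider_plateaus_never_decrease_biomass(self):
        """Dominance: relaxing every limitation curve cannot lower biomass."""
        grid = synthdata.simulate_environment(3, 3, autocorr_range=2.0, seed=0)
        narrow = synthdata.example_species_params(grid, seed=1, breadth=0.3)
        wide_curves = {}
        for name, var, kind, nbp in CURVE_SPECS:
            bp = np.array(narrow.curves[name].breakpoints)
            if kind == "inc":
                wide = (bp[0] - abs(bp[0]) - 10, bp[1] - (bp[1] - bp[0]) / 2)
            elif kind == "dec":
                wide = (bp[0] + (bp[1] - bp[0]) / 2, bp[1] + abs(bp[1]) + 10)
            else:
                wide = (bp[0] - 10, bp[1] - (bp[1] - bp[0]) / 2,
                        bp[2] + (bp[3] - bp[2]) / 2, bp[3] + 10)
            wide_curves[name] = LimitationCurve(kind, tuple(np.sort(wide)))
        wide_p = TTRParameters(wide_curves)
        forc = grid.forcings_at(np.arange(grid.n_cells))
        b_narrow = equilibrium_biomass(narrow, forc, max_years=150)
        b_wide = equilibrium_biomass(wide_p, forc, max_years=150)
        assert np.all(b_wide >= b_narrow - 1e-9)

    def test_convergence_flag_false_when_capped(self):
        params = _flat_params()
        _, conv = equilibrium_biomass(
            params, _constant_forcings(), max_years=1, tol=1e-15,
            return_converged=True,
        )
        assert not np.any(conv)


class TestOccurrenceModel:
    def test_cloglog_closed_forms(self):
        assert occ_probability(0.0, 0.0, 1.0) == pytest.approx(1 - np.exp(-1))
        p = occ_probability(np.array([0.0, 5.0, 50.0]), -1.0, 0.0)
        assert np.allclose(p, 1 - np.exp(-np.exp(-1.0)))

    def test_monotone_in_biomass(self):
        b = np.linspace(0, 20, 50)
        p = occ_probability(b, -2.0, 0.7)
        assert np.all(np.diff(p) >= 0)
        with pytest.raises(ValueError):
            occ_probability(1.0, 0.0, -0.5)

    def test_nll_hand_computed_cases(self):
        n = 7
        assert neg_log_likelihood(np.full(n, 0.5), np.ones(n)) == pytest.approx(
            n * np.log(2)
        )
        p = np.array([0.8, 0.3, 0.6])
        y = np.array([1, 0, 1])
        hand = -(np.log(0.8) + np.log(0.7) + np.log(0.6))
        assert neg_log_likelihood(p, y) == pytest.approx(hand)
        # perfect separation at clipped probabilities is ~0
        assert neg_log_likelihood(np.array([1.0, 0.0]), np.array([1, 0])) < 1e-9

    def test_nll_validates_labels(self):
        with pytest.raises(ValueError):
            neg_log_likelihood(np.array([0.5]), np.array([2]))

    def test_confusion_hand_counts(self):
        out = confusion(np.array([0.9, 0.4]), np.array([1, 1]))
        assert out["FN"] == 1 and out["false_negative_rate"] == 0.5
        out = confusion(np.full(5, 0.9), np.ones(5))
        assert out["FN"] == 0 and out["false_negative_rate"] == 0.0
        out = confusion(np.array([0.2, 0.7, 0.6, 0.1]), np.array([0, 1, 0, 0]))
        assert out["TP"] + out["TN"] + out["FP"] + out["FN"] == 4
        assert np.isnan(confusion(np.array([0.2]), np.array([0]))["false_negative_rate"])


@pytest.fixture(scope="module")
def tiny_fit():
    grid = synthdata.simulate_environment(8, 8, autocorr_range=2.0, seed=2)
    params = synthdata.example_species_params(grid, seed=4, breadth=0.5)
    pres = synthdata.simulate_occurrences(params, grid, 12, seed=1)
    rng = np.random.default_rng(0)
    abs_cells = rng.choice(grid.n_cells, size=12, replace=False)
    pc = grid.cell_index(pres["lon"].to_numpy(), pres["lat"].to_numpy())
    settings = {"popsize": 6, "maxiter": 8, "max_years": 10}
    args = (grid.forcings_at(pc), grid.forcings_at(abs_cells))
    fit1 = fit_ttr(*args, seed=5, de_settings=settings)
    fit2 = fit_ttr(*args, seed=5, de_settings=settings)
    return fit1, fit2


class TestFitting:
    def test_same_seed_identical_fit(self, tiny_fit):
        fit1, fit2 = tiny_fit
        assert np.allclose(fit1.params.to_vector(), fit2.params.to_vector())
        assert fit1.nll == fit2.nll

    def test_best_likelihood_trace_is_monotone(self, tiny_fit):
        fit1, _ = tiny_fit
        assert np.all(np.diff(fit1.trace) <= 1e-12)

    def test_breakpoints_sorted_by_reparameterization(self, tiny_fit):
        fit1, _ = tiny_fit
        for name, _, _, _ in CURVE_SPECS:
            bp = fit1.params.curves[name].breakpoints
            assert all(b2 >= b1 for b1, b2 in zip(bp, bp[1:]))

    def test_minimum_site_counts_enforced(self):
        forc = _constant_forcings(3)
        with pytest.raises(ValueError):
            fit_ttr(forc, forc, seed=0)

    def test_theta_decoding_orders_breakpoints(self):
        rng = np.random.default_rng(3)
        theta = rng.uniform(-5, 5, size=26)
        params = theta_to_params(theta)
        vec = params.to_vector()
        i = 0
        for _, _, _, nbp in CURVE_SPECS:
            assert np.all(np.diff(vec[i : i + nbp]) >= 0)
            i += nbp
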