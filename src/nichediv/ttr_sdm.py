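"""Process-based physiological species distribution model.

A two-compartment (shoot/root) carbon-nitrogen plant growth model in the
transport-resistance tradition drives occupancy predictions.  Resource
uptake and growth are limited by piecewise-linear response curves of the
monthly environmental forcings; the breakpoints of those curves are the
species' physiological niche traits.  Equilibrium biomass maps to
occurrence probability through a complementary log-log link, and the
breakpoints plus link coefficients are estimated from presence/absence
data by differential evolution on the Bernoulli likelihood.

Model structure (one monthly step, all pools dimensionless):

    fC = prod of carbon-uptake limitation multipliers
    fN = prod of nitrogen-uptake limitation multipliers
    fG = growth/respiration temperature multiplier
    growth  = uc * fG * fC * Cs/(1+Cs) * Ns/(kn+Ns)     (joint C+N limitation)
    uptakeN = un * fN * Cr/(1+Cr) * max(0, 1-Nr/nmax)
    TC = tc*(Cs-Cr),  TN = tn*(Nr-Ns)                    (transport resistance)
    Cs += growth - TC - resp*fG*Cs
    Cr += TC - resp*fG*Cr
    Ns += TN - q*growth
    Nr += uptakeN - TN

Pools are clipped at zero after each step.  Equilibrium biomass is the
shoot+root carbon after annual cycles converge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import differential_evolution

from .env import VARIABLES

__all__ = [
    "LimitationCurve",
    "TTRParameters",
    "TTRConfig",
    "PlantState",
    "SDMFit",
    "CURVE_SPECS",
    "TRAIT_NAMES",
    "limitation",
    "ttr_step",
    "equilibrium_biomass",
    "occ_probability",
    "neg_log_likelihood",
    "fit_ttr",
    "confusion",
]

_EPS = 1e-12

# (curve name, forcing variable, kind, number of breakpoints)
# 24 breakpoints total; these breakpoints are the species' niche traits.
CURVE_SPECS: tuple[tuple[str, str, str, int], ...] = (
    ("c_tmin", "tmin", "inc", 2),  # frost limitation of carbon gain
    ("c_tmean", "tmean", "trap", 4),  # thermal optimum of carbon gain
    ("c_tmax", "tmax", "dec", 2),  # heat limitation of carbon gain
    ("c_soil_moisture", "soil_moisture", "trap", 4),  # drought & waterlogging
    ("c_radiation", "radiation", "inc", 2),  # light limitation
    ("n_tmean", "tmean", "inc", 2),  # temperature limitation of N uptake
    ("n_soil_moisture", "soil_moisture", "trap", 4),  # moisture envelope of N uptake
    ("n_soil_n", "soil_n", "inc", 2),  # soil-N availability
    ("g_tmean", "tmean", "inc", 2),  # growth/respiration temperature scaling
)

N_BREAKPOINTS = sum(nbp for *_, nbp in CURVE_SPECS)  # 24
N_FREE = N_BREAKPOINTS + 2  # + cloglog link (b0, b1)

#: Flat names of the 24 breakpoint niche traits, e.g. "n_soil_moisture_3"
TRAIT_NAMES: tuple[str, ...] = tuple(
    f"{name}_{k + 1}" for name, _, _, nbp in CURVE_SPECS for k in range(nbp)
)


@dataclass(frozen=True)
class LimitationCurve:
    """Piecewise-linear limitation response in [0, 1].

    kind "inc": 0 below p1, linear p1->p2, 1 above p2 (2 breakpoints);
    kind "dec": mirror image (2 breakpoints);
    kind "trap": 0 / rise p1->p2 / 1 on [p2,p3] / fall p3->p4 / 0
    (4 breakpoints).
    """

    kind: str
    breakpoints: tuple[float, ...]

    def __post_init__(self) -> None:
        nbp = {"inc": 2, "dec": 2, "trap": 4}.get(self.kind)
        if nbp is None:
            raise ValueError(f"unknown curve kind {self.kind!r}")
        if len(self.breakpoints) != nbp:
            raise ValueError(f"{self.kind} curve needs {nbp} breakpoints")
        if any(
            b - a < -1e-12 for a, b in zip(self.breakpoints, self.breakpoints[1:])
        ):
            raise ValueError("breakpoints must be sorted non-decreasing")


def limitation(x, curve: LimitationCurve):
    """Evaluate a limitation curve; vectorized over ``x``."""
    x = np.asarray(x, dtype=float)
    bp = curve.breakpoints
    if curve.kind == "inc":
        return np.clip((x - bp[0]) / max(bp[1] - bp[0], _EPS), 0.0, 1.0)
    if curve.kind == "dec":
        return 1.0 - np.clip((x - bp[0]) / max(bp[1] - bp[0], _EPS), 0.0, 1.0)
    rise = (x - bp[0]) / max(bp[1] - bp[0], _EPS)
    fall = (bp[3] - x) / max(bp[3] - bp[2], _EPS)
    return np.clip(np.minimum(rise, fall), 0.0, 1.0)


@dataclass(frozen=True)
class TTRParameters:
    """Full niche-trait set of one species: 24 breakpoints + link terms."""

    curves: dict[str, LimitationCurve]
    b0: float = 0.0
    b1: float = 1.0

    def __post_init__(self) -> None:
        for name, _, kind, _ in CURVE_SPECS:
            if name not in self.curves:
                raise ValueError(f"missing curve {name!r}")
            if self.curves[name].kind != kind:
                raise ValueError(f"curve {name!r} must have kind {kind!r}")
        if self.b1 < 0:
            raise ValueError("b1 must be non-negative")

    def to_vector(self) -> np.ndarray:
        """Flatten to (26,): 24 breakpoints in CURVE_SPECS order, b0, b1."""
        vals = [b for name, *_ in CURVE_SPECS for b in self.curves[name].breakpoints]
        return np.array(vals + [self.b0, self.b1])

    @classmethod
    def from_vector(cls, vec: np.ndarray, sort_within_curve: bool = False):
        vec = np.asarray(vec, dtype=float)
        if vec.size != N_FREE:
            raise ValueError(f"expected {N_FREE} values, got {vec.size}")
        curves = {}
        i = 0
        for name, _, kind, nbp in CURVE_SPECS:
            bp = vec[i : i + nbp]
            if sort_within_curve:
                bp = np.sort(bp)
            curves[name] = LimitationCurve(kind, tuple(bp))
            i += nbp
        return cls(curves, b0=float(vec[-2]), b1=float(max(vec[-1], 0.0)))

    def trait_dict(self) -> dict[str, float]:
        return dict(zip(TRAIT_NAMES, self.to_vector()[:N_BREAKPOINTS]))


@dataclass(frozen=True)
class TTRConfig:
    """Fixed kinetic constants of the growth recursion (per month).

    These rates are conventions of this implementation, exposed so they
    can be varied; they set the biomass scale, not the niche geometry.
    """

    uc: float = 1.0  # maximal carbon gain rate
    un: float = 0.5  # maximal nitrogen uptake rate
    tc: float = 0.1  # shoot->root carbon transport conductance
    tn: float = 0.1  # root->shoot nitrogen transport conductance
    resp: float = 0.05  # respiration rate per unit pool
    kn: float = 0.2  # half-saturation of growth on shoot N
    q: float = 0.2  # N consumed per unit carbon growth
    nmax: float = 5.0  # root N storage capacity
    init_pool: float = 0.1  # initial value of all four pools


@dataclass
class PlantState:
    """Shoot/root carbon and nitrogen pools (arrays broadcast together)."""

    shoot_c: np.ndarray
    root_c: np.ndarray
    shoot_n: np.ndarray
    root_n: np.ndarray

    @classmethod
    def initial(cls, shape, config: TTRConfig = TTRConfig()):
        full = lambda: np.full(shape, config.init_pool, dtype=float)
        return cls(full(), full(), full(), full())

    @property
    def biomass(self) -> np.ndarray:
        return self.shoot_c + self.root_c

    @property
    def total_n(self) -> np.ndarray:
        return self.shoot_n + self.root_n


def _multipliers(params: TTRParameters, forcing: dict[str, np.ndarray]):
    """(fC, fN, fG) limitation products for one month of forcings."""
    fC = fN = fG = 1.0
    for name, var, _, _ in CURVE_SPECS:
        m = limitation(forcing[var], params.curves[name])
        if name.startswith("c_"):
            fC = fC * m
        elif name.startswith("n_"):
            fN = fN * m
        else:
            fG = fG * m
    return fC, fN, fG


def ttr_step(
    state: PlantState,
    forcing: dict[str, np.ndarray],
    params: TTRParameters,
    config: TTRConfig = TTRConfig(),
) -> PlantState:
    """Advance the plant one month; pools are clipped at zero."""
    for var in VARIABLES:
        if var not in forcing:
            raise KeyError(f"forcing variable {var!r} missing from site data")
    fC, fN, fG = _multipliers(params, forcing)
    cs, cr, ns, nr = state.shoot_c, state.root_c, state.shoot_n, state.root_n
    growth = config.uc * fG * fC * cs / (1.0 + cs) * ns / (config.kn + ns)
    uptake_n = (
        config.un * fN * cr / (1.0 + cr) * np.clip(1.0 - nr / config.nmax, 0.0, None)
    )
    tc_flux = config.tc * (cs - cr)
    tn_flux = config.tn * (nr - ns)
    new = PlantState(
        np.clip(cs + growth - tc_flux - config.resp * fG * cs, 0.0, None),
        np.clip(cr + tc_flux - config.resp * fG * cr, 0.0, None),
        np.clip(ns + tn_flux - config.q * growth, 0.0, None),
        np.clip(nr + uptake_n - tn_flux, 0.0, None),
    )
    return new


def equilibrium_biomass(
    params: TTRParameters,
    site_forcings: dict[str, np.ndarray],
    max_years: int = 200,
    tol: float = 1e-4,
    config: TTRConfig = TTRConfig(),
    return_converged: bool = False,
):
    """Iterate annual cycles to the equilibrium shoot+root carbon.

    ``site_forcings[var]`` has shape ``(..., 12)`` (any leading shape of
    sites/candidates); returns biomass with that leading shape.
    Convergence: relative change of biomass between successive years
    below ``tol``.
    """
    if max_years < 1:
        raise ValueError("max_years must be >= 1")
    lead = np.broadcast_shapes(*(np.shape(site_forcings[v])[:-1] for v in VARIABLES))
    state = PlantState.initial(lead, config)
    biomass = state.biomass.copy()
    converged = np.zeros(lead, dtype=bool) if lead else np.array(False)
    for _year in range(max_years):
        for m in range(12):
            month = {v: np.asarray(site_forcings[v])[..., m] for v in VARIABLES}
            state = ttr_step(state, month, params, config)
        if not np.all(np.isfinite(state.biomass)):
            raise FloatingPointError(
                "non-finite plant state at sites "
                f"{np.flatnonzero(~np.isfinite(np.atleast_1d(state.biomass)))[:10]}"
            )
        new_b = state.biomass
        converged = np.abs(new_b - biomass) <= tol * np.maximum(biomass, 1e-8)
        biomass = new_b.copy()
        if np.all(converged):
            break
    if return_converged:
        return biomass, converged
    return biomass


def occ_probability(biomass, b0: float, b1: float):
    """Complementary log-log link: p = 1 - exp(-exp(b0 + b1*biomass))."""
    if b1 < 0:
        raise ValueError("b1 must be non-negative")
    eta = np.clip(b0 + b1 * np.asarray(biomass, dtype=float), -700, 30)
    return 1.0 - np.exp(-np.exp(eta))


def neg_log_likelihood(p, y) -> float:
    """Bernoulli negative log-likelihood with probabilities clipped 1e-12."""
    p = np.clip(np.asarray(p, dtype=float), _EPS, 1.0 - _EPS)
    y = np.asarray(y, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("y must be 0/1")
    return float(-np.sum(y * np.log(p) + (1.0 - y) * np.log1p(-p)))


def confusion(p, y, threshold: float = 0.5) -> dict[str, float]:
    """Confusion counts at a probability threshold plus false-negative rate."""
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=int)
    pred = p >= threshold
    tp = int(np.sum(pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    fnr = fn / (fn + tp) if (fn + tp) > 0 else float("nan")
    return {"TP": tp, "TN": tn, "FP": fp, "FN": fn, "false_negative_rate": fnr}


# ----------------------------------------------------------------------
# fitting
# ----------------------------------------------------------------------
@dataclass
class SDMFit:
    """Result of a differential-evolution fit of the SDM."""

    params: TTRParameters
    nll: float
    p: np.ndarray
    y: np.ndarray
    confusion: dict[str, float]
    seed: int
    converged: bool
    message: str
    trace: list[float] = field(default_factory=list)
    n_iterations: int = 0
    n_evaluations: int = 0
    config: TTRConfig = TTRConfig()


def _theta_bounds(site_forcings: dict[str, np.ndarray]):
    """Box bounds for the increment parameterization of the 26 free scalars.

    Each curve is encoded as (first breakpoint, positive increments), so
    every candidate decodes to sorted breakpoints and the search stays
    box-constrained.
    """
    bounds = []
    for _, var, _, nbp in CURVE_SPECS:
        v = np.asarray(site_forcings[var])
        lo, hi = float(v.min()), float(v.max())
        span = max(hi - lo, 1e-6)
        lo -= 0.1 * span
        hi += 0.1 * span
        bounds.append((lo, hi))  # first breakpoint
        for _ in range(nbp - 1):
            bounds.append((0.0, 1.2 * span))  # increments
    bounds.append((-10.0, 5.0))  # b0
    bounds.append((0.0, 10.0))  # b1
    return bounds


def _init_population(
    site_forcings: dict[str, np.ndarray],
    n_members: int,
    bounds,
    rng: np.random.Generator,
) -> np.ndarray:
    """Feasible starting population on the increment parameterization.

    Random box candidates almost always switch every limitation
    multiplier to zero (no biomass anywhere), leaving the likelihood on
    a flat plateau.  Instead, breakpoints are drawn at random quantiles
    of the observed forcing distributions with plateaus that overlap the
    data, so initial members produce spatially varying suitability.
    """
    quant = {}
    for _, var, _, _ in CURVE_SPECS:
        v = np.sort(np.asarray(site_forcings[var]).ravel())
        quant[var] = v
    theta = np.empty((n_members, N_FREE))
    for s in range(n_members):
        i = 0
        for _, var, kind, nbp in CURVE_SPECS:
            v = quant[var]
            q = lambda x: float(np.interp(x, np.linspace(0, 1, v.size), v))
            if kind == "inc":
                a = rng.uniform(0.0, 0.6)
                bp = (q(a * rng.uniform(0, 1)), q(a))
            elif kind == "dec":
                a = rng.uniform(0.4, 1.0)
                bp = (q(a), q(a + (1 - a) * rng.uniform(0, 1)))
            else:
                lo = rng.uniform(0.0, 0.35)
                hi = rng.uniform(0.65, 1.0)
                bp = (q(lo * rng.uniform(0, 1)), q(lo), q(hi),
                      q(hi + (1 - hi) * rng.uniform(0, 1)))
            theta[s, i] = bp[0]
            for k in range(1, nbp):
                theta[s, i + k] = bp[k] - bp[k - 1]
            i += nbp
        theta[s, -2] = rng.uniform(-4.0, 1.0)
        theta[s, -1] = rng.uniform(0.1, 2.0)
    # clip into bounds for safety
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    return np.clip(theta, lo[None, :], hi[None, :])


def theta_to_params(theta: np.ndarray) -> TTRParameters:
    """Decode an increment-parameterized vector into TTRParameters."""
    theta = np.asarray(theta, dtype=float)
    vec = np.empty(N_FREE)
    i = 0
    for _, _, _, nbp in CURVE_SPECS:
        vec[i] = theta[i]
        for k in range(1, nbp):
            vec[i + k] = vec[i + k - 1] + max(theta[i + k], 0.0)
        i += nbp
    vec[-2:] = theta[-2:]
    return TTRParameters.from_vector(vec)


def _batch_biomass(theta_batch, site_forcings, max_years, tol, config):
    """Equilibrium biomass for a (26, S) batch of candidate vectors.

    Vectorized over candidates and sites simultaneously; returns (S, n_sites).
    """
    theta_batch = np.atleast_2d(np.asarray(theta_batch, dtype=float))
    if theta_batch.shape[0] != N_FREE:
        theta_batch = theta_batch.T
    S = theta_batch.shape[1]
    # decode breakpoints: (S, 24)
    bps = np.empty((S, N_BREAKPOINTS))
    i = 0
    for _, _, _, nbp in CURVE_SPECS:
        bps[:, i] = theta_batch[i]
        for k in range(1, nbp):
            bps[:, i + k] = bps[:, i + k - 1] + np.maximum(theta_batch[i + k], 0.0)
        i += nbp

    n_sites = np.asarray(site_forcings["tmean"]).shape[0]
    cs = np.full((S, n_sites), config.init_pool)
    cr, ns, nr = cs.copy(), cs.copy(), cs.copy()
    biomass = cs + cr
    forc = {v: np.asarray(site_forcings[v], dtype=float) for v in VARIABLES}

    def lim_inc(x, p1, p2):
        return np.clip((x - p1) / np.maximum(p2 - p1, _EPS), 0.0, 1.0)

    # forcings repeat annually: precompute the 12 monthly multiplier fields
    fC12 = np.ones((12, S, n_sites))
    fN12 = np.ones((12, S, n_sites))
    fG12 = np.ones((12, S, n_sites))
    for m in range(12):
        i = 0
        for name, var, kind, nbp in CURVE_SPECS:
            x = forc[var][None, :, m]
            if kind == "inc":
                mlt = lim_inc(x, bps[:, i, None], bps[:, i + 1, None])
            elif kind == "dec":
                mlt = 1.0 - lim_inc(x, bps[:, i, None], bps[:, i + 1, None])
            else:
                rise = (x - bps[:, i, None]) / np.maximum(
                    bps[:, i + 1, None] - bps[:, i, None], _EPS
                )
                fall = (bps[:, i + 3, None] - x) / np.maximum(
                    bps[:, i + 3, None] - bps[:, i + 2, None], _EPS
                )
                mlt = np.clip(np.minimum(rise, fall), 0.0, 1.0)
            if name.startswith("c_"):
                fC12[m] *= mlt
            elif name.startswith("n_"):
                fN12[m] *= mlt
            else:
                fG12[m] *= mlt
            i += nbp

    for _year in range(max_years):
        for m in range(12):
            fC, fN, fG = fC12[m], fN12[m], fG12[m]
            growth = config.uc * fG * fC * cs / (1.0 + cs) * ns / (config.kn + ns)
            upn = (
                config.un
                * fN
                * cr
                / (1.0 + cr)
                * np.clip(1.0 - nr / config.nmax, 0.0, None)
            )
            tcf = config.tc * (cs - cr)
            tnf = config.tn * (nr - ns)
            cs = np.clip(cs + growth - tcf - config.resp * fG * cs, 0.0, None)
            cr = np.clip(cr + tcf - config.resp * fG * cr, 0.0, None)
            ns = np.clip(ns + tnf - config.q * growth, 0.0, None)
            nr = np.clip(nr + upn - tnf, 0.0, None)
        new_b = cs + cr
        if np.all(np.abs(new_b - biomass) <= tol * np.maximum(biomass, 1e-8)):
            biomass = new_b
            break
        biomass = new_b
    return biomass


def predict_probability(
    params: TTRParameters,
    site_forcings: dict[str, np.ndarray],
    max_years: int = 200,
    tol: float = 1e-4,
    config: TTRConfig = TTRConfig(),
) -> np.ndarray:
    """Occurrence probability of a species at sites given their forcings."""
    b = equilibrium_biomass(params, site_forcings, max_years, tol, config)
    return occ_probability(b, params.b0, params.b1)


def fit_ttr(
    presences: dict[str, np.ndarray],
    absences: dict[str, np.ndarray],
    seed: int,
    bounds=None,
    de_settings: dict | None = None,
    config: TTRConfig = TTRConfig(),
) -> SDMFit:
    """Fit the 26 free scalars to presence/absence sites.

    ``presences`` / ``absences`` map forcing variables to ``(n, 12)``
    monthly series at the sites.  Breakpoint ordering is enforced by the
    increment reparameterization; the optimizer is deterministic given
    ``seed``.
    """
    n_pres = np.asarray(presences["tmean"]).shape[0]
    n_abs = np.asarray(absences["tmean"]).shape[0]
    if n_pres < 5 or n_abs < 5:
        raise ValueError("need at least 5 presences and 5 absences")
    site_forcings = {
        v: np.vstack([np.asarray(presences[v]), np.asarray(absences[v])])
        for v in VARIABLES
    }
    y = np.concatenate([np.ones(n_pres), np.zeros(n_abs)])

    settings = {
        "popsize": 12,
        "maxiter": 120,
        "tol": 1e-3,
        "mutation": (0.4, 1.0),
        "recombination": 0.8,
        "max_years": 40,
        "eq_tol": 1e-3,
    }
    settings.update(de_settings or {})
    max_years = settings.pop("max_years")
    eq_tol = settings.pop("eq_tol")

    if bounds is None:
        bounds = _theta_bounds(site_forcings)

    trace: list[float] = []
    best = [np.inf]

    def objective(theta_batch):
        single = theta_batch.ndim == 1
        biomass = _batch_biomass(
            theta_batch if not single else theta_batch[:, None],
            site_forcings,
            max_years,
            eq_tol,
            config,
        )
        b0 = np.atleast_2d(theta_batch.T)[:, -2][:, None]
        b1 = np.clip(np.atleast_2d(theta_batch.T)[:, -1][:, None], 0.0, None)
        eta = np.clip(b0 + b1 * biomass, -700, 30)
        p = np.clip(1.0 - np.exp(-np.exp(eta)), _EPS, 1.0 - _EPS)
        nll = -np.sum(y * np.log(p) + (1.0 - y) * np.log1p(-p), axis=1)
        best[0] = min(best[0], float(nll.min()))
        trace.append(best[0])
        return nll[0] if single else nll

    n_members = max(settings.pop("popsize") * N_FREE, 5 * N_FREE)
    init = _init_population(
        site_forcings, n_members, bounds, np.random.default_rng(seed)
    )
    result = differential_evolution(
        objective,
        bounds,
        seed=seed,
        vectorized=True,
        updating="deferred",
        polish=False,
        init=init,
        **settings,
    )
    params = theta_to_params(result.x)
    biomass = _batch_biomass(
        result.x[:, None], site_forcings, max_years, eq_tol, config
    )[0]
    p = occ_probability(biomass, params.b0, params.b1)
    if not result.success:
        warnings.warn(f"differential evolution did not converge: {result.message}")
    return SDMFit(
        params=params,
        nll=float(result.fun),
        p=p,
        y=y.astype(int),
        confusion=confusion(p, y),
        seed=seed,
        converged=bool(result.success),
        message=str(result.message),
        trace=trace,
        n_iterations=int(result.nit),
        n_evaluations=int(result.nfev),
        config=config,
    )
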