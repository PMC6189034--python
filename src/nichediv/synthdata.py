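"""Synthetic data generators for every stage of the pipeline.

The empirical system this package targets — several hundred species with
a fossil-calibrated phylogeny, cleaned occurrence records and gridded
monthly forcings — is emulated here with known generating parameters:
birth-death clade structure, multivariate Brownian-motion niche traits,
spatially autocorrelated environmental fields, presence points sampled
from a physiological suitability surface, and clade-level path-model
datasets with recorded truth.  Every generator draws from its own
deterministic stream (seed + operation tag), so pipeline stages can be
re-run independently.
"""

from __future__ import annotations

import random as _random
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve
from scipy.special import expit

from . import path_model
from .env import N_MONTHS, VARIABLES, EnvGrid
from .trees import TimeTree
from .ttr_sdm import (
    CURVE_SPECS,
    LimitationCurve,
    TTRConfig,
    TTRParameters,
    predict_probability,
)

__all__ = [
    "rng_for",
    "simulate_bd_tree",
    "simulate_bm_traits",
    "simulate_environment",
    "simulate_occurrences",
    "PathScenario",
    "make_path_scenario",
    "simulate_path_dataset",
    "implied_covariance",
    "DEFAULT_PATH_COEFFICIENTS",
    "params_from_trait_vector",
    "example_species_params",
]


def rng_for(seed: int, tag: str) -> np.random.Generator:
    """Deterministic per-operation random stream."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(tag.encode())])
    )


# ----------------------------------------------------------------------
# trees
# ----------------------------------------------------------------------
def simulate_bd_tree(
    n_tips: int,
    birth: float,
    death: float = 0.0,
    crown_age: float | None = None,
    seed: int = 0,
) -> TimeTree:
    """Birth-death tree conditioned on tip count via GSA sampling.

    The generalized sampling approach simulates past the target richness
    and draws the observation time from the windows in which exactly
    ``n_tips`` lineages are extant, avoiding the bias of stopping at the
    n-th speciation event.  Optionally rescales to a fixed crown age.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if not (birth > death >= 0):
        raise ValueError("rates must satisfy birth > death >= 0")
    rng = rng_for(seed, "bd_tree")
    py_rng = _random.Random(int(rng.integers(2**31)))
    from dendropy.model import birthdeath

    dtree = birthdeath.birth_death_tree(
        birth_rate=birth,
        death_rate=death,
        num_extant_tips=n_tips,
        gsa_ntax=max(2 * n_tips, n_tips + 5),
        rng=py_rng,
    )
    tree = TimeTree.from_dendropy(dtree)
    if tree.n_tips != n_tips:
        raise RuntimeError("simulator returned wrong tip count")
    if crown_age is not None:
        tree = tree.rescaled(crown_age)
    return tree


# ----------------------------------------------------------------------
# traits
# ----------------------------------------------------------------------
def _psd_sqrt(M: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(M)
    if vals.min() < -1e-8 * max(vals.max(), 1.0):
        raise ValueError("rate_matrix must be positive semidefinite")
    vals = np.clip(vals, 0.0, None)
    return vecs * np.sqrt(vals)


def simulate_bm_traits(
    tree: TimeTree,
    rate_matrix: np.ndarray,
    root_state: np.ndarray | float = 0.0,
    seed: int = 0,
    trait_names: list[str] | None = None,
) -> pd.DataFrame:
    """Tip values of multivariate Brownian motion along the tree.

    Tip values are jointly Gaussian with covariance
    ``rate_matrix (x) V`` where V holds shared root-to-MRCA path
    lengths; the trait table has one row per tip.
    """
    R = np.atleast_2d(np.asarray(rate_matrix, dtype=float))
    p = R.shape[0]
    if R.shape != (p, p) or not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("rate_matrix must be symmetric")
    root = np.broadcast_to(np.asarray(root_state, dtype=float), (p,))
    rng = rng_for(seed, "bm_traits")
    V = tree.vcv()
    A = _psd_sqrt(V)  # (n, n)
    Bf = _psd_sqrt(R)  # (p, p)
    Z = rng.standard_normal((tree.n_tips, p))
    X = root[None, :] + A @ Z @ Bf.T
    names = trait_names or [f"trait_{j + 1}" for j in range(p)]
    return pd.DataFrame(X, index=tree.tip_labels, columns=names)


# ----------------------------------------------------------------------
# environment
# ----------------------------------------------------------------------
def _grf(shape, autocorr_range: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian random field, exponential kernel smoothing.

    White noise convolved with the kernel exp(-d / range); an infinite
    range degenerates to a single shared value (constant layer).
    """
    if np.isinf(autocorr_range):
        return np.full(shape, rng.standard_normal())
    noise = rng.standard_normal(shape)
    if autocorr_range <= 0:
        return noise
    r = int(np.ceil(4 * autocorr_range))
    ax = np.arange(-r, r + 1)
    dist = np.hypot(ax[:, None], ax[None, :])
    kernel = np.exp(-dist / autocorr_range)
    sm = fftconvolve(noise, kernel, mode="same")
    return (sm - sm.mean()) / max(sm.std(), 1e-12)


def simulate_environment(
    n_rows: int,
    n_cols: int,
    autocorr_range: float = 5.0,
    seed: int = 0,
    cell_size: float = 0.25,
    origin: tuple[float, float] = (0.0, 0.0),
    n_realms: int = 1,
) -> EnvGrid:
    """Spatially autocorrelated monthly forcing layers on a lon/lat grid.

    Each variable combines a static spatial field, a shared seasonal
    cycle and small month-specific fields; the tmin <= tmean <= tmax
    ordering is enforced by construction.  Cells are ``cell_size``
    degrees (0.25 by default) with centre registration.
    """
    if n_rows < 2 or n_cols < 2:
        raise ValueError("grid must be at least 2x2")
    rng = rng_for(seed, "environment")
    shape = (n_rows, n_cols)
    lon0, lat0 = origin
    lon = lon0 + cell_size * (np.arange(n_cols) + 0.5)
    lat = lat0 + cell_size * (np.arange(n_rows) + 0.5)

    month = np.arange(N_MONTHS)
    season = np.cos(2 * np.pi * (month - 6) / 12)  # peak mid-year

    def monthly(base_field, seas_amp, month_amp):
        layers = np.empty((N_MONTHS, n_rows, n_cols))
        for m in range(N_MONTHS):
            wiggle = month_amp * _grf(shape, autocorr_range, rng) if month_amp else 0.0
            layers[m] = base_field + seas_amp * season[m] + wiggle
        return layers

    t_space = _grf(shape, autocorr_range, rng)
    tmean = monthly(12.0 + 8.0 * t_space, 6.0, 1.0)
    dlo = 2.0 + 2.0 * expit(_grf(shape, autocorr_range, rng))
    dhi = 2.0 + 2.0 * expit(_grf(shape, autocorr_range, rng))
    tmin = tmean - dlo[None, :, :]
    tmax = tmean + dhi[None, :, :]

    sm_space = _grf(shape, autocorr_range, rng)
    soil_moisture = np.clip(
        expit(0.9 * sm_space)[None, :, :] + 0.15 * season[:, None, None], 0.02, 0.98
    )
    rad = np.clip(monthly(15.0 + 3.0 * _grf(shape, autocorr_range, rng), 6.0, 0.5), 0.5, None)
    soil_n = np.repeat(
        (1.0 + 3.0 * expit(_grf(shape, autocorr_range, rng)))[None, :, :],
        N_MONTHS,
        axis=0,
    )
    altitude = np.clip(500.0 + 400.0 * _grf(shape, autocorr_range, rng), 0.0, None)
    realm = None
    if n_realms > 1:
        edges = np.linspace(0, n_cols, n_realms + 1).astype(int)
        realm = np.zeros(shape, dtype=int)
        for r in range(n_realms):
            realm[:, edges[r] : edges[r + 1]] = r
    return EnvGrid(
        lon=lon,
        lat=lat,
        layers={
            "tmin": tmin,
            "tmean": tmean,
            "tmax": tmax,
            "soil_moisture": soil_moisture,
            "radiation": rad,
            "soil_n": soil_n,
        },
        altitude=altitude,
        realm=realm,
    )


# ----------------------------------------------------------------------
# species and occurrences
# ----------------------------------------------------------------------
def params_from_trait_vector(
    traits, b0: float = -6.0, b1: float = 1.5
) -> TTRParameters:
    """Build valid TTRParameters from a 24-vector of (raw) niche traits.

    Values are sorted within each limitation curve so any real-valued
    trait vector (e.g. Brownian-motion simulated) decodes to a valid
    breakpoint set.
    """
    vec = np.asarray(traits, dtype=float)
    full = np.concatenate([vec, [b0, b1]])
    return TTRParameters.from_vector(full, sort_within_curve=True)


def example_species_params(
    grid: EnvGrid, seed: int = 0, breadth: float = 0.5, b0: float = -6.0, b1: float = 1.5
) -> TTRParameters:
    """A species whose niche envelope sits inside the grid's forcing ranges.

    Breakpoints are placed at jittered quantile positions of each
    forcing variable so the suitability surface is informative (neither
    empty nor saturated); ``breadth`` widens or narrows the plateau.
    """
    rng = rng_for(seed, "example_species")
    curves = {}
    for name, var, kind, nbp in CURVE_SPECS:
        v = grid.layers[var]
        lo, hi = float(v.min()), float(v.max())
        span = max(hi - lo, 1e-9)
        j = 0.05 * rng.uniform(-1, 1, size=4)
        if kind == "inc":
            bp = (lo + (0.10 + j[0] * 0.5) * span, lo + (0.30 + j[1] * 0.5) * span)
        elif kind == "dec":
            bp = (hi - (0.30 - j[0] * 0.5) * span, hi - (0.10 - j[1] * 0.5) * span)
        else:
            half = breadth / 2
            bp = (
                lo + (0.5 - half - 0.15 + j[0]) * span,
                lo + (0.5 - half + 0.05 + j[1]) * span,
                lo + (0.5 + half - 0.05 + j[2]) * span,
                lo + (0.5 + half + 0.15 + j[3]) * span,
            )
        curves[name] = LimitationCurve(kind, tuple(np.sort(bp)))
    return TTRParameters(curves, b0=b0, b1=b1)


def simulate_occurrences(
    params: TTRParameters,
    grid: EnvGrid,
    n_presence: int,
    seed: int = 0,
    species: str = "sp1",
    replace: bool = True,
    max_years: int = 120,
    config: TTRConfig = TTRConfig(),
) -> pd.DataFrame:
    """Presence records sampled proportionally to modelled suitability."""
    cells = np.arange(grid.n_cells)
    p = predict_probability(
        params, grid.forcings_at(cells), max_years=max_years, config=config
    )
    p = np.where(p > 1e-10, p, 0.0)  # cloglog never reaches exactly 0
    total = p.sum()
    if total <= 0:
        raise ValueError("no habitable cells: suitability is zero everywhere")
    rng = rng_for(seed, "occurrences")
    chosen = rng.choice(cells, size=n_presence, replace=replace, p=p / total)
    lon, lat = grid.cell_lonlat()
    return pd.DataFrame(
        {
            "species": species,
            "lon": lon[chosen],
            "lat": lat[chosen],
            "altitude": grid.altitude_at(chosen),
        }
    )


# ----------------------------------------------------------------------
# path-model scenarios
# ----------------------------------------------------------------------
#: Generating edge coefficients whose implied total effects on richness
#: are cci -0.85, evo 0.61, age -0.21 with a negative niche-size effect
#: (the 10-clade-scale configuration).
DEFAULT_PATH_COEFFICIENTS: dict[tuple[str, str], float] = {
    ("cci", "evo"): -0.40,
    ("cci", "size"): -0.52,
    ("evo", "size"): -0.19,
    ("cci", "rich"): -0.762,
    ("evo", "rich"): 0.553,
    ("size", "rich"): -0.30,
    ("age", "rich"): -0.21,
}


@dataclass
class PathScenario:
    """Generating configuration for a clade-level path dataset."""

    n_clades: int
    coefficients: dict[tuple[str, str], float]
    residual_sd: dict[str, float]
    tree: TimeTree
    seed: int = 0
    dag: path_model.PathDAG = field(default_factory=path_model.PathDAG)

    def __post_init__(self) -> None:
        if set(self.coefficients) != set(self.dag.edges):
            raise ValueError("coefficients must cover exactly the DAG edges")
        if any(s <= 0 for s in self.residual_sd.values()):
            raise ValueError("residual sds must be positive")
        if self.tree.n_tips != self.n_clades:
            raise ValueError("clade tree size must equal n_clades")


def make_path_scenario(
    n_clades: int = 10,
    seed: int = 0,
    coefficients: dict | None = None,
    residual_sd: float | dict = 0.4,
) -> PathScenario:
    """Default scenario: Yule clade tree + the 10-clade-scale coefficients."""
    tree = simulate_bd_tree(n_clades, birth=0.1, death=0.0, crown_age=300.0, seed=seed)
    dag = path_model.PathDAG()
    if not isinstance(residual_sd, dict):
        residual_sd = {v: float(residual_sd) for v in dag.endogenous}
    return PathScenario(
        n_clades=n_clades,
        coefficients=dict(coefficients or DEFAULT_PATH_COEFFICIENTS),
        residual_sd=residual_sd,
        tree=tree,
        seed=seed,
    )


def simulate_path_dataset(
    scenario: PathScenario,
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Standardized clade metrics generated from the structural equations.

    Exogenous variables (age, competition index) are drawn marginally
    standard with the clade tree's correlation structure; each
    endogenous variable is its parents' linear combination plus
    MVN(0, sigma^2 V) residuals, where V is the clade-tree Brownian
    covariance normalized to unit diagonal.  Returns the design (columns
    age, cci, evo, size, rich) and the generating truth.
    """
    rng = rng_for(scenario.seed if seed is None else seed, "path_dataset")
    V = scenario.tree.vcv()
    V = V / np.diag(V).mean()
    # correlation form so standardized-scale coefficients are coherent
    d = np.sqrt(np.diag(V))
    Vbar = V / np.outer(d, d)
    A = _psd_sqrt(Vbar)
    n = scenario.n_clades

    def mvn():
        return A @ rng.standard_normal(n)

    data: dict[str, np.ndarray] = {}
    for var in scenario.dag.exogenous:
        data[var] = mvn()
    for var in scenario.dag.endogenous:
        mean = np.zeros(n)
        for par in scenario.dag.parents(var):
            mean = mean + scenario.coefficients[(par, var)] * data[par]
        data[var] = mean + scenario.residual_sd[var] * mvn()

    design = pd.DataFrame(
        {v: data[v] for v in path_model.VARIABLES}, index=scenario.tree.tip_labels
    )
    truth = {
        "coefficients": dict(scenario.coefficients),
        "residual_sd": dict(scenario.residual_sd),
        "total_effects": path_model.total_effect_matrix(scenario.coefficients),
        "V": Vbar,
        "implied_variance": implied_covariance(scenario),
    }
    return design, truth


def implied_covariance(scenario: PathScenario) -> dict[str, float]:
    """Model-implied marginal variance of each variable (per clade).

    Solves the structural system in reduced form: with x = B x + e and
    Var(e) = Psi (unit for exogenous, sigma^2 for endogenous),
    Var(x) = (I-B)^{-1} Psi (I-B)^{-T}.
    """
    order = list(path_model.VARIABLES)
    idx = {v: i for i, v in enumerate(order)}
    k = len(order)
    B = np.zeros((k, k))
    for (s, dst), c in scenario.coefficients.items():
        B[idx[dst], idx[s]] = c
    psi = np.ones(k)
    for v, s in scenario.residual_sd.items():
        psi[idx[v]] = s**2
    M = np.linalg.inv(np.eye(k) - B)
    cov = M @ np.diag(psi) @ M.T
    return {v: float(cov[idx[v], idx[v]]) for v in order}
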