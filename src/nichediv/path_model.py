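"""Bayesian phylogenetically corrected path analysis of clade richness.

A fixed a-priori DAG relates five clade-level variables: clade age
(``age``), clade competition index (``cci``), niche evolution rate
(``evo``), clade niche size (``size``) and species richness (``rich``).
Age and competition are exogenous; the three endogenous variables are
modelled by linear structural equations whose residuals follow a
multivariate normal with covariance sigma^2 * V, where V is the
Brownian-motion variance-covariance matrix of the clade-level tree.
Coefficients get diffuse Normal(0, 10^2) priors, residual scales
half-normal priors; sampling is Gibbs for the coefficients and
random-walk Metropolis for the log residual scales.

Total effects on richness are computed per posterior draw by summing
edge-coefficient products over every directed path, following the
standard direct + indirect decomposition of path analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trees import TimeTree

__all__ = [
    "PathDAG",
    "PhyloCovariance",
    "PathFit",
    "DEFAULT_EDGES",
    "clade_tree_vcv",
    "prepare_variables",
    "fit_path",
    "total_effects",
    "total_effect_matrix",
    "diagnose",
]

VARIABLES = ("age", "cci", "evo", "size", "rich")

DEFAULT_EDGES: tuple[tuple[str, str], ...] = (
    ("cci", "evo"),
    ("cci", "size"),
    ("evo", "size"),
    ("cci", "rich"),
    ("evo", "rich"),
    ("size", "rich"),
    ("age", "rich"),
)


@dataclass(frozen=True)
class PathDAG:
    """Directed acyclic graph of the structural model."""

    edges: tuple[tuple[str, str], ...] = DEFAULT_EDGES

    def __post_init__(self) -> None:
        for s, d in self.edges:
            if s not in VARIABLES or d not in VARIABLES:
                raise ValueError(f"unknown variable in edge {s}->{d}")
        if self._topological_order() is None:
            raise ValueError("edge set contains a cycle")

    def _topological_order(self) -> list[str] | None:
        indeg = {v: 0 for v in VARIABLES}
        for _, d in self.edges:
            indeg[d] += 1
        order, queue = [], [v for v in VARIABLES if indeg[v] == 0]
        while queue:
            v = queue.pop(0)
            order.append(v)
            for s, d in self.edges:
                if s == v:
                    indeg[d] -= 1
                    if indeg[d] == 0:
                        queue.append(d)
        return order if len(order) == len(VARIABLES) else None

    def parents(self, var: str) -> list[str]:
        return [s for s, d in self.edges if d == var]

    @property
    def endogenous(self) -> list[str]:
        order = self._topological_order()
        assert order is not None
        return [v for v in order if self.parents(v)]

    @property
    def exogenous(self) -> list[str]:
        return [v for v in VARIABLES if not self.parents(v)]

    def paths(self, source: str, target: str = "rich") -> list[list[tuple[str, str]]]:
        """All directed edge-paths from source to target."""
        out: list[list[tuple[str, str]]] = []

        def dfs(node: str, path: list[tuple[str, str]]) -> None:
            if node == target:
                out.append(list(path))
                return
            for s, d in self.edges:
                if s == node:
                    path.append((s, d))
                    dfs(d, path)
                    path.pop()

        dfs(source, [])
        return out


@dataclass
class PhyloCovariance:
    """Clade-tree Brownian covariance and its inverse."""

    tree: TimeTree
    V: np.ndarray
    V_inv: np.ndarray

    @property
    def clade_ids(self) -> list[str]:
        return self.tree.tip_labels


def clade_tree_vcv(clade_tree: TimeTree) -> PhyloCovariance:
    """Shared-path-length covariance of a clade-level tree.

    ``V[i, j]`` is the root-to-MRCA path length of clades i and j; the
    diagonal holds root-to-tip depths.  A non-ultrametric clade tree
    (clade crown ages differ) is accepted with a warning.
    """
    if clade_tree.n_tips < 3:
        raise ValueError("need at least 3 clades")
    if not clade_tree.is_ultrametric(rtol=1e-6):
        warnings.warn("clade tree is not ultrametric; using depths as-is")
    V = clade_tree.vcv()
    jitter = 1e-10 * np.trace(V) / V.shape[0]
    V_inv = np.linalg.inv(V + jitter * np.eye(V.shape[0]))
    return PhyloCovariance(clade_tree, V, V_inv)


# ----------------------------------------------------------------------
# variable preparation
# ----------------------------------------------------------------------
_COLUMN_MAP = {
    "age": "age",
    "competition_index": "cci",
    "evolution_rate": "evo",
    "niche_size": "size",
    "richness": "rich",
}


def prepare_variables(metrics: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Standardize the clade metrics table for the path model.

    Richness is log-transformed, divided by its maximum (relative log
    richness) and z-scored; every other variable is z-scored.  Returns
    the standardized design (columns age, cci, evo, size, rich, indexed
    by clade) and a transform record sufficient to invert the mapping.
    """
    required = set(_COLUMN_MAP)
    if not required.issubset(metrics.columns):
        raise ValueError(f"metrics table missing columns {required - set(metrics.columns)}")
    if len(metrics) < 3:
        raise ValueError("need at least 3 clades")
    out = {}
    record: dict = {}
    for col, short in _COLUMN_MAP.items():
        x = metrics[col].to_numpy(dtype=float)
        steps: list[tuple[str, float]] = []
        if short == "rich":
            x = np.log(x)
            mx = float(x.max())
            x = x / mx
            steps += [("log", np.nan), ("div_max", mx)]
        mu, sd = float(x.mean()), float(x.std(ddof=0))
        if sd == 0:
            raise ValueError(f"variable {col!r} has zero variance")
        out[short] = (x - mu) / sd
        steps.append(("zscore", (mu, sd)))
        record[short] = steps
    index = (
        metrics["clade_id"] if "clade_id" in metrics.columns else metrics.index
    )
    design = pd.DataFrame(out, index=index)
    return design, record


def invert_variables(design: pd.DataFrame, record: dict) -> pd.DataFrame:
    """Undo :func:`prepare_variables` (bookkeeping check)."""
    out = {}
    inv_map = {v: k for k, v in _COLUMN_MAP.items()}
    for short, steps in record.items():
        x = design[short].to_numpy(dtype=float)
        for name, val in reversed(steps):
            if name == "zscore":
                mu, sd = val
                x = x * sd + mu
            elif name == "div_max":
                x = x * val
            elif name == "log":
                x = np.exp(x)
        out[inv_map[short]] = x
    return pd.DataFrame(out, index=design.index)


# ----------------------------------------------------------------------
# MCMC fit
# ----------------------------------------------------------------------
DEFAULT_MCMC = {"chains": 3, "iterations": 15000, "burnin": 25000, "thin": 5}


@dataclass
class PathFit:
    """Posterior of all edge coefficients of the structural model."""

    draws: dict[tuple[str, str], np.ndarray]  # (chains, kept)
    sigma_draws: dict[str, np.ndarray]
    summary: pd.DataFrame
    rhat: dict[str, float]
    converged: bool
    settings: dict
    seed: int
    dag: PathDAG = field(default_factory=PathDAG)

    def stacked(self, edge: tuple[str, str]) -> np.ndarray:
        return self.draws[edge].reshape(-1)


def _summarize(name: str, x: np.ndarray) -> dict:
    lo, hi = np.percentile(x, [2.5, 97.5])
    return {
        "parameter": name,
        "mean": float(x.mean()),
        "sd": float(x.std(ddof=0)),
        "ci_lower": float(lo),
        "ci_upper": float(hi),
        "significant": bool(lo > 0 or hi < 0),
    }


def fit_path(
    design: pd.DataFrame,
    dag: PathDAG,
    phylo: PhyloCovariance,
    mcmc: dict | None = None,
    seed: int = 0,
    prior_sd: float = 10.0,
    sigma_prior_scale: float = 2.5,
) -> PathFit:
    """Sample the structural-equation posteriors.

    One linear regression per endogenous variable, residuals
    MVN(0, sigma^2 V); Gibbs updates for the coefficient blocks and a
    random-walk Metropolis step on log(sigma) per equation.  Chains are
    vectorized; draws are thinned after burn-in.
    """
    settings = dict(DEFAULT_MCMC)
    settings.update(mcmc or {})
    chains = settings["chains"]
    n_iter = settings["iterations"]
    burnin = settings["burnin"]
    thin = settings["thin"]
    if chains < 1 or n_iter < thin:
        raise ValueError("invalid MCMC settings")

    n = len(design)
    if n != phylo.V.shape[0]:
        raise ValueError("design rows must match clades in the covariance")
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(phylo.V + 1e-10 * np.trace(phylo.V) / n * np.eye(n))

    equations = []
    for var in dag.endogenous:
        parents = dag.parents(var)
        X = design[parents].to_numpy(dtype=float)
        y = design[var].to_numpy(dtype=float)
        equations.append((var, parents, X, y))

    from scipy.linalg import solve_triangular

    kept = n_iter // thin
    draws: dict[tuple[str, str], np.ndarray] = {}
    sigma_draws: dict[str, np.ndarray] = {}
    tau2 = prior_sd**2

    for var, parents, X, y in equations:
        Xw = solve_triangular(L, X, lower=True)
        yw = solve_triangular(L, y, lower=True)
        p = X.shape[1]
        XtX = Xw.T @ Xw
        Xty = Xw.T @ yw
        yty = float(yw @ yw)

        beta = np.zeros((chains, p))
        log_sig = np.zeros(chains)
        out_beta = np.empty((chains, kept, p))
        out_sig = np.empty((chains, kept))
        eye = np.eye(p)
        step = 0.25
        k = 0
        for it in range(burnin + n_iter):
            sig2 = np.exp(2 * log_sig)
            # Gibbs: beta | sigma
            A = XtX[None, :, :] / sig2[:, None, None] + eye[None, :, :] / tau2
            b = Xty[None, :] / sig2[:, None]
            La = np.linalg.cholesky(A)
            mean = np.linalg.solve(A, b[:, :, None])[:, :, 0]
            z = rng.standard_normal((chains, p))
            # sample: mean + La^{-T} z
            pert = np.linalg.solve(np.transpose(La, (0, 2, 1)), z[:, :, None])[:, :, 0]
            beta = mean + pert
            # Metropolis: log sigma | beta
            ssr = (
                yty
                - 2 * beta @ Xty
                + np.einsum("cp,pq,cq->c", beta, XtX, beta)
            )
            ssr = np.clip(ssr, 1e-12, None)

            def logpost(ls):
                s2 = np.exp(2 * ls)
                # likelihood + half-normal prior on sigma + Jacobian (d sigma/d ls)
                return (
                    -n * ls
                    - ssr / (2 * s2)
                    - np.exp(2 * ls) / (2 * sigma_prior_scale**2)
                    + ls
                )

            prop = log_sig + step * rng.standard_normal(chains)
            accept = np.log(rng.uniform(size=chains)) < logpost(prop) - logpost(
                log_sig
            )
            log_sig = np.where(accept, prop, log_sig)
            if it >= burnin and (it - burnin) % thin == thin - 1:
                out_beta[:, k, :] = beta
                out_sig[:, k] = np.exp(log_sig)
                k += 1
        for j, par in enumerate(parents):
            draws[(par, var)] = out_beta[:, :, j]
        sigma_draws[var] = out_sig

    # summaries + diagnostics
    rows = []
    for (s, d), x in draws.items():
        rows.append(_summarize(f"{s}->{d}", x.reshape(-1)))
    summary = pd.DataFrame(rows)
    named = {f"{s}->{d}": x for (s, d), x in draws.items()}
    named.update({f"sigma_{v}": x for v, x in sigma_draws.items()})
    rhat = diagnose(named)["rhat"] if chains >= 2 else {}
    converged = all(v < 1.1 for v in rhat.values()) if rhat else True
    if not converged:
        warnings.warn("MCMC chains did not converge (R-hat > 1.1)")
    return PathFit(
        draws=draws,
        sigma_draws=sigma_draws,
        summary=summary,
        rhat=rhat,
        converged=converged,
        settings=settings,
        seed=seed,
        dag=dag,
    )


def total_effects(fit: PathFit, dag: PathDAG | None = None) -> tuple[pd.DataFrame, dict]:
    """Total effect of each predictor on richness, per posterior draw.

    Total effect = sum over all directed paths to richness of the product
    of the path's edge coefficients (direct edge included as the length-1
    path).
    """
    dag = dag or fit.dag
    effects: dict[str, np.ndarray] = {}
    some = next(iter(fit.draws.values()))
    for var in VARIABLES:
        if var == "rich":
            continue
        paths = dag.paths(var, "rich")
        if not paths:
            continue
        total = np.zeros_like(some)
        for path in paths:
            prod = np.ones_like(some)
            for edge in path:
                prod = prod * fit.draws[edge]
            total = total + prod
        effects[var] = total
    rows = [_summarize(v, x.reshape(-1)) for v, x in effects.items()]
    return pd.DataFrame(rows), effects


def total_effect_matrix(coeffs: dict[tuple[str, str], float]) -> dict[str, float]:
    """Closed-form total effects via (I - B)^{-1} on the coefficient matrix.

    ``B[i, j]`` holds the coefficient of edge j->i; the total-effect
    matrix is (I-B)^{-1} - I and the richness row gives each predictor's
    total effect.  Used as the algebraic oracle for the draw-wise path
    enumeration.
    """
    idx = {v: i for i, v in enumerate(VARIABLES)}
    B = np.zeros((len(VARIABLES), len(VARIABLES)))
    for (s, d), c in coeffs.items():
        B[idx[d], idx[s]] = c
    T = np.linalg.inv(np.eye(len(VARIABLES)) - B) - np.eye(len(VARIABLES))
    return {v: float(T[idx["rich"], idx[v]]) for v in VARIABLES if v != "rich"}


def diagnose(draws: dict[str, np.ndarray]) -> dict:
    """Split-R-hat and effective sample size per parameter (via arviz)."""
    import arviz as az

    ds = az.convert_to_dataset({k: np.asarray(v) for k, v in draws.items()})
    rhat = az.rhat(ds)
    ess = az.ess(ds)
    return {
        "rhat": {k: float(rhat[k].values) for k in draws},
        "ess": {k: float(ess[k].values) for k in draws},
        "pass": all(float(rhat[k].values) < 1.1 for k in draws),
    }
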