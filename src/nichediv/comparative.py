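"""Phylogenetic comparative statistics on niche traits.

Implements Felsenstein's independent contrasts, maximum-likelihood
Pagel's lambda with a boundary-halved likelihood-ratio test, Blomberg's
K with a tip-randomization test, phylogenetically corrected PCA for
trait selection, PGLS regression (through statsmodels GLS with the
Brownian tree covariance), and the node-level contrast ANOVA of
per-clade trait evolution rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .trees import TimeTree

__all__ = [
    "ContrastSet",
    "SignalStats",
    "PGLSFit",
    "pic",
    "pic_rate",
    "pagels_lambda",
    "blomberg_k",
    "phylo_pca_select",
    "pgls",
    "node_rate_contrasts",
]


# ----------------------------------------------------------------------
# independent contrasts
# ----------------------------------------------------------------------
@dataclass
class ContrastSet:
    """Standardized contrasts at the internal nodes of a binary tree."""

    node_ids: np.ndarray  # (n_tips - 1,) internal node indices
    contrasts: np.ndarray  # (n_tips - 1, p) standardized contrasts
    variances: np.ndarray  # (n_tips - 1,) expected contrast variances
    node_values: np.ndarray  # (n_tips - 1, p) weighted ancestral values


def pic(tree: TimeTree, traits) -> ContrastSet:
    """Felsenstein's phylogenetic independent contrasts.

    ``traits`` is an (n_tips,) vector or (n_tips, p) matrix aligned with
    the tree's tip order (or a DataFrame/Series indexed by tip label).
    Contrasts are standardized by the square root of their expected
    variance (sum of adjusted branch lengths).
    """
    if isinstance(traits, (pd.DataFrame, pd.Series)):
        traits = (
            traits.reindex(tree.tip_labels).to_numpy(dtype=float)
            if isinstance(traits, pd.DataFrame)
            else traits.reindex(tree.tip_labels).to_numpy(dtype=float)
        )
    X = np.atleast_2d(np.asarray(traits, dtype=float))
    if X.shape[0] == 1 and tree.n_tips != 1:
        X = X.T
    if X.shape[0] != tree.n_tips:
        raise ValueError("trait rows must match tips")
    if np.isnan(X).any():
        raise ValueError("missing trait value at one or more tips")
    n, p = X.shape
    ch = tree.children()
    vals = np.zeros((tree.n_nodes, p))
    vals[:n] = X
    extra = tree.edge_length.copy()
    node_ids, contrasts, variances, node_values = [], [], [], []
    for node in tree.postorder():
        if node < n:
            continue
        kids = ch[node]
        if len(kids) != 2:
            raise ValueError("contrasts require a fully binary tree")
        c1, c2 = kids
        v1, v2 = extra[c1], extra[c2]
        u = (vals[c1] - vals[c2]) / np.sqrt(v1 + v2)
        vals[node] = (vals[c1] / v1 + vals[c2] / v2) / (1 / v1 + 1 / v2)
        extra[node] = tree.edge_length[node] + v1 * v2 / (v1 + v2)
        node_ids.append(node)
        contrasts.append(u)
        variances.append(v1 + v2)
        node_values.append(vals[node].copy())
    return ContrastSet(
        np.array(node_ids),
        np.vstack(contrasts),
        np.array(variances),
        np.vstack(node_values),
    )


def pic_rate(tree: TimeTree, traits) -> np.ndarray:
    """BM rate matrix from normalized contrasts: R = (1/N) sum u u^T."""
    cs = pic(tree, traits)
    U = cs.contrasts
    return U.T @ U / U.shape[0]


# ----------------------------------------------------------------------
# phylogenetic signal
# ----------------------------------------------------------------------
@dataclass
class SignalStats:
    trait: str
    lam: float
    p_lam: float
    K: float
    p_K: float


def _gls_mean(y: np.ndarray, Vinv: np.ndarray) -> float:
    one = np.ones(len(y))
    return float(one @ Vinv @ y / (one @ Vinv @ one))


def _bm_loglik(y: np.ndarray, V: np.ndarray) -> float:
    """Profile log-likelihood of BM with given covariance structure."""
    n = len(y)
    sign, logdet = np.linalg.slogdet(V)
    if sign <= 0:
        return -np.inf
    Vinv = np.linalg.inv(V)
    a = _gls_mean(y, Vinv)
    r = y - a
    s2 = float(r @ Vinv @ r) / n
    if s2 <= 0:
        return -np.inf
    return -0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)


def _lambda_cov(V: np.ndarray, lam: float) -> np.ndarray:
    D = np.diag(np.diag(V))
    return lam * (V - D) + D


def lambda_max(V: np.ndarray, upper: float = 3.0) -> float:
    """Largest lambda keeping the scaled covariance positive definite."""
    lo, hi = 1.0, upper
    if np.linalg.eigvalsh(_lambda_cov(V, hi)).min() > 0:
        return hi
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if np.linalg.eigvalsh(_lambda_cov(V, mid)).min() > 0:
            lo = mid
        else:
            hi = mid
    return lo


def pagels_lambda(
    tree: TimeTree, trait, cap_at_one: bool = False
) -> tuple[float, float, float]:
    """ML Pagel's lambda and boundary-halved LRT p-value vs lambda = 0.

    Returns (lambda_hat, p_value, loglik_at_hat).  Lambda multiplies the
    off-diagonal shared path lengths; the search range is [0, lambda_max]
    where lambda_max keeps the covariance positive definite (optionally
    capped at 1).
    """
    y = _trait_vector(tree, trait)
    if tree.n_tips < 4:
        raise ValueError("need at least 4 tips")
    V = tree.vcv()
    lmax = 1.0 if cap_at_one else lambda_max(V)

    def nll(lam):
        return -_bm_loglik(y, _lambda_cov(V, lam))

    res = minimize_scalar(nll, bounds=(0.0, lmax), method="bounded",
                          options={"xatol": 1e-6})
    cands = [(float(res.x), -res.fun), (0.0, _bm_loglik(y, _lambda_cov(V, 0.0))),
             (lmax, _bm_loglik(y, _lambda_cov(V, lmax)))]
    lam_hat, ll_hat = max(cands, key=lambda t: t[1])
    ll0 = _bm_loglik(y, _lambda_cov(V, 0.0))
    lrt = max(2 * (ll_hat - ll0), 0.0)
    p = 0.5 * stats.chi2.sf(lrt, df=1) + 0.5 * (lrt == 0.0)
    return lam_hat, float(p), float(ll_hat)


def _trait_vector(tree: TimeTree, trait) -> np.ndarray:
    if isinstance(trait, pd.Series):
        trait = trait.reindex(tree.tip_labels).to_numpy(dtype=float)
    y = np.asarray(trait, dtype=float)
    if y.shape != (tree.n_tips,):
        raise ValueError("trait must be one value per tip")
    return y


def _k_statistic(y: np.ndarray, V: np.ndarray, Vinv: np.ndarray) -> float:
    n = len(y)
    a = _gls_mean(y, Vinv)
    r = y - a
    mse0 = float(r @ r) / (n - 1)
    mse = float(r @ Vinv @ r) / (n - 1)
    if mse <= 0:
        raise ValueError("trait has zero variance; K undefined")
    expected = (np.trace(V) - n / np.ones(n).dot(Vinv).dot(np.ones(n))) / (n - 1)
    return (mse0 / mse) / expected


def blomberg_k(
    tree: TimeTree, trait, n_sim: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Blomberg's K with a tip-randomization significance test.

    K is calibrated to 1 under Brownian motion; the p-value is the
    (add-one) fraction of tip-label permutations whose K reaches the
    observed value.
    """
    y = _trait_vector(tree, trait)
    if tree.n_tips < 4:
        raise ValueError("need at least 4 tips")
    if np.allclose(y, y[0]):
        raise ValueError("trait has zero variance; K undefined")
    V = tree.vcv()
    Vinv = np.linalg.inv(V)
    k_obs = _k_statistic(y, V, Vinv)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_sim):
        k_perm = _k_statistic(rng.permutation(y), V, Vinv)
        if abs(k_perm) >= abs(k_obs):
            count += 1
    p = (count + 1) / (n_sim + 1)
    return float(k_obs), float(p)


def signal_table(
    tree: TimeTree, traits: pd.DataFrame, n_sim: int = 1000, seed: int = 0
) -> pd.DataFrame:
    """Per-trait lambda, P(lambda), K and P(K) summary table."""
    rows = []
    for j, name in enumerate(traits.columns):
        y = traits[name].reindex(tree.tip_labels).to_numpy(dtype=float)
        lam, p_lam, _ = pagels_lambda(tree, y)
        K, p_K = blomberg_k(tree, y, n_sim=n_sim, seed=seed + j)
        rows.append(
            {"trait": name, "lambda": lam, "p_lambda": p_lam, "K": K, "p_K": p_K}
        )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# trait selection by phylogenetic PCA
# ----------------------------------------------------------------------
def phylo_pca_select(
    tree: TimeTree,
    traits: pd.DataFrame,
    loading_cut: float = 0.3,
    var_target: float = 0.94,
    corr_threshold: float = 0.8,
) -> tuple[list[str], pd.DataFrame]:
    """Rank and select informative traits by phylogenetic PCA.

    The evolutionary covariance of the traits is the GLS-centred
    cross-product under BM; principal components are kept until the
    cumulative variance reaches ``var_target``; traits loading above
    ``loading_cut`` (absolute) on any kept PC are candidates, ranked by
    the loading magnitudes weighted by each PC's variance share, and
    pruned for collinearity (pairs with |r| > ``corr_threshold`` keep the
    higher-ranked member).
    """
    X = traits.reindex(tree.tip_labels).to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("traits must be complete")
    n, p = X.shape
    if p > n:
        import warnings

        warnings.warn("more traits than tips: evolutionary covariance is rank-deficient")
    V = tree.vcv()
    Vinv = np.linalg.inv(V)
    one = np.ones(n)
    a = (one @ Vinv @ X) / (one @ Vinv @ one)
    Xc = X - a
    C = Xc.T @ Vinv @ Xc / (n - 1)
    vals, vecs = np.linalg.eigh(C)
    order = np.argsort(vals)[::-1]
    vals, vecs = np.clip(vals[order], 0, None), vecs[:, order]
    share = vals / vals.sum()
    n_keep = int(np.searchsorted(np.cumsum(share), var_target) + 1)
    n_keep = min(n_keep, p)
    loadings = vecs[:, :n_keep]
    score = (np.abs(loadings) * share[:n_keep][None, :]).sum(axis=1)
    candidate = (np.abs(loadings) > loading_cut).any(axis=1)
    table = pd.DataFrame(
        {
            "trait": traits.columns,
            "score": score,
            "candidate": candidate,
            "max_abs_loading": np.abs(loadings).max(axis=1),
        }
    ).sort_values("score", ascending=False, kind="stable")
    # collinearity pruning among candidates, higher-ranked trait wins
    corr = np.corrcoef(X, rowvar=False)
    names = list(traits.columns)
    selected: list[str] = []
    for trait_name in table.loc[table["candidate"], "trait"]:
        j = names.index(trait_name)
        if all(
            abs(corr[j, names.index(s)]) <= corr_threshold for s in selected
        ):
            selected.append(trait_name)
    table["selected"] = table["trait"].isin(selected)
    return selected, table.reset_index(drop=True)


# ----------------------------------------------------------------------
# PGLS
# ----------------------------------------------------------------------
@dataclass
class PGLSFit:
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    transforms: dict[str, str]
    result: object


_TRANSFORMS = {
    "sqrt": np.sqrt,
    "log": np.log,
    "none": lambda x: x,
}


def pgls(
    y: str,
    X: list[str],
    data: pd.DataFrame,
    tree: TimeTree | None = None,
    V: np.ndarray | None = None,
    transforms: dict[str, str] | None = None,
) -> PGLSFit:
    """Phylogenetic GLS regression with BM correlation from the tree.

    ``transforms`` maps column names to "sqrt" / "log" / "none"
    (applied before fitting, e.g. sqrt for the competition index and
    evolution rate, log for richness).  With an identity correlation
    this reduces to ordinary least squares.
    """
    import statsmodels.api as sm

    transforms = transforms or {}
    df = data.copy()
    for col, tname in transforms.items():
        df[col] = _TRANSFORMS[tname](df[col].to_numpy(dtype=float))
    if V is None:
        if tree is None:
            raise ValueError("provide a tree or a covariance matrix")
        order = [lab for lab in tree.tip_labels]
        df = df.loc[order]
        V = tree.vcv()
    if np.linalg.eigvalsh(V).min() <= 0:
        raise ValueError("correlation matrix is not positive definite")
    yv = df[y].to_numpy(dtype=float)
    Xm = sm.add_constant(df[X].to_numpy(dtype=float))
    res = sm.GLS(yv, Xm, sigma=V).fit()
    names = ["intercept"] + list(X)
    return PGLSFit(
        params=pd.Series(res.params, index=names),
        bse=pd.Series(res.bse, index=names),
        tvalues=pd.Series(res.tvalues, index=names),
        pvalues=pd.Series(res.pvalues, index=names),
        transforms=transforms,
        result=res,
    )


# ----------------------------------------------------------------------
# node-level rate contrasts
# ----------------------------------------------------------------------
def node_rate_contrasts(
    clade_tree: TimeTree, rates: pd.DataFrame, log_transform: bool = True
) -> dict:
    """PIC-rescaled per-node trait evolution rates with ANOVA + Tukey HSD.

    ``rates`` is a clades x traits table of (positive) univariate BM
    rates.  Rates are log-transformed, rescaled by independent contrasts
    on the clade tree, and the per-trait contrast values at the terminal
    nodes (internal nodes with at least one tip child) are compared by
    one-way ANOVA and all pairwise Tukey-adjusted differences.
    """
    R = rates.reindex(clade_tree.tip_labels)
    if R.isna().any().any():
        raise ValueError("rates must be complete per clade x trait")
    X = R.to_numpy(dtype=float)
    if log_transform:
        X = np.log(X)
    cs = pic(clade_tree, X)
    ch = clade_tree.children()
    terminal = np.array(
        [any(c < clade_tree.n_tips for c in ch[node]) for node in cs.node_ids]
    )
    if terminal.sum() < 2:
        raise ValueError("need at least 2 terminal nodes")
    node_ids = cs.node_ids[terminal]
    values = cs.contrasts[terminal]  # (n_terminal, p traits)
    node_means = pd.Series(values.mean(axis=1), index=node_ids, name="mean_rate_pic")

    groups = [values[i] for i in range(len(node_ids))]
    flat = np.concatenate(groups)
    labels = np.concatenate(
        [np.full(len(g), str(nid)) for g, nid in zip(groups, node_ids)]
    )
    if np.allclose(flat, flat[0]):
        F, p = 0.0, 1.0
        tukey_df = pd.DataFrame(
            [
                {
                    "node_i": str(a),
                    "node_j": str(b),
                    "diff": 0.0,
                    "p_adj": 1.0,
                    "significant": False,
                }
                for i, a in enumerate(node_ids)
                for b in node_ids[i + 1 :]
            ]
        )
    else:
        F, p = stats.f_oneway(*groups)
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        tk = pairwise_tukeyhsd(flat, labels)
        tukey_df = pd.DataFrame(
            tk.summary().data[1:], columns=[c.lower() for c in tk.summary().data[0]]
        ).rename(
            columns={
                "group1": "node_i",
                "group2": "node_j",
                "meandiff": "diff",
                "p-adj": "p_adj",
                "reject": "significant",
            }
        )[["node_i", "node_j", "diff", "p_adj", "significant"]]
    return {
        "node_means": node_means,
        "anova_F": float(F),
        "anova_p": float(p),
        "df": (len(node_ids) - 1, flat.size - len(node_ids)),
        "tukey": tukey_df,
        "terminal_nodes": node_ids,
    }
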