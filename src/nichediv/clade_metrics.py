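"""Clade definitions and the clade-level diversification metrics.

Four quantities summarise each clade for the path analysis: crown age,
species richness, clade niche size (mean potential-range union of
fixed-size species subsamples, correcting for richness), niche
evolution rate (summed Brownian-motion rates of the niche traits on the
clade subtree), and the clade competition index (mean over within-clade
species pairs of rescaled Schoener niche overlap times geographic
overlap).  A tip-shuffle permutation test verifies that the expected
competition index does not depend on clade size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .comparative import pic_rate
from .geo import cross_distance_deg
from .trees import TimeTree

__all__ = [
    "CladePartition",
    "OverlapMatrices",
    "clades_by_time_slice",
    "clade_age",
    "clade_niche_size",
    "schoener_overlap",
    "schoener_matrix",
    "geographic_overlap",
    "competition_matrix",
    "clade_competition_index",
    "niche_evolution_rate",
    "permutation_bias_test",
    "clade_metrics_table",
]


@dataclass
class CladePartition:
    """Disjoint monophyletic clades over (a subset of) the tree's tips."""

    clades: dict[str, list[str]]
    method: str  # "topology" | "time-slice"
    slice_age: float | None = None
    dropped_tips: list[str] = field(default_factory=list)

    def sizes(self) -> dict[str, int]:
        return {cid: len(tips) for cid, tips in self.clades.items()}


def clades_by_time_slice(tree: TimeTree, slice_age: float = 33.9) -> CladePartition:
    """Clades = lineages crossing a fixed age; singletons dropped.

    Every edge spanning ``slice_age`` (Myr before present) defines a
    clade containing the tips below it.  Single-species clades are
    removed and reported, since the downstream metrics (evolution rate,
    overlaps) are undefined for one species.
    """
    ages = tree.node_ages()
    if slice_age >= ages[tree.root]:
        raise ValueError("slice age must be younger than the root")
    below = tree.tips_below()
    clades: dict[str, list[str]] = {}
    dropped: list[str] = []
    k = 0
    for node in range(tree.n_nodes):
        parent = tree.parent[node]
        if parent < 0:
            continue
        if ages[node] <= slice_age < ages[parent]:
            tips = [tree.tip_labels[t] for t in below[node]]
            if len(tips) == 1:
                dropped.extend(tips)
            else:
                k += 1
                clades[f"clade_{k}"] = tips
    return CladePartition(clades, "time-slice", slice_age, dropped)


def clade_age(tree: TimeTree, tips: list[str]) -> float:
    """Crown age: depth of the clade's MRCA below the present (Myr)."""
    idx = tree.tip_index(tips)
    if idx.size < 2:
        raise ValueError("crown age needs at least 2 tips")
    if not tree.is_monophyletic(idx):
        raise ValueError("tip set is not monophyletic")
    return float(tree.node_ages()[tree.mrca(idx)])


def clade_niche_size(
    occupancy: dict[str, np.ndarray],
    tips: list[str],
    m: int,
    reps: int = 10000,
    seed: int = 0,
    exhaustive_limit: int = 200,
) -> float:
    """Mean union range size of random ``m``-species subsamples.

    ``occupancy`` maps species to boolean occupancy vectors over a
    shared set of locations.  When the number of distinct subsets is
    small the mean is computed exhaustively; otherwise by Monte Carlo
    with ``reps`` draws.
    """
    if m > len(tips):
        raise ValueError("subsample size exceeds clade richness")
    occ = np.vstack([np.asarray(occupancy[t], dtype=bool) for t in tips])
    from math import comb

    n_subsets = comb(len(tips), m)
    if n_subsets <= exhaustive_limit:
        counts = [
            np.any(occ[list(sub)], axis=0).sum()
            for sub in combinations(range(len(tips)), m)
        ]
        return float(np.mean(counts))
    rng = np.random.default_rng(seed)
    total = 0.0
    for _ in range(reps):
        sub = rng.choice(len(tips), size=m, replace=False)
        total += np.any(occ[sub], axis=0).sum()
    return total / reps


# ----------------------------------------------------------------------
# overlaps
# ----------------------------------------------------------------------
def schoener_overlap(pa: np.ndarray, pb: np.ndarray) -> float:
    """Schoener's D between two probability surfaces on a shared grid.

    Each surface is normalized to sum to one; D = 1 - 0.5 * sum |a - b|.
    """
    pa = np.asarray(pa, dtype=float)
    pb = np.asarray(pb, dtype=float)
    if pa.shape != pb.shape:
        raise ValueError("surfaces must share one grid")
    sa, sb = pa.sum(), pb.sum()
    if sa <= 0 or sb <= 0:
        return 0.0
    return float(1.0 - 0.5 * np.abs(pa / sa - pb / sb).sum())


def schoener_matrix(surfaces: dict[str, np.ndarray]) -> pd.DataFrame:
    """Pairwise Schoener's D for all species, unit diagonal."""
    names = list(surfaces)
    D = np.eye(len(names))
    for i, j in combinations(range(len(names)), 2):
        D[i, j] = D[j, i] = schoener_overlap(surfaces[names[i]], surfaces[names[j]])
    return pd.DataFrame(D, index=names, columns=names)


def geographic_overlap(occsets: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Pairwise geographic overlap from mean cross-record distances.

    For each species pair: the mean great-circle distance over all
    cross-species record pairs; the pair matrix is min-max normalized to
    [0, 1] and subtracted from 1, so the closest pair scores 1 and the
    farthest 0.
    """
    names = list(occsets)
    if len(names) < 2:
        raise ValueError("need at least 2 species")
    pts = {}
    for s, df in occsets.items():
        if len(df) == 0:
            raise ValueError(f"species {s!r} has no records")
        pts[s] = df[["lon", "lat"]].to_numpy(dtype=float)
    n = len(names)
    mean_d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        d = cross_distance_deg(pts[names[i]], pts[names[j]])
        mean_d[i, j] = mean_d[j, i] = d.mean()
    off = mean_d[~np.eye(n, dtype=bool)]
    lo, hi = off.min(), off.max()
    span = max(hi - lo, 1e-300)
    overlap = 1.0 - (mean_d - lo) / span
    np.fill_diagonal(overlap, 1.0)
    return pd.DataFrame(overlap, index=names, columns=names)


@dataclass
class OverlapMatrices:
    """Species-pair Schoener (raw + rescaled) and geographic overlaps."""

    schoener_raw: pd.DataFrame
    schoener: pd.DataFrame  # min-max rescaled over the pair matrix
    geographic: pd.DataFrame

    @classmethod
    def build(
        cls, surfaces: dict[str, np.ndarray], occsets: dict[str, pd.DataFrame]
    ) -> "OverlapMatrices":
        raw = schoener_matrix(surfaces)
        D = raw.to_numpy().copy()
        n = D.shape[0]
        off = D[~np.eye(n, dtype=bool)]
        span = max(off.max() - off.min(), 1e-300)
        resc = (D - off.min()) / span
        np.fill_diagonal(resc, 1.0)
        rescaled = pd.DataFrame(np.clip(resc, 0, 1), index=raw.index, columns=raw.columns)
        return cls(raw, rescaled, geographic_overlap(occsets))

    @property
    def species(self) -> list[str]:
        return list(self.schoener.index)

    def competition(self) -> pd.DataFrame:
        """Pairwise competition: rescaled Schoener x geographic overlap."""
        geo = self.geographic.reindex(
            index=self.schoener.index, columns=self.schoener.columns
        )
        return self.schoener * geo


def competition_matrix(overlaps: OverlapMatrices) -> pd.DataFrame:
    return overlaps.competition()


def clade_competition_index(overlaps: OverlapMatrices, tips: list[str]) -> float:
    """Mean pairwise competition over all unordered within-clade pairs."""
    if len(tips) < 2:
        raise ValueError("clade competition index needs >= 2 species")
    comp = overlaps.competition().loc[tips, tips].to_numpy()
    iu = np.triu_indices(len(tips), k=1)
    return float(comp[iu].mean())


def _mean_offdiag_by_group(comp: np.ndarray, groups: list[np.ndarray]) -> np.ndarray:
    out = np.empty(len(groups))
    for g, idx in enumerate(groups):
        sub = comp[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), k=1)
        out[g] = sub[iu].mean()
    return out


def permutation_bias_test(
    overlaps: OverlapMatrices,
    clade_sizes: list[int],
    reps: int = 10000,
    seed: int = 0,
) -> dict:
    """Tip-shuffle null of the clade competition index vs clade size.

    Species are randomly reassigned to clades of the fixed sizes,
    ``reps`` times; the per-size null mean index is regressed on clade
    richness — an unbiased index gives a slope indistinguishable from
    zero, because the expected index equals the global mean pairwise
    competition for every clade size (linearity of expectation).
    """
    comp = overlaps.competition().to_numpy()
    n = comp.shape[0]
    if sum(clade_sizes) > n:
        raise ValueError("clade sizes exceed the species pool")
    rng = np.random.default_rng(seed)
    bounds = np.cumsum([0] + list(clade_sizes))
    null = np.empty((reps, len(clade_sizes)))
    for r in range(reps):
        perm = rng.permutation(n)
        groups = [perm[bounds[i] : bounds[i + 1]] for i in range(len(clade_sizes))]
        null[r] = _mean_offdiag_by_group(comp, groups)
    null_mean = null.mean(axis=0)
    null_se = null.std(axis=0, ddof=1) / np.sqrt(reps)
    sizes = np.asarray(clade_sizes, dtype=float)
    if np.unique(sizes).size < 2 or np.allclose(null_mean, null_mean[0]):
        slope, pvalue, intercept = 0.0, 1.0, float(null_mean.mean())
    else:
        reg = stats.linregress(sizes, null_mean)
        slope, pvalue, intercept = reg.slope, reg.pvalue, reg.intercept
    iu = np.triu_indices(n, k=1)
    return {
        "null_mean": null_mean,
        "null_se": null_se,
        "clade_sizes": sizes,
        "slope": float(slope),
        "intercept": float(intercept),
        "p_value": float(pvalue),
        "global_mean": float(comp[iu].mean()),
    }


# ----------------------------------------------------------------------
# evolution rate and the assembled metrics table
# ----------------------------------------------------------------------
def niche_evolution_rate(
    tree: TimeTree,
    tips: list[str],
    traits: pd.DataFrame,
    mode: str = "multivariate",
    top_trait: str | None = None,
) -> float:
    """Summed BM rate of the niche traits on the clade's subtree.

    The rate matrix is estimated from normalized independent contrasts;
    multivariate mode returns its trace (requires richness > trait
    count for a stable estimate, else falls back to univariate with a
    warning), univariate mode the rate of the single top-ranked trait.
    """
    if len(tips) < 2:
        raise ValueError("evolution rate needs >= 2 tips")
    sub = tree.extract_subtree(tips)
    if mode == "multivariate" and len(tips) <= traits.shape[1]:
        warnings.warn(
            "richness <= trait count: falling back to univariate rate"
        )
        mode = "univariate"
    if mode == "multivariate":
        X = traits.loc[sub.tip_labels]
        R = pic_rate(sub, X)
        return float(np.trace(R))
    if mode == "univariate":
        col = top_trait or traits.columns[0]
        y = traits.loc[sub.tip_labels, col]
        R = pic_rate(sub, y)
        return float(R[0, 0])
    raise ValueError(f"unknown mode {mode!r}")


def clade_metrics_table(
    tree: TimeTree,
    partition: CladePartition,
    traits: pd.DataFrame,
    occupancy: dict[str, np.ndarray],
    overlaps: OverlapMatrices,
    m: int = 12,
    reps: int = 10000,
    mode: str = "multivariate",
    top_trait: str | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """One row per clade: richness, age, niche size, rate, competition."""
    rows = []
    for cid, tips in partition.clades.items():
        rows.append(
            {
                "clade_id": cid,
                "richness": len(tips),
                "age": clade_age(tree, tips),
                "niche_size": clade_niche_size(
                    occupancy, tips, m=min(m, len(tips)), reps=reps, seed=seed
                ),
                "evolution_rate": niche_evolution_rate(
                    tree, tips, traits, mode=mode, top_trait=top_trait
                ),
                "competition_index": clade_competition_index(overlaps, tips),
            }
        )
    return pd.DataFrame(rows)
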