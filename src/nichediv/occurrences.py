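"""Occurrence cleaning, environmental zonation and pseudoabsence sampling.

Occurrence sets are plain DataFrames with columns
``species, lon, lat, altitude``.  Cleaning removes exact duplicate
coordinates and records whose reported altitude disagrees with the
gridded reference by more than a tolerance (300 m by default); such
records are reported, not silently repaired.  Environmental zones are
CLARA-style k-medoids clusters of the z-standardized monthly forcing
features, and pseudoabsences are drawn stratified across zones, outside
a great-circle buffer around the presences, and restricted to occupied
realms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .env import EnvGrid
from .geo import cross_distance_deg

__all__ = [
    "EnvZonePartition",
    "clean_occurrences",
    "classify_env_zones",
    "sample_pseudoabsences",
    "pam_exhaustive_objective",
]

REQUIRED_COLUMNS = ("species", "lon", "lat", "altitude")


def _check_occurrences(records: pd.DataFrame) -> pd.DataFrame:
    for col in ("species", "lon", "lat"):
        if col not in records.columns:
            raise ValueError(f"occurrence table missing column {col!r}")
    if len(records) == 0:
        raise ValueError("occurrence table is empty")
    if (records["lat"].abs() > 90).any() or (records["lon"].abs() > 180).any():
        raise ValueError("coordinates outside valid lon/lat ranges")
    return records


# ----------------------------------------------------------------------
# cleaning
# ----------------------------------------------------------------------
def clean_occurrences(
    records: pd.DataFrame,
    grid: EnvGrid,
    tolerance: float = 300.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop duplicate coordinates and altitude-inconsistent records.

    A record is rejected when the absolute difference between its
    reported altitude and the reference altitude of its grid cell
    exceeds ``tolerance`` metres.  Returns (cleaned records, rejection
    report); the report lists each dropped record with its reason, since
    replacement with nearby estimates is a judgement call left to the
    analyst.
    """
    records = _check_occurrences(records).reset_index(drop=True)
    dup_mask = records.duplicated(subset=["lon", "lat"], keep="first")
    report_rows = []
    for i in records.index[dup_mask]:
        report_rows.append({**records.loc[i].to_dict(), "reason": "duplicate"})
    kept = records[~dup_mask].copy()

    if "altitude" in kept.columns and grid.altitude is not None:
        cells = grid.cell_index(kept["lon"].to_numpy(), kept["lat"].to_numpy())
        ref = grid.altitude_at(cells)
        mismatch = np.abs(kept["altitude"].to_numpy(dtype=float) - ref) > tolerance
        for i, bad in zip(kept.index, mismatch):
            if bad:
                report_rows.append(
                    {**kept.loc[i].to_dict(), "reason": "altitude_mismatch"}
                )
        kept = kept[~mismatch]
    report = pd.DataFrame(
        report_rows, columns=list(records.columns) + ["reason"]
    )
    if len(kept) == 0:
        warnings.warn("all occurrence records were rejected")
    return kept.reset_index(drop=True), report


# ----------------------------------------------------------------------
# environmental zonation (CLARA-style k-medoids)
# ----------------------------------------------------------------------
@dataclass
class EnvZonePartition:
    """k-medoids partition of the grid cells in forcing-feature space."""

    k: int
    labels: np.ndarray  # (n_cells,) zone of every grid cell
    medoids: np.ndarray  # (k,) flat cell indices
    feature_mean: np.ndarray
    feature_std: np.ndarray

    def zone_of_cells(self, cells: np.ndarray) -> np.ndarray:
        return self.labels[np.asarray(cells, dtype=int)]


def _pam(dist: np.ndarray, k: int, rng: np.random.Generator, max_swaps: int = 200):
    """Partitioning-around-medoids on a precomputed distance matrix.

    Greedy BUILD followed by best-improvement SWAP until no swap lowers
    the total distance-to-medoid objective.
    """
    n = dist.shape[0]
    # BUILD
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    while len(medoids) < k:
        current = dist[:, medoids].min(axis=1)
        gains = np.maximum(current[None, :] - dist, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    medoids = np.array(medoids)

    def objective(meds):
        return dist[:, meds].min(axis=1).sum()

    best = objective(medoids)
    for _ in range(max_swaps):
        improved = False
        non_medoids = np.setdiff1d(np.arange(n), medoids)
        for mi in range(k):
            trial = medoids.copy()
            d_others = dist[:, np.delete(medoids, mi)]
            nearest_other = (
                d_others.min(axis=1) if k > 1 else np.full(n, np.inf)
            )
            # candidate objective for swapping medoid mi -> h, all h at once
            cand = np.minimum(nearest_other[:, None], dist[:, non_medoids]).sum(axis=0)
            h_best = int(np.argmin(cand))
            if cand[h_best] < best - 1e-12:
                trial[mi] = non_medoids[h_best]
                medoids = trial
                best = cand[h_best]
                improved = True
                break  # medoid set changed; restart swap scan
        if not improved:
            break
    return medoids, best


def pam_exhaustive_objective(dist: np.ndarray, k: int) -> float:
    """Brute-force optimal k-medoids objective (small instances only)."""
    from itertools import combinations

    n = dist.shape[0]
    best = np.inf
    for meds in combinations(range(n), k):
        best = min(best, dist[:, meds].min(axis=1).sum())
    return float(best)


def classify_env_zones(
    grid: EnvGrid,
    k: int = 25,
    sample_size: int = 400,
    n_samples: int = 5,
    seed: int = 0,
) -> EnvZonePartition:
    """CLARA-style sampled k-medoids on standardized forcing features.

    PAM runs on ``n_samples`` random subsamples of the cells (plus the
    incumbent medoids); each candidate medoid set is scored on the full
    grid and the best is kept.  Every cell is then assigned to its
    nearest medoid.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    feats = grid.feature_matrix()
    n = feats.shape[0]
    if k > n:
        raise ValueError("k exceeds the number of grid cells")
    mean = feats.mean(axis=0)
    std = feats.std(axis=0)
    std[std == 0] = 1.0
    Z = (feats - mean) / std
    if np.unique(Z, axis=0).shape[0] < k:
        raise ValueError("fewer distinct feature vectors than requested zones")

    rng = np.random.default_rng(seed)
    best_meds, best_obj = None, np.inf
    size = min(sample_size, n)
    for _ in range(n_samples):
        idx = rng.choice(n, size=size, replace=False)
        if best_meds is not None:
            idx = np.unique(np.concatenate([idx, best_meds]))
        sub = Z[idx]
        dist = np.sqrt(((sub[:, None, :] - sub[None, :, :]) ** 2).sum(-1))
        meds_local, _ = _pam(dist, k, rng)
        meds = idx[meds_local]
        full_d = np.sqrt(((Z[:, None, :] - Z[meds][None, :, :]) ** 2).sum(-1))
        obj = full_d.min(axis=1).sum()
        if obj < best_obj:
            best_obj, best_meds = obj, meds
    full_d = np.sqrt(((Z[:, None, :] - Z[best_meds][None, :, :]) ** 2).sum(-1))
    labels = full_d.argmin(axis=1)
    return EnvZonePartition(
        k=k, labels=labels, medoids=np.asarray(best_meds), feature_mean=mean,
        feature_std=std,
    )


# ----------------------------------------------------------------------
# pseudoabsences
# ----------------------------------------------------------------------
def sample_pseudoabsences(
    presences: pd.DataFrame,
    grid: EnvGrid,
    partition: EnvZonePartition,
    min_dist: float = 0.25,
    seed: int = 0,
) -> pd.DataFrame:
    """Stratified background points matching the presence count.

    One absence per presence, allocated as evenly as the eligible cells
    allow across the environmental zones of the eligible area (remainder
    zones chosen at random), every absence at least ``min_dist`` degrees
    of great-circle arc from every presence, and restricted to realms
    holding at least one presence.
    """
    presences = _check_occurrences(presences)
    n_needed = len(presences)
    rng = np.random.default_rng(seed)

    lon, lat = grid.cell_lonlat()
    pres_cells = np.unique(
        grid.cell_index(presences["lon"].to_numpy(), presences["lat"].to_numpy())
    )
    eligible = np.ones(grid.n_cells, dtype=bool)
    eligible[pres_cells] = False

    if grid.realm is not None:
        realms = grid.realm.ravel()
        occupied = np.unique(realms[pres_cells])
        in_realm = np.isin(realms, occupied)
        eligible &= in_realm
    # distance buffer (great-circle arc degrees)
    pts = presences[["lon", "lat"]].to_numpy(dtype=float)
    cells_xy = np.column_stack([lon, lat])
    dmin = cross_distance_deg(cells_xy, pts).min(axis=1)
    eligible &= dmin > min_dist

    candidates = np.flatnonzero(eligible)
    if candidates.size < n_needed:
        # identify the binding constraint for the error message
        base = np.ones(grid.n_cells, dtype=bool)
        base[pres_cells] = False
        n_no_dist = int((base & (dmin > min_dist)).sum())
        if grid.realm is not None and int((base & in_realm).sum()) < n_needed:
            binding = "realm restriction"
        elif n_no_dist < n_needed:
            binding = f"distance buffer ({min_dist} deg)"
        else:
            binding = "zone stratification"
        raise ValueError(
            f"only {candidates.size} eligible cells for {n_needed} absences; "
            f"binding constraint: {binding}"
        )

    zones = partition.labels[candidates]
    zone_ids = np.unique(zones)
    # even allocation with randomized remainder, then redistribute shortfalls
    quota = {z: n_needed // zone_ids.size for z in zone_ids}
    extra = rng.permutation(zone_ids)[: n_needed % zone_ids.size]
    for z in extra:
        quota[z] += 1
    chosen: list[np.ndarray] = []
    shortfall = 0
    leftovers: dict[int, np.ndarray] = {}
    for z in zone_ids:
        pool = candidates[zones == z]
        take = min(quota[z], pool.size)
        pick = rng.choice(pool, size=take, replace=False)
        chosen.append(pick)
        shortfall += quota[z] - take
        leftovers[z] = np.setdiff1d(pool, pick)
    if shortfall > 0:
        spare = np.concatenate([v for v in leftovers.values()])
        chosen.append(rng.choice(spare, size=shortfall, replace=False))
    cells = np.concatenate(chosen)

    return pd.DataFrame(
        {
            "species": presences["species"].iloc[0],
            "lon": lon[cells],
            "lat": lat[cells],
            "altitude": grid.altitude_at(cells),
        }
    )
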