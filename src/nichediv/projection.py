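"""Potential-range projection and the zone-resampled environmental space.

Projections are restricted to the environmental zones represented in a
species' occurrence data, which keeps predictions inside the data
domain the model was estimated on.  Niche size can be measured in two
spaces: the geographic grid itself, or a resampled environmental space
in which every environmental zone contributes the same number of
locations (correcting range sizes for unequal zone extents while
preserving the within-zone covariance of the forcings, because sampled
locations are real cells).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .env import EnvGrid
from .occurrences import EnvZonePartition, classify_env_zones
from .ttr_sdm import TTRConfig, TTRParameters, predict_probability

__all__ = [
    "SpeciesRange",
    "ResampledEnvironment",
    "restrict_domain",
    "project_range",
    "resample_environment",
]


@dataclass
class SpeciesRange:
    """Per-location occurrence probability and thresholded occupancy."""

    space: str  # "geographic" | "resampled"
    p: np.ndarray
    occupancy: np.ndarray  # bool, same length as p
    threshold: float

    @property
    def cell_count(self) -> int:
        return int(self.occupancy.sum())


@dataclass
class ResampledEnvironment:
    """Equal-representation sample of the environmental zones.

    ``n_per_zone`` locations drawn (with replacement) from the cells of
    each of the ``k`` zones; forcings are those of the source cells.
    """

    k: int
    n_per_zone: int
    zone: np.ndarray  # (k * n_per_zone,)
    source_cells: np.ndarray  # (k * n_per_zone,) flat grid cell indices
    forcings: dict[str, np.ndarray]  # var -> (k * n_per_zone, 12)
    partition: EnvZonePartition


def restrict_domain(
    occurrences: pd.DataFrame, grid: EnvGrid, partition: EnvZonePartition
) -> set[int]:
    """Environmental zones containing at least one occurrence record."""
    lon = occurrences["lon"].to_numpy(dtype=float)
    lat = occurrences["lat"].to_numpy(dtype=float)
    half_lon = 0.5 * float(np.median(np.diff(grid.lon))) if grid.lon.size > 1 else 0.5
    half_lat = 0.5 * float(np.median(np.diff(grid.lat))) if grid.lat.size > 1 else 0.5
    pad = 1e-9
    if (
        lon.min() < grid.lon.min() - half_lon - pad
        or lon.max() > grid.lon.max() + half_lon + pad
        or lat.min() < grid.lat.min() - half_lat - pad
        or lat.max() > grid.lat.max() + half_lat + pad
    ):
        raise ValueError("occurrence records fall outside the grid")
    cells = grid.cell_index(lon, lat)
    return set(int(z) for z in np.unique(partition.zone_of_cells(cells)))


def resample_environment(
    grid: EnvGrid,
    k: int = 50,
    n_per_zone: int = 1000,
    seed: int = 0,
    partition: EnvZonePartition | None = None,
) -> ResampledEnvironment:
    """Sample ``n_per_zone`` real cells from each of ``k`` zones."""
    if partition is None:
        partition = classify_env_zones(grid, k=k, seed=seed)
    rng = np.random.default_rng(seed)
    zones, cells = [], []
    for z in range(partition.k):
        pool = np.flatnonzero(partition.labels == z)
        if pool.size == 0:
            raise ValueError(f"environmental zone {z} has no cells")
        cells.append(rng.choice(pool, size=n_per_zone, replace=True))
        zones.append(np.full(n_per_zone, z))
    cells = np.concatenate(cells)
    zone = np.concatenate(zones)
    return ResampledEnvironment(
        k=partition.k,
        n_per_zone=n_per_zone,
        zone=zone,
        source_cells=cells,
        forcings=grid.forcings_at(cells),
        partition=partition,
    )


def project_range(
    params: TTRParameters,
    grid: EnvGrid,
    partition: EnvZonePartition,
    allowed_zones: set[int],
    threshold: float = 0.5,
    space: str = "geographic",
    resampled: ResampledEnvironment | None = None,
    max_years: int = 120,
    config: TTRConfig = TTRConfig(),
) -> SpeciesRange:
    """Occurrence probability everywhere, occupancy inside allowed zones.

    Occupancy = (p >= threshold) AND (location's zone in allowed_zones);
    the probability surface itself is computed for every location.
    """
    if space == "geographic":
        forcings = grid.forcings_at(np.arange(grid.n_cells))
        zone = partition.labels
    elif space == "resampled":
        if resampled is None:
            raise ValueError("resampled space requires a ResampledEnvironment")
        forcings = resampled.forcings
        zone = resampled.zone
    else:
        raise ValueError(f"unknown space {space!r}")
    p = predict_probability(params, forcings, max_years=max_years, config=config)
    if not allowed_zones:
        warnings.warn("empty allowed-zone set: projected range is empty")
    allowed = np.isin(zone, sorted(allowed_zones))
    occupancy = (p >= threshold) & allowed
    return SpeciesRange(space=space, p=p, occupancy=occupancy, threshold=threshold)
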