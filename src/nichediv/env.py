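"""Gridded monthly environmental forcings.

The plant-growth SDM is driven by six forcing variables on a regular
lon/lat grid, each with 12 monthly layers: minimum / mean / maximum
temperature (degC), soil moisture (volumetric fraction, 0-1 scale),
solar radiation (MJ m-2 day-1) and plant-available soil nitrogen
(index units).  Cell registration is at cell centres.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

VARIABLES = ("tmin", "tmean", "tmax", "soil_moisture", "radiation", "soil_n")
N_MONTHS = 12


@dataclass
class EnvGrid:
    """Monthly environmental forcings on a regular lon/lat grid.

    ``layers[var]`` has shape ``(12, n_rows, n_cols)``; rows map to
    latitudes, columns to longitudes, both stored as cell-centre
    coordinates in decimal degrees.
    """

    lon: np.ndarray  # (n_cols,)
    lat: np.ndarray  # (n_rows,)
    layers: dict[str, np.ndarray]
    altitude: np.ndarray | None = None  # (n_rows, n_cols), metres
    realm: np.ndarray | None = None  # (n_rows, n_cols), int labels

    def __post_init__(self) -> None:
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        shape = (N_MONTHS, self.lat.size, self.lon.size)
        for var in VARIABLES:
            if var not in self.layers:
                raise ValueError(f"missing forcing variable {var!r}")
            if self.layers[var].shape != shape:
                raise ValueError(
                    f"layer {var!r} has shape {self.layers[var].shape}, expected {shape}"
                )
        bad = ~(
            (self.layers["tmin"] <= self.layers["tmean"] + 1e-9)
            & (self.layers["tmean"] <= self.layers["tmax"] + 1e-9)
        )
        if bad.any():
            raise ValueError("tmin <= tmean <= tmax violated on the grid")

    # ------------------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return (self.lat.size, self.lon.size)

    @property
    def n_cells(self) -> int:
        return self.lat.size * self.lon.size

    def cell_lonlat(self) -> tuple[np.ndarray, np.ndarray]:
        """Flattened per-cell lon and lat (row-major, C order)."""
        glon, glat = np.meshgrid(self.lon, self.lat)
        return glon.ravel(), glat.ravel()

    def cell_index(self, lon, lat) -> np.ndarray:
        """Nearest-cell flat index for point coordinates."""
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        i = np.abs(lat[:, None] - self.lat[None, :]).argmin(axis=1)
        j = np.abs(lon[:, None] - self.lon[None, :]).argmin(axis=1)
        return i * self.lon.size + j

    def feature_matrix(self) -> np.ndarray:
        """(n_cells, 72) matrix of all monthly forcing layers."""
        cols = [
            self.layers[var][m].ravel() for var in VARIABLES for m in range(N_MONTHS)
        ]
        return np.column_stack(cols)

    def forcings_at(self, cells: np.ndarray) -> dict[str, np.ndarray]:
        """Forcing series for flat cell indices: var -> (n_sites, 12)."""
        cells = np.asarray(cells, dtype=int)
        out = {}
        for var in VARIABLES:
            flat = self.layers[var].reshape(N_MONTHS, -1)
            out[var] = flat[:, cells].T.copy()
        return out

    def altitude_at(self, cells: np.ndarray) -> np.ndarray:
        cells = np.asarray(cells, dtype=int)
        if self.altitude is None:
            return np.zeros(cells.size)
        return self.altitude.ravel()[cells]

    # ------------------------------------------------------------------
    def to_csv_dir(self, path) -> None:
        """Write one gridded CSV per variable-month plus coordinates."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({"lon": self.lon}).to_csv(path / "lon.csv", index=False)
        pd.DataFrame({"lat": self.lat}).to_csv(path / "lat.csv", index=False)
        for var in VARIABLES:
            for m in range(N_MONTHS):
                np.savetxt(
                    path / f"{var}_{m + 1:02d}.csv",
                    self.layers[var][m],
                    delimiter=",",
                    fmt="%.6g",
                )
        if self.altitude is not None:
            np.savetxt(path / "altitude.csv", self.altitude, delimiter=",", fmt="%.6g")
        if self.realm is not None:
            np.savetxt(path / "realm.csv", self.realm, delimiter=",", fmt="%d")

    @classmethod
    def from_csv_dir(cls, path) -> "EnvGrid":
        path = Path(path)
        lon = pd.read_csv(path / "lon.csv")["lon"].to_numpy()
        lat = pd.read_csv(path / "lat.csv")["lat"].to_numpy()
        layers = {}
        for var in VARIABLES:
            layers[var] = np.stack(
                [
                    np.loadtxt(path / f"{var}_{m + 1:02d}.csv", delimiter=",", ndmin=2)
                    for m in range(N_MONTHS)
                ]
            )
        altitude = realm = None
        if (path / "altitude.csv").exists():
            altitude = np.loadtxt(path / "altitude.csv", delimiter=",", ndmin=2)
        if (path / "realm.csv").exists():
            realm = np.loadtxt(path / "realm.csv", delimiter=",", ndmin=2).astype(int)
        return cls(lon, lat, layers, altitude, realm)
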