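"""Great-circle geometry helpers (haversine on a sphere, R = 6371 km)."""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0


def central_angle_deg(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle central angle between points, in degrees of arc.

    Broadcasts over array inputs; this is the distance convention used
    for the pseudoabsence buffer ("> 0.25 degrees").
    """
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return np.degrees(2 * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0))))


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in kilometres."""
    return np.radians(central_angle_deg(lon1, lat1, lon2, lat2)) * EARTH_RADIUS_KM


def cross_distance_deg(lonlat_a: np.ndarray, lonlat_b: np.ndarray) -> np.ndarray:
    """All-pairs central angles (degrees) between two (n, 2) point sets."""
    a = np.asarray(lonlat_a, dtype=float)
    b = np.asarray(lonlat_b, dtype=float)
    return central_angle_deg(
        a[:, 0][:, None], a[:, 1][:, None], b[:, 0][None, :], b[:, 1][None, :]
    )
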