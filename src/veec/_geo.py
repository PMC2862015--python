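"""Spherical-Earth geodesy helpers (radius 6371 km, adequate at survey scale)."""
from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km between points in decimal degrees.

    Inputs broadcast like numpy arrays.
    """
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(a, dtype=float)) for a in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def track_distance_km(lats, lons):
    """Cumulative along-track great-circle distance, starting at 0."""
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    if lats.size == 0:
        return np.zeros(0)
    steps = haversine_km(lats[:-1], lons[:-1], lats[1:], lons[1:])
    return np.concatenate([[0.0], np.cumsum(steps)])


def cell_area_km2(lat_centers_deg, dlat_deg, dlon_deg):
    """Area of regular lon/lat grid cells at the given latitudes (km^2)."""
    phi = np.radians(np.asarray(lat_centers_deg, dtype=float))
    return (
        EARTH_RADIUS_KM**2
        * np.radians(dlat_deg)
        * np.radians(dlon_deg)
        * np.cos(phi)
    )
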