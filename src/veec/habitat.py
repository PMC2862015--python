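"""Gridding of Z_VEEC and habitat-volume integration over a horizontal mask.

The oxygenated habitat volume is the integral of the boundary depth over the
horizontal area a population occupies: each grid cell contributes its depth
(km) times its spherical-Earth cell area (km^2), with cells straddling the
mask boundary contributing by their fractional area inside the polygon.  The
surface is the upper bound; an optional bathymetry grid can clip the depth
in shallow cells.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.interpolate
import xarray as xr
from shapely.geometry import MultiPolygon, Polygon, box, shape
from shapely.prepared import prep

from ._geo import cell_area_km2, haversine_km
from .zveec import ZveecSeries


class GriddingError(ValueError):
    """Raised when scattered points cannot support a triangulation."""


@dataclass
class DepthGrid:
    """Regular lon/lat grid of boundary depths (m, >= 0) with a valid mask."""

    lon: np.ndarray  # cell-centre longitudes, shape (nx,)
    lat: np.ndarray  # cell-centre latitudes, shape (ny,)
    z_m: np.ndarray  # shape (ny, nx)
    valid: np.ndarray  # shape (ny, nx)

    def __post_init__(self):
        if self.z_m.shape != (self.lat.size, self.lon.size):
            raise ValueError("z grid shape must be (n_lat, n_lon)")
        for ax in (self.lon, self.lat):
            if ax.size > 1 and not np.allclose(np.diff(ax), ax[1] - ax[0]):
                raise ValueError("grid spacing must be uniform per axis")
        if np.any(self.z_m[self.valid] < 0):
            raise ValueError("depths must be >= 0")

    @property
    def dlon(self) -> float:
        return float(self.lon[1] - self.lon[0]) if self.lon.size > 1 else 0.0

    @property
    def dlat(self) -> float:
        return float(self.lat[1] - self.lat[0]) if self.lat.size > 1 else 0.0

    def to_netcdf(self, path) -> None:
        ds = xr.Dataset(
            {
                "z_m": (("lat", "lon"), self.z_m),
                "valid": (("lat", "lon"), self.valid.astype(np.int8)),
            },
            coords={"lon": self.lon, "lat": self.lat},
        )
        ds.to_netcdf(path, engine="scipy")


@dataclass
class HabitatVolume:
    volume_km3: float
    area_km2: float
    n_cells: int

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {"volume_km3": self.volume_km3, "area_km2": self.area_km2, "n_cells": self.n_cells},
                indent=2,
            )
        )


def load_mask_geojson(path) -> MultiPolygon:
    """Read a habitat mask polygon from GeoJSON (Polygon/MultiPolygon features)."""
    data = json.loads(Path(path).read_text())
    geoms = []
    if data.get("type") == "FeatureCollection":
        for feat in data["features"]:
            geoms.append(shape(feat["geometry"]))
    elif data.get("type") == "Feature":
        geoms.append(shape(data["geometry"]))
    else:
        geoms.append(shape(data))
    polys: list[Polygon] = []
    for g in geoms:
        if isinstance(g, Polygon):
            polys.append(g)
        elif isinstance(g, MultiPolygon):
            polys.extend(g.geoms)
        else:
            raise ValueError(f"unsupported geometry type {g.geom_type}")
    mp = MultiPolygon(polys)
    if not mp.is_valid:
        raise ValueError("habitat mask rings must be closed and non-self-intersecting")
    return mp


def grid_zveec(
    z: ZveecSeries | None,
    resolution_deg: float,
    lons: np.ndarray | None = None,
    lats: np.ndarray | None = None,
    values: np.ndarray | None = None,
) -> DepthGrid:
    """Interpolate scattered Z_VEEC points onto a regular lon/lat grid.

    Triangulation-based linear interpolation; cells outside the convex hull
    of the observations are invalid.  Points may come from a ZveecSeries or
    be passed directly as arrays.
    """
    if z is not None:
        keep = z.valid
        lons = np.array([p.lon for p in z.pings])[keep]
        lats = np.array([p.lat for p in z.pings])[keep]
        values = z.z_veec_m[keep]
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    values = np.asarray(values, dtype=float)
    if lons.size < 3:
        raise GriddingError("need >= 3 points to grid")

    glon = np.arange(lons.min(), lons.max() + resolution_deg / 2, resolution_deg)
    glat = np.arange(lats.min(), lats.max() + resolution_deg / 2, resolution_deg)
    mlon, mlat = np.meshgrid(glon, glat)
    try:
        gz = scipy.interpolate.griddata(
            np.column_stack([lons, lats]), values, (mlon, mlat), method="linear"
        )
    except scipy.spatial.QhullError as err:  # pragma: no cover - message path
        raise GriddingError(f"points do not support a triangulation: {err}") from err
    if np.all(np.isnan(gz)):
        raise GriddingError("all grid cells fall outside the data hull (collinear points?)")
    valid = np.isfinite(gz)
    gz = np.where(valid, gz, np.nan)
    return DepthGrid(lon=glon, lat=glat, z_m=gz, valid=valid)


def habitat_volume(
    g: DepthGrid,
    mask: Polygon | MultiPolygon,
    bathymetry_m: np.ndarray | None = None,
) -> HabitatVolume:
    """Integrate the depth grid over the masked horizontal area (km^3).

    Boundary cells contribute by the fraction of their area inside the
    polygon.  ``bathymetry_m`` (same shape as the grid) optionally clips the
    depth to the seabed in shallow cells.
    """
    dlon, dlat = g.dlon, g.dlat
    if dlon == 0 or dlat == 0:
        raise ValueError("grid must have at least 2 cells per axis")
    prepared = prep(mask)
    areas = cell_area_km2(g.lat, dlat, dlon)  # per row
    z = g.z_m.copy()
    if bathymetry_m is not None:
        z = np.minimum(z, np.asarray(bathymetry_m, dtype=float))

    volume = 0.0
    area_sum = 0.0
    n_cells = 0
    for i, latc in enumerate(g.lat):
        for j, lonc in enumerate(g.lon):
            if not g.valid[i, j]:
                continue
            cell = box(lonc - dlon / 2, latc - dlat / 2, lonc + dlon / 2, latc + dlat / 2)
            if prepared.contains(cell):
                frac = 1.0
            elif prepared.intersects(cell):
                frac = mask.intersection(cell).area / cell.area
            else:
                continue
            a = areas[i] * frac
            volume += (z[i, j] / 1000.0) * a
            area_sum += a
            n_cells += 1
    if n_cells == 0:
        warnings.warn("mask does not intersect the depth grid; volume is 0", stacklevel=2)
    return HabitatVolume(volume_km3=float(volume), area_km2=float(area_sum), n_cells=n_cells)


def meridional_profile(
    g: DepthGrid,
    coastline_lonlat: np.ndarray,
    offshore_limit_km: float = 200.0,
) -> pd.DataFrame:
    """Mean and sd of the boundary depth per latitude band near the coast.

    For each grid-latitude band, averages valid cells within
    ``offshore_limit_km`` of the coastline polyline (distance to its densely
    sampled vertices).
    """
    coast = np.asarray(coastline_lonlat, dtype=float)
    if coast.ndim != 2 or coast.shape[1] != 2 or coast.shape[0] < 2:
        raise ValueError("coastline must be an (n, 2) lon/lat polyline")
    rows = []
    for i, latc in enumerate(g.lat):
        sel = []
        for j, lonc in enumerate(g.lon):
            if not g.valid[i, j]:
                continue
            d = haversine_km(latc, lonc, coast[:, 1], coast[:, 0]).min()
            if d <= offshore_limit_km:
                sel.append(g.z_m[i, j])
        if sel:
            rows.append(
                {
                    "lat": float(latc),
                    "mean_m": float(np.mean(sel)),
                    "sd_m": float(np.std(sel, ddof=0)),
                    "n": len(sel),
                }
            )
    return pd.DataFrame(rows)
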