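"""Dissolved-oxygen profile handling and oxycline feature extraction.

A profile is a depth-ordered series of DO concentrations (mL L^-1), either
continuous (CTD-O2, ~0.03 mL L^-1 precision) or discrete (Niskin bottles at
fixed levels, Winkler titration, ~0.1 mL L^-1).  The oxycline is split at the
depth of the most negative vertical DO gradient into an upper and a lower
part; the base of the lower oxycline (top of the OMZ) is the deeper of two
criteria: (A) the shallowest depth where DO drops below 0.5 mL L^-1 and (B)
the deepest depth where the gradient is weaker (more negative) than
-0.9 umol kg^-1 m^-1, i.e. -0.02 mL L^-1 m^-1.
"""
from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

CTDO_CONTINUOUS = "ctdo_continuous"
NISKIN_DISCRETE = "niskin_discrete"

NISKIN_LEVELS_M = (0.0, 10.0, 25.0, 50.0, 75.0, 100.0, 150.0)

DEFAULT_ISO_ML_L = 0.8
DEFAULT_OMZ_CONC_ML_L = 0.5
DEFAULT_GRAD_CRIT = -0.02  # mL L^-1 m^-1, equivalent to -0.9 umol kg^-1 m^-1

#: Sensor precisions recorded as metadata (mL L^-1).
SOURCE_PRECISION_ML_L = {CTDO_CONTINUOUS: 0.03, NISKIN_DISCRETE: 0.1}


@dataclass
class DOProfile:
    """One station's dissolved-oxygen profile."""

    station_id: str
    lat: float
    lon: float
    time: _dt.datetime
    depths_m: np.ndarray
    do_ml_l: np.ndarray
    source: str = CTDO_CONTINUOUS
    zone: str | None = None  # inshore | offshore (an input label, not computed)
    diel: str | None = None

    def __post_init__(self):
        self.depths_m = np.asarray(self.depths_m, dtype=float)
        self.do_ml_l = np.asarray(self.do_ml_l, dtype=float)
        if self.depths_m.size < 2:
            raise ValueError("a DO profile needs at least 2 levels")
        if self.depths_m.size != self.do_ml_l.size:
            raise ValueError("depths and DO arrays differ in length")
        if np.any(np.diff(self.depths_m) <= 0):
            raise ValueError("depths must be strictly increasing")
        if np.any(self.do_ml_l < 0):
            raise ValueError("DO concentrations must be >= 0")
        if self.source not in (CTDO_CONTINUOUS, NISKIN_DISCRETE):
            raise ValueError(f"unknown source kind {self.source!r}")

    @property
    def precision_ml_l(self) -> float:
        return SOURCE_PRECISION_ML_L[self.source]


@dataclass
class OxyclineFeatures:
    """Oxycline delimitation for one profile (depths in m; None = undefined)."""

    z_iso: float | None
    z_max_grad: float | None
    z_bot_oxy: float | None

    @property
    def lower_oxycline(self) -> tuple[float, float] | None:
        if self.z_max_grad is None or self.z_bot_oxy is None:
            return None
        return (self.z_max_grad, self.z_bot_oxy)


def z_isovalue(p: DOProfile, iso: float = DEFAULT_ISO_ML_L) -> float | None:
    """Depth of the shallowest downward crossing of a DO isovalue.

    DO is linearly interpolated between the bracketing samples.  A sample
    exactly at the isovalue is an exact hit.  Returns None when the profile
    never crosses the isovalue from above (e.g. a cast that does not reach
    the base of the oxycline).
    """
    z, do = p.depths_m, p.do_ml_l
    exact = np.flatnonzero(do == iso)
    cross = np.flatnonzero((do[:-1] > iso) & (do[1:] < iso))
    candidates = []
    if exact.size:
        candidates.append(z[exact[0]])
    if cross.size:
        i = cross[0]
        frac = (do[i] - iso) / (do[i] - do[i + 1])
        candidates.append(z[i] + frac * (z[i + 1] - z[i]))
    if not candidates:
        return None
    return float(min(candidates))


def vertical_gradient(p: DOProfile, grid_step_m: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """DO vertical gradient (mL L^-1 m^-1) on a uniform depth grid.

    The profile is linearly interpolated to ``grid_step_m`` spacing; the
    gradient uses centred differences (one-sided at the endpoints).  Depth is
    positive downward, so oxycline gradients are negative.
    """
    z0, z1 = p.depths_m[0], p.depths_m[-1]
    grid = np.arange(z0, z1 + grid_step_m / 2, grid_step_m)
    do = np.interp(grid, p.depths_m, p.do_ml_l)
    grad = np.gradient(do, grid)
    return grid, grad


def convert_units(
    value_umol_kg: float,
    density_kg_l: float = 1.025,
    molar_volume_l_mol: float = 22.392,
) -> float:
    """Convert a DO quantity from umol kg^-1 (per metre) to mL L^-1 (per metre).

    umol kg^-1 x kg L^-1 -> umol L^-1; x 22.392 L mol^-1 x 10^-3 -> mL L^-1.
    (-0.9 umol kg^-1 m^-1 -> -0.0207, i.e. -0.02 mL L^-1 m^-1 at display
    precision.)
    """
    if density_kg_l <= 0:
        raise ValueError("density must be > 0")
    return value_umol_kg * density_kg_l * molar_volume_l_mol * 1e-3


def oxycline_features(
    p: DOProfile,
    iso: float = DEFAULT_ISO_ML_L,
    omz_conc: float = DEFAULT_OMZ_CONC_ML_L,
    grad_crit: float = DEFAULT_GRAD_CRIT,
    grid_step_m: float = 1.0,
) -> OxyclineFeatures:
    """Extract Z_iso, the max-gradient depth and the lower-oxycline base.

    criterion A: shallowest depth where DO drops below ``omz_conc`` (linear
    interpolation); criterion B: deepest grid depth whose gradient is <=
    ``grad_crit``.  The base of the lower oxycline is the deeper of the two;
    if neither is met the base is undefined and the features are partial.
    """
    grid, grad = vertical_gradient(p, grid_step_m)
    z_max_grad = float(grid[int(np.argmin(grad))]) if grid.size else None

    z_a = z_isovalue(p, omz_conc)
    below = np.flatnonzero(grad <= grad_crit)
    z_b = float(grid[below[-1]]) if below.size else None
    if z_a is None and z_b is None:
        z_bot = None
    else:
        z_bot = max(v for v in (z_a, z_b) if v is not None)
    return OxyclineFeatures(
        z_iso=z_isovalue(p, iso),
        z_max_grad=z_max_grad,
        z_bot_oxy=z_bot,
    )


# ---------------------------------------------------------------------------
# I/O: long-format CSV of profiles, and a features table
# ---------------------------------------------------------------------------

def write_profiles_csv(profiles: list[DOProfile], path) -> None:
    rows = []
    for p in profiles:
        for z, do in zip(p.depths_m, p.do_ml_l):
            rows.append(
                {
                    "station_id": p.station_id,
                    "time_iso": p.time.isoformat(),
                    "lat": p.lat,
                    "lon": p.lon,
                    "source": p.source,
                    "zone": p.zone,
                    "diel": p.diel,
                    "depth_m": z,
                    "do_ml_l": do,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_profiles_csv(path) -> list[DOProfile]:
    df = pd.read_csv(Path(path))
    profiles = []
    for sid, g in df.groupby("station_id", sort=False):
        g = g.sort_values("depth_m")
        first = g.iloc[0]
        zone = first["zone"] if "zone" in g.columns and pd.notna(first.get("zone")) else None
        diel = first["diel"] if "diel" in g.columns and pd.notna(first.get("diel")) else None
        profiles.append(
            DOProfile(
                station_id=str(sid),
                lat=float(first["lat"]),
                lon=float(first["lon"]),
                time=pd.to_datetime(first["time_iso"]).to_pydatetime(),
                depths_m=g["depth_m"].to_numpy(),
                do_ml_l=g["do_ml_l"].to_numpy(),
                source=str(first["source"]),
                zone=zone,
                diel=diel,
            )
        )
    return profiles


def features_table(profiles: list[DOProfile], **kwargs) -> pd.DataFrame:
    """OxyclineFeatures for many profiles as a tidy table."""
    rows = []
    for p in profiles:
        f = oxycline_features(p, **kwargs)
        rows.append(
            {
                "station_id": p.station_id,
                "z_iso_m": f.z_iso,
                "z_max_grad_m": f.z_max_grad,
                "z_bot_oxy_m": f.z_bot_oxy,
            }
        )
    return pd.DataFrame(rows)
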