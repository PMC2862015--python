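"""Station matching and statistical validation of Z_VEEC against DO depths.

Because the boundary depth is displaced by internal waves at ~100 m
horizontal scales, station comparisons average Z_VEEC over the closest 300
pings recorded within 5 km of the station; stations with fewer valid pings
in range are excluded.  Matched pairs feed OLS regressions (slope,
intercept, n, F, p, R^2), one-way ANOVA of group effects (day/night,
inshore/offshore) and gridded difference maps.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from ._geo import haversine_km
from .oxygen import DOProfile
from .zveec import ZveecSeries

DEFAULT_MIN_PINGS = 300
DEFAULT_MAX_RADIUS_KM = 5.0


@dataclass
class StationMatch:
    """Z_VEEC averaged near one oceanographic station."""

    station_id: str
    z_veec_mean_m: float
    n_pings: int
    max_radius_km: float
    do_at_zveec_ml_l: float | None = None
    visible_track: bool = False


@dataclass
class RegressionResult:
    """Ordinary-least-squares summary (slope, intercept, n, F, p, R^2)."""

    slope: float
    intercept: float
    n: int
    F: float
    p: float
    r2: float

    def __post_init__(self):
        if self.n < 3:
            raise ValueError("regression needs n >= 3")
        if not 0.0 <= self.r2 <= 1.0 + 1e-12:
            raise ValueError("R^2 out of [0, 1]")


def match_station(
    z: ZveecSeries,
    station: DOProfile,
    min_pings: int = DEFAULT_MIN_PINGS,
    max_radius_km: float = DEFAULT_MAX_RADIUS_KM,
    visible_track_depth_m: float | None = None,
) -> StationMatch | None:
    """Average Z_VEEC over the closest ``min_pings`` valid pings within range.

    Returns None when fewer than ``min_pings`` valid pings lie within
    ``max_radius_km`` (exclusion is a result, not an error).  When the
    station's probe track was visible on the echogram, the user may supply
    the exact crossing depth instead via ``visible_track_depth_m``.
    """
    if visible_track_depth_m is not None:
        return StationMatch(
            station_id=station.station_id,
            z_veec_mean_m=float(visible_track_depth_m),
            n_pings=0,
            max_radius_km=max_radius_km,
            visible_track=True,
        )
    lats = np.array([p.lat for p in z.pings])
    lons = np.array([p.lon for p in z.pings])
    dist = haversine_km(lats, lons, station.lat, station.lon)
    ok = z.valid & (dist <= max_radius_km)
    if int(ok.sum()) < min_pings:
        return None
    idx = np.flatnonzero(ok)
    closest = idx[np.argsort(dist[idx], kind="stable")[:min_pings]]
    return StationMatch(
        station_id=station.station_id,
        z_veec_mean_m=float(np.mean(z.z_veec_m[closest])),
        n_pings=min_pings,
        max_radius_km=max_radius_km,
    )


def do_at_zveec(station: DOProfile, z_m: float) -> float | None:
    """DO concentration linearly interpolated at a depth; None outside span."""
    if not np.isfinite(z_m) or z_m < station.depths_m[0] or z_m > station.depths_m[-1]:
        return None
    return float(np.interp(z_m, station.depths_m, station.do_ml_l))


def ols_regression(x, y) -> RegressionResult:
    """OLS of y on x with the slope's F statistic, two-sided p and R^2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("regression needs n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("regression inputs must be finite")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x: regression is degenerate")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        n=int(x.size),
        F=float(model.fvalue),
        p=float(model.f_pvalue),
        r2=float(model.rsquared),
    )


def oneway_anova(groups: dict) -> tuple[float, float]:
    """Classical one-way ANOVA (F, p) over labelled groups."""
    if len(groups) < 2:
        raise ValueError("ANOVA needs >= 2 groups")
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group must be nonempty")
    if any(a.size == 1 for a in arrays) and all(np.ptp(a) == 0 for a in arrays):
        raise ValueError("degenerate ANOVA: singleton groups with zero variance")
    res = scipy.stats.f_oneway(*arrays)
    return float(res.statistic), float(res.pvalue)


def difference_map(
    z_veec_grid: np.ndarray, z_iso_grid: np.ndarray
) -> tuple[np.ndarray, dict]:
    """Cellwise Z_iso - Z_VEEC difference map with a box-plot summary."""
    a = np.asarray(z_iso_grid, dtype=float)
    b = np.asarray(z_veec_grid, dtype=float)
    if a.shape != b.shape:
        raise ValueError("grids are not aligned")
    diff = a - b
    finite = diff[np.isfinite(diff)]
    if finite.size == 0:
        summary = {k: float("nan") for k in ("mean", "q1", "median", "q3")}
    else:
        summary = {
            "mean": float(np.mean(finite)),
            "q1": float(np.percentile(finite, 25)),
            "median": float(np.median(finite)),
            "q3": float(np.percentile(finite, 75)),
        }
    return diff, summary


def match_survey(
    z: ZveecSeries,
    stations: list[DOProfile],
    min_pings: int = DEFAULT_MIN_PINGS,
    max_radius_km: float = DEFAULT_MAX_RADIUS_KM,
    iso_depths: dict | None = None,
) -> pd.DataFrame:
    """Match every station of a survey and attach DO at the matched depth.

    ``iso_depths`` optionally maps station_id to a reference depth (e.g.
    Z_0.8) to include in the table.  Excluded stations are omitted.
    """
    rows = []
    for st in stations:
        m = match_station(z, st, min_pings, max_radius_km)
        if m is None:
            continue
        do = do_at_zveec(st, m.z_veec_mean_m)
        rows.append(
            {
                "station_id": st.station_id,
                "zone": st.zone,
                "diel": st.diel,
                "z_veec_mean_m": m.z_veec_mean_m,
                "n_pings": m.n_pings,
                "do_at_zveec_ml_l": do,
                "z_ref_m": None if iso_depths is None else iso_depths.get(st.station_id),
            }
        )
    return pd.DataFrame(rows)


def regression_table(matches: pd.DataFrame, x_col: str = "z_ref_m", y_col: str = "z_veec_mean_m") -> pd.DataFrame:
    """Regression-summary table shaped like a survey report (one row here)."""
    sub = matches.dropna(subset=[x_col, y_col])
    r = ols_regression(sub[x_col].to_numpy(), sub[y_col].to_numpy())
    return pd.DataFrame(
        [
            {
                "y": y_col,
                "x": x_col,
                "slope": r.slope,
                "intercept": r.intercept,
                "n": r.n,
                "F": r.F,
                "p": r.p,
                "R2": r.r2,
            }
        ]
    )
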