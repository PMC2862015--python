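"""Echogram domain types, diel classification and on-disk readers/writers.

An echogram is a ping x depth-bin grid of volume backscattering strength
``Sv`` (dB re 1 m^-1).  Depths are metres below the sea surface, positive
downward; echosounder sample ranges (below the transducer) are converted to
below-surface depths once, at construction/load time, by adding the
transducer depth (default 3.4 m).  No-data cells are held as NaN and exposed
through a boolean ``valid`` mask; NaN cells never enter linear-domain sums.
"""
from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import xarray as xr

DAY = "day"
NIGHT = "night"
TWILIGHT = "twilight"

Dialect = Literal["netcdf", "csv"]

DEFAULT_TRANSDUCER_DEPTH_M = 3.4


class EchogramFormatError(ValueError):
    """Raised for malformed on-disk echograms or invariant violations."""


class MetadataError(ValueError):
    """Raised for missing/invalid ping metadata (positions, times)."""


@dataclass(frozen=True)
class PingMeta:
    """Per-ping metadata: index, UTC time, position and diel class."""

    index: int
    time: _dt.datetime
    lat: float
    lon: float
    diel: str | None = None

    def __post_init__(self):
        if self.index < 0:
            raise MetadataError(f"ping index must be >= 0, got {self.index}")
        if not np.isfinite(self.lat) or not np.isfinite(self.lon):
            raise MetadataError(f"non-finite position for ping {self.index}")
        if not (-90.0 <= self.lat <= 90.0) or not (-180.0 <= self.lon <= 180.0):
            raise MetadataError(f"position out of range for ping {self.index}")


class Echogram:
    """Single-frequency Sv grid with geo/time metadata.

    Parameters
    ----------
    frequency_khz : float
        Acoustic frequency (38 or 120 for the surveys this package emulates).
    sv_db : ndarray, shape (n_pings, n_bins)
        Volume backscattering strength in dB re 1 m^-1; NaN marks no-data.
    depth_edges : ndarray, shape (n_bins + 1,)
        Bin edges in metres below the sea surface, strictly increasing and
        uniformly spaced.
    pings : sequence of PingMeta
        One entry per row of ``sv_db``; times strictly increasing.
    transducer_depth_m : float
        Depth of the transducer face below the surface.  Depth edges are
        already surface-referenced; this records the offset applied upstream.
    """

    def __init__(
        self,
        frequency_khz: float,
        sv_db: np.ndarray,
        depth_edges: np.ndarray,
        pings: Sequence[PingMeta],
        transducer_depth_m: float = DEFAULT_TRANSDUCER_DEPTH_M,
    ):
        sv_db = np.asarray(sv_db, dtype=float)
        depth_edges = np.asarray(depth_edges, dtype=float)
        if sv_db.ndim != 2:
            raise EchogramFormatError("sv_db must be 2-D (ping x depth_bin)")
        if depth_edges.ndim != 1 or depth_edges.size != sv_db.shape[1] + 1:
            raise EchogramFormatError(
                f"depth_edges length {depth_edges.size} != depth_bins+1 = {sv_db.shape[1] + 1}"
            )
        steps = np.diff(depth_edges)
        if not np.all(steps > 0):
            raise EchogramFormatError("depth_edges must be strictly increasing")
        if steps.size and not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise EchogramFormatError("depth bins must have uniform height")
        if len(pings) != sv_db.shape[0]:
            raise MetadataError(f"{len(pings)} ping metadata for {sv_db.shape[0]} ping rows")
        times = [p.time for p in pings]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise MetadataError("ping times must be strictly increasing")
        finite = sv_db[np.isfinite(sv_db)]
        if finite.size and finite.max() > 0.0:
            raise EchogramFormatError("finite Sv must be <= 0 dB re 1 m^-1")
        self.frequency_khz = float(frequency_khz)
        self.sv_db = sv_db
        self.depth_edges = depth_edges
        self.pings = list(pings)
        self.transducer_depth_m = float(transducer_depth_m)

    # -- basic geometry -------------------------------------------------
    @property
    def n_pings(self) -> int:
        return self.sv_db.shape[0]

    @property
    def n_bins(self) -> int:
        return self.sv_db.shape[1]

    @property
    def bin_height_m(self) -> float:
        return float(self.depth_edges[1] - self.depth_edges[0])

    @property
    def depth_centers(self) -> np.ndarray:
        return 0.5 * (self.depth_edges[:-1] + self.depth_edges[1:])

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of cells that hold data."""
        return np.isfinite(self.sv_db)

    @property
    def sv_linear(self) -> np.ndarray:
        """Linear-domain backscattering coefficient 10^(Sv/10); NaN preserved."""
        return 10.0 ** (self.sv_db / 10.0)

    # -- metadata arrays ------------------------------------------------
    @property
    def times(self) -> np.ndarray:
        return np.array([p.time for p in self.pings], dtype="datetime64[us]")

    @property
    def lats(self) -> np.ndarray:
        return np.array([p.lat for p in self.pings], dtype=float)

    @property
    def lons(self) -> np.ndarray:
        return np.array([p.lon for p in self.pings], dtype=float)

    @property
    def diel(self) -> np.ndarray:
        return np.array([p.diel for p in self.pings], dtype=object)

    def select_pings(self, keep: np.ndarray) -> "Echogram":
        """Subset pings by boolean mask or integer indices (metadata kept)."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return Echogram(
            self.frequency_khz,
            self.sv_db[idx],
            self.depth_edges,
            [self.pings[i] for i in idx],
            self.transducer_depth_m,
        )

    def with_sv(self, sv_db: np.ndarray) -> "Echogram":
        """Same grid and metadata with replaced Sv values."""
        return Echogram(self.frequency_khz, sv_db, self.depth_edges, self.pings, self.transducer_depth_m)


@dataclass
class BiFrequencyEchogram:
    """Ping-synchronised 38/120 kHz echogram pair on one common grid."""

    e38: Echogram
    e120: Echogram

    def __post_init__(self):
        a, b = self.e38, self.e120
        if a.n_pings != b.n_pings or not np.array_equal(a.depth_edges, b.depth_edges):
            raise EchogramFormatError("38/120 kHz echograms must share ping and depth grids")
        if [p.index for p in a.pings] != [p.index for p in b.pings]:
            raise EchogramFormatError("38/120 kHz echograms must share ping indices")

    @property
    def n_pings(self) -> int:
        return self.e38.n_pings

    def select_pings(self, keep: np.ndarray) -> "BiFrequencyEchogram":
        return BiFrequencyEchogram(self.e38.select_pings(keep), self.e120.select_pings(keep))


# ---------------------------------------------------------------------------
# Solar position and diel classification
# ---------------------------------------------------------------------------

_J2000 = np.datetime64("2000-01-01T12:00:00", "us")


def solar_elevation(times, lats, lons) -> np.ndarray:
    """Solar elevation angle in degrees (low-precision NOAA/Meeus algorithm).

    Accurate to ~0.01 degrees, ample for day/night banding.  ``times`` are
    UTC (datetime64 array or datetime sequence); positions in degrees.
    """
    t = np.asarray(times, dtype="datetime64[us]")
    n = (t - _J2000) / np.timedelta64(1, "D")  # days since J2000
    lat = np.radians(np.asarray(lats, dtype=float))
    lon = np.asarray(lons, dtype=float)

    L = np.mod(280.460 + 0.9856474 * n, 360.0)  # mean longitude
    g = np.radians(np.mod(357.528 + 0.9856003 * n, 360.0))  # mean anomaly
    lam = np.radians(L + 1.915 * np.sin(g) + 0.020 * np.sin(2 * g))  # ecliptic lon
    eps = np.radians(23.439 - 4.0e-7 * n)  # obliquity
    dec = np.arcsin(np.sin(eps) * np.sin(lam))
    ra = np.arctan2(np.cos(eps) * np.sin(lam), np.cos(lam))
    gmst_deg = np.mod(280.46061837 + 360.98564736629 * n, 360.0)
    hour_angle = np.radians(gmst_deg + lon) - ra
    sin_elev = np.sin(lat) * np.sin(dec) + np.cos(lat) * np.cos(dec) * np.cos(hour_angle)
    return np.degrees(np.arcsin(np.clip(sin_elev, -1.0, 1.0)))


def classify_diel(
    ping: PingMeta,
    solar_day_min_elev: float = 0.0,
    solar_night_max_elev: float = -12.0,
) -> str:
    """Diel class of one ping: day above 0 deg solar elevation, night below
    -12 deg (nautical dusk), twilight between.  Bounds are configurable."""
    elev = float(solar_elevation([ping.time], [ping.lat], [ping.lon])[0])
    if elev > solar_day_min_elev:
        return DAY
    if elev < solar_night_max_elev:
        return NIGHT
    return TWILIGHT


def assign_diel(
    e: Echogram,
    solar_day_min_elev: float = 0.0,
    solar_night_max_elev: float = -12.0,
) -> Echogram:
    """Return an echogram whose pings carry diel labels."""
    elev = solar_elevation(e.times, e.lats, e.lons)
    labels = np.where(elev > solar_day_min_elev, DAY, np.where(elev < solar_night_max_elev, NIGHT, TWILIGHT))
    pings = [replace(p, diel=str(d)) for p, d in zip(e.pings, labels)]
    return Echogram(e.frequency_khz, e.sv_db, e.depth_edges, pings, e.transducer_depth_m)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_EPOCH = np.datetime64("1970-01-01T00:00:00", "us")


def write_echogram(e: Echogram, path, dialect: Dialect = "netcdf") -> None:
    """Write an echogram; both dialects round-trip through read_echogram."""
    path = Path(path)
    if dialect == "netcdf":
        _write_netcdf(e, path)
    elif dialect == "csv":
        _write_csv(e, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_echogram(path, dialect: Dialect = "netcdf") -> Echogram:
    """Read an echogram written by :func:`write_echogram`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "netcdf":
        return _read_netcdf(path)
    if dialect == "csv":
        return _read_csv(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _write_netcdf(e: Echogram, path: Path) -> None:
    seconds = (e.times - _EPOCH) / np.timedelta64(1, "s")
    ds = xr.Dataset(
        {
            "sv_db": (("ping", "depth_bin"), e.sv_db),
            "time": ("ping", seconds.astype(float)),
            "lat": ("ping", e.lats),
            "lon": ("ping", e.lons),
            "depth_edges": ("depth_edge", e.depth_edges),
        },
        attrs={
            "frequency_khz": e.frequency_khz,
            "transducer_depth_m": e.transducer_depth_m,
        },
    )
    ds["time"].attrs["units"] = "seconds since 1970-01-01T00:00:00"
    ds["sv_db"].attrs["units"] = "dB re 1 m-1"
    ds.to_netcdf(path, engine="scipy")


def _read_netcdf(path: Path) -> Echogram:
    with xr.open_dataset(path, engine="scipy", decode_times=False) as ds:
        try:
            sv = ds["sv_db"].values.astype(float)
            seconds = ds["time"].values.astype(float)
            lats = ds["lat"].values.astype(float)
            lons = ds["lon"].values.astype(float)
            edges = ds["depth_edges"].values.astype(float)
            freq = float(ds.attrs["frequency_khz"])
            tdepth = float(ds.attrs["transducer_depth_m"])
        except KeyError as err:
            raise EchogramFormatError(f"missing variable/attribute in {path}: {err}") from err
    if np.any(~np.isfinite(lats)) or np.any(~np.isfinite(lons)):
        raise MetadataError("NaN ping positions")
    times = _EPOCH + (seconds * 1e6).round().astype("timedelta64[us]")
    pings = [
        PingMeta(i, t.astype(_dt.datetime), float(la), float(lo))
        for i, (t, la, lo) in enumerate(zip(times, lats, lons))
    ]
    return Echogram(freq, sv, edges, pings, tdepth)


def _write_csv(e: Echogram, path: Path) -> None:
    centers = e.depth_centers
    header = [
        f"# frequency_khz={e.frequency_khz!r}",
        f"# transducer_depth_m={e.transducer_depth_m!r}",
        "# depth_edges_m=" + ",".join(repr(float(v)) for v in e.depth_edges),
    ]
    df = pd.DataFrame(e.sv_db, columns=[repr(float(c)) for c in centers])
    df.insert(0, "time", [p.time.isoformat() for p in e.pings])
    df.insert(1, "lat", e.lats)
    df.insert(2, "lon", e.lons)
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        df.to_csv(fh, index=False, na_rep="NaN")


def _read_csv(path: Path) -> Echogram:
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    for key in ("frequency_khz", "transducer_depth_m"):
        if key not in meta:
            raise EchogramFormatError(f"missing '# {key}=' header in {path}")
    freq = float(meta["frequency_khz"])
    tdepth = float(meta["transducer_depth_m"])
    depth_cols = [c for c in df.columns if c not in ("time", "lat", "lon")]
    if not depth_cols:
        raise EchogramFormatError(f"no depth-bin columns in {path}")
    if "depth_edges_m" in meta:
        edges = np.array([float(v) for v in meta["depth_edges_m"].split(",")])
    else:
        centers = np.array([float(c) for c in depth_cols])
        h = np.diff(centers)
        if centers.size < 2:
            raise EchogramFormatError("cannot infer bin height from a single unlabelled bin")
        edges = np.concatenate([centers - h[0] / 2.0, [centers[-1] + h[0] / 2.0]])
    lats = df["lat"].to_numpy(dtype=float)
    lons = df["lon"].to_numpy(dtype=float)
    if np.any(~np.isfinite(lats)) or np.any(~np.isfinite(lons)):
        raise MetadataError("NaN ping positions")
    times = pd.to_datetime(df["time"]).to_list()
    pings = [PingMeta(i, t.to_pydatetime(), float(la), float(lo)) for i, (t, la, lo) in enumerate(zip(times, lats, lons))]
    sv = df[depth_cols].to_numpy(dtype=float)
    return Echogram(freq, sv, edges, pings, tdepth)
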