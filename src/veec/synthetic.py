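"""Synthetic coastal-survey generator with known ground truth.

Emulates a cross-shore bi-frequency (38/120 kHz) acoustic transect over a
shallow oxygen minimum zone:

* an oxycline depth field Z*(x) = large-scale trend + mesoscale/submesoscale
  sinusoidal undulations + optional Gaussian filament ridge;
* a zooplankton scattering layer filling the water column above Z*(x)
  (stronger at 120 kHz), with a sharp base tapering to zero within ~2 m;
* per-cell lognormal speckle (mean-one) emulating echo variability, plus a
  smooth layer-base displacement field emulating internal-wave heaving (the
  ping-scale Z_VEEC variability seen at ~100 m horizontal scales);
* fish schools rendered as ellipses, ~35 dB above the zooplankton at 38 kHz
  and slightly weaker at 120 kHz;
* an optional mesopelagic layer, either merged into the epipelagic band
  (night) or sitting deep inside the OMZ;
* optional sparse strong scatterers below the layer base (the case that
  makes a 99 % threshold erratic);
* range-dependent background noise following the preprocess noise model;
* DO profiles from a logistic family whose 0.8 mL L^-1 isoline lies exactly
  at Z*(x), sampled continuously (1 m) or at discrete Niskin levels.

Everything is deterministic under the spec's seed; independent substreams
per component keep e.g. a day and a night scene cell-for-cell comparable.
"""
from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage

from .echogram import (
    BiFrequencyEchogram,
    Echogram,
    PingMeta,
    assign_diel,
)
from .oxygen import (
    CTDO_CONTINUOUS,
    NISKIN_DISCRETE,
    NISKIN_LEVELS_M,
    DOProfile,
)
from .preprocess import NoiseModel, noise_field

KM_PER_DEG = 111.195  # spherical Earth, pi * 6371 / 180

#: Default logistic DO-profile family: DO(z) = floor + amp / (1 + e^{(z-z50)/width})
LOGISTIC_FLOOR_ML_L = 0.05
LOGISTIC_AMP_ML_L = 5.0
LOGISTIC_WIDTH_M = 5.0


@dataclass(frozen=True)
class SceneSpec:
    """Survey design and environmental conditions of a synthetic scene."""

    length_km: float = 25.0
    ping_rate_hz: float = 1.0
    speed_knots: float = 10.0
    native_bin_m: float = 0.25
    max_depth_m: float = 150.0
    transducer_depth_m: float = 3.4

    # oxycline depth field Z*(x): trend endpoints + (wavelength_km, amplitude_m)
    z_star_start_m: float = 40.0
    z_star_end_m: float = 60.0
    undulations: tuple[tuple[float, float], ...] = ((8.0, 6.0), (3.0, 2.5))
    filament: tuple[float, float, float] | None = None  # (centre_km, width_km, amp_m)

    # scatterers
    zoo_sv38_db: float = -85.0
    zoo_sv120_db: float = -75.0
    speckle_db: float = 5.0
    taper_m: float = 2.0
    base_jitter_sd_m: float = 4.0
    base_jitter_corr_km: float = 0.3
    n_schools: int = 6
    school_sv38_db: float = -50.0
    school_diff_db: tuple[float, float] = (-3.0, 0.0)  # Sv120 - Sv38 range
    mesopelagic: str | None = None  # None | "merged" | "deep"
    meso_sv38_db: float = -90.0
    meso_sv120_db: float = -82.0
    meso_depth_range_m: tuple[float, float] = (115.0, 140.0)
    deep_scatterer_ping_fraction: float = 0.0
    deep_scatterer_mass_fraction: float = 0.015
    deep_scatterer_depth_m: float = 120.0

    # background noise; None offsets disable noise
    noise_alpha_db_per_m: dict = field(default_factory=lambda: {38: 0.0097, 120: 0.0267})
    noise_offset_db: dict | None = None  # e.g. {38: -140.0, 120: -140.0}

    # track
    start_time: str = "2008-02-10T17:00:00"  # UTC; ~noon local off Peru
    start_lat: float = -8.0
    start_lon: float = -79.0
    heading_deg: float = 270.0

    seed: int = 0

    def __post_init__(self):
        zoo_diff = self.zoo_sv120_db - self.zoo_sv38_db
        if zoo_diff < 4.0:
            raise ValueError("zooplankton must satisfy Sv120 - Sv38 >= +4 dB")
        if self.school_diff_db[1] > 0.0:
            raise ValueError("fish schools must satisfy Sv120 - Sv38 <= 0 dB")
        zmax = max(self.z_star_start_m, self.z_star_end_m) + sum(a for _, a in self.undulations)
        if zmax >= self.max_depth_m:
            raise ValueError("Z* must stay within the sampled depth range")
        if self.mesopelagic not in (None, "merged", "deep"):
            raise ValueError("mesopelagic must be None, 'merged' or 'deep'")

    # -- derived geometry ------------------------------------------------
    @property
    def ping_spacing_m(self) -> float:
        return self.speed_knots * 1852.0 / 3600.0 / self.ping_rate_hz

    @property
    def n_pings(self) -> int:
        return int(np.floor(self.length_km * 1000.0 / self.ping_spacing_m))

    def x_km(self) -> np.ndarray:
        return np.arange(self.n_pings) * self.ping_spacing_m / 1000.0


@dataclass
class GroundTruth:
    """What the generator knows: the clean oxycline field and scatterer truth."""

    z_star_m: np.ndarray  # per ping, the clean field (== station Z_0.8)
    layer_base_m: np.ndarray  # per ping, Z* + internal-wave displacement
    fish_mask: np.ndarray  # native-grid boolean, True where a school was rendered
    stations: pd.DataFrame  # station_id, x_km, lat, lon, z_0p8_m

    def stations_to_csv(self, path) -> None:
        self.stations.to_csv(path, index=False)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream])


def z_star_field(spec: SceneSpec, x_km: np.ndarray) -> np.ndarray:
    """Clean oxycline depth Z*(x): trend + undulations + optional filament."""
    x = np.asarray(x_km, dtype=float)
    L = spec.length_km
    z = spec.z_star_start_m + (spec.z_star_end_m - spec.z_star_start_m) * (x / L)
    rng = _rng(spec.seed, 0)
    for wavelength, amp in spec.undulations:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        z = z + amp * np.sin(2.0 * np.pi * x / wavelength + phase)
    if spec.filament is not None:
        centre, width, amp = spec.filament
        z = z + amp * np.exp(-0.5 * ((x - centre) / width) ** 2)
    return z


def _track(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray, list[_dt.datetime]]:
    x = spec.x_km()
    theta = np.radians(spec.heading_deg)
    lat = spec.start_lat + x * np.cos(theta) / KM_PER_DEG
    lon = spec.start_lon + x * np.sin(theta) / (KM_PER_DEG * np.cos(np.radians(spec.start_lat)))
    t0 = _dt.datetime.fromisoformat(spec.start_time)
    times = [t0 + _dt.timedelta(seconds=i / spec.ping_rate_hz) for i in range(spec.n_pings)]
    return lat, lon, times


def _speckle(rng: np.random.Generator, shape, sigma_db: float) -> np.ndarray:
    """Mean-one lognormal multiplicative field with the given dB spread."""
    if sigma_db <= 0:
        return np.ones(shape)
    sigma_ln = sigma_db * np.log(10.0) / 10.0
    return np.exp(rng.normal(-0.5 * sigma_ln**2, sigma_ln, size=shape))


def _base_jitter(spec: SceneSpec, n: int) -> np.ndarray:
    """Smooth internal-wave-like displacement of the layer base (metres)."""
    if spec.base_jitter_sd_m <= 0:
        return np.zeros(n)
    rng = _rng(spec.seed, 4)
    white = rng.standard_normal(n)
    sigma_pings = max(spec.base_jitter_corr_km * 1000.0 / spec.ping_spacing_m, 1.0)
    smooth = scipy.ndimage.gaussian_filter1d(white, sigma_pings, mode="reflect")
    smooth = smooth - smooth.mean()  # zero-mean displacement: waves heave, not shift
    sd = smooth.std()
    if sd == 0:
        return np.zeros(n)
    return smooth / sd * spec.base_jitter_sd_m


def _occupancy(base_m: np.ndarray, centers: np.ndarray, taper_m: float) -> np.ndarray:
    """1 above the layer base, linear taper to 0 within ``taper_m`` below it."""
    return np.clip((base_m[:, None] + taper_m - centers[None, :]) / taper_m, 0.0, 1.0)


def generate_scene(
    spec: SceneSpec,
    n_stations: int = 0,
    niskin: bool = False,
) -> tuple[BiFrequencyEchogram, list[DOProfile], GroundTruth]:
    """Render a synthetic bi-frequency survey with matched DO stations.

    Deterministic under ``spec.seed``; the zooplankton, fish, mesopelagic,
    displacement and station substreams are independent, so changing one
    scene ingredient leaves the others bit-identical.
    """
    n = spec.n_pings
    if n < 1:
        raise ValueError("scene has no pings; increase length_km")
    lat, lon, times = _track(spec)
    x = spec.x_km()
    z_star = z_star_field(spec, x)
    base = z_star + _base_jitter(spec, n)

    edges = spec.transducer_depth_m + spec.native_bin_m * np.arange(
        int(np.ceil((spec.max_depth_m - spec.transducer_depth_m) / spec.native_bin_m)) + 1
    )
    centers = 0.5 * (edges[:-1] + edges[1:])
    nb = centers.size

    if np.any(base >= edges[-1]):
        raise ValueError("layer base exceeds the sampled depth range")

    occ = _occupancy(base, centers, spec.taper_m)
    speckle = _speckle(_rng(spec.seed, 1), (n, nb), spec.speckle_db)
    lin38 = 10.0 ** (spec.zoo_sv38_db / 10.0) * occ * speckle
    lin120 = 10.0 ** (spec.zoo_sv120_db / 10.0) * occ * speckle

    # mesopelagic community; merged migrators share the epipelagic patch
    # structure (co-located communities are aggregated by the same physical
    # processes), so a merged layer rescales columns without moving the base
    if spec.mesopelagic == "merged":
        lin38 = lin38 + 10.0 ** (spec.meso_sv38_db / 10.0) * occ * speckle
        lin120 = lin120 + 10.0 ** (spec.meso_sv120_db / 10.0) * occ * speckle
    elif spec.mesopelagic == "deep":
        meso_speckle = _speckle(_rng(spec.seed, 3), (n, nb), spec.speckle_db)
        z0, z1 = spec.meso_depth_range_m
        deep_occ = ((centers >= z0) & (centers <= z1)).astype(float)[None, :]
        lin38 = lin38 + 10.0 ** (spec.meso_sv38_db / 10.0) * deep_occ * meso_speckle
        lin120 = lin120 + 10.0 ** (spec.meso_sv120_db / 10.0) * deep_occ * meso_speckle

    # fish schools (ellipses in ping x depth space)
    fish_mask = np.zeros((n, nb), dtype=bool)
    rng_fish = _rng(spec.seed, 2)
    for _ in range(spec.n_schools):
        pc = rng_fish.uniform(0, n)
        a = rng_fish.uniform(5, 20)  # semi-axis, pings
        b = rng_fish.uniform(2.0, 5.0)  # semi-axis, metres
        lo = min(base[int(np.clip(pc, 0, n - 1))] - b - 3.0, spec.max_depth_m)
        zc = rng_fish.uniform(8.0, max(lo, 9.0))
        diff_db = rng_fish.uniform(*spec.school_diff_db)
        s_spk = _speckle(rng_fish, (n, nb), spec.speckle_db)
        inside = ((np.arange(n)[:, None] - pc) / a) ** 2 + (
            (centers[None, :] - zc) / b
        ) ** 2 <= 1.0
        f38 = 10.0 ** (spec.school_sv38_db / 10.0)
        lin38 = lin38 + np.where(inside, f38 * s_spk, 0.0)
        lin120 = lin120 + np.where(inside, f38 * 10.0 ** (diff_db / 10.0) * s_spk, 0.0)
        fish_mask |= inside

    # sparse strong scatterers below the layer base (non-fish response)
    if spec.deep_scatterer_ping_fraction > 0:
        rng_deep = _rng(spec.seed, 5)
        affected = rng_deep.random(n) < spec.deep_scatterer_ping_fraction
        cells = np.abs(centers - spec.deep_scatterer_depth_m) <= 2.0
        n_cells = int(cells.sum())
        if n_cells:
            f = spec.deep_scatterer_mass_fraction
            col_mass = lin120.sum(axis=1)
            per_cell = f / (1.0 - f) * col_mass / n_cells
            add120 = np.where(affected[:, None] & cells[None, :], per_cell[:, None], 0.0)
            lin120 = lin120 + add120
            lin38 = lin38 + add120 / 10.0  # zooplankton-like +10 dB response

    # background noise (deterministic range-dependent field)
    ranges = centers - spec.transducer_depth_m
    if spec.noise_offset_db is not None:
        for freq, lin in ((38, lin38), (120, lin120)):
            model = NoiseModel(spec.noise_alpha_db_per_m[freq], spec.noise_offset_db[freq])
            lin += 10.0 ** (noise_field(ranges, model) / 10.0)[None, :]

    with np.errstate(divide="ignore"):
        sv38 = np.where(lin38 > 0, 10.0 * np.log10(np.where(lin38 > 0, lin38, 1.0)), np.nan)
        sv120 = np.where(lin120 > 0, 10.0 * np.log10(np.where(lin120 > 0, lin120, 1.0)), np.nan)

    pings = [
        PingMeta(i, t, float(la), float(lo)) for i, (t, la, lo) in enumerate(zip(times, lat, lon))
    ]
    e38 = assign_diel(Echogram(38.0, sv38, edges, pings, spec.transducer_depth_m))
    e120 = assign_diel(Echogram(120.0, sv120, edges, pings, spec.transducer_depth_m))
    bi = BiFrequencyEchogram(e38, e120)

    profiles, stations = _stations(spec, n_stations, niskin, x, lat, lon, times, z_star)
    truth = GroundTruth(
        z_star_m=z_star, layer_base_m=base, fish_mask=fish_mask, stations=stations
    )
    return bi, profiles, truth


def logistic_do_profile(z_m: np.ndarray, z_0p8_m: float, iso: float = 0.8) -> np.ndarray:
    """Logistic DO(z) whose ``iso`` isoline lies exactly at ``z_0p8_m``."""
    c, amp, width = LOGISTIC_FLOOR_ML_L, LOGISTIC_AMP_ML_L, LOGISTIC_WIDTH_M
    z50 = z_0p8_m - width * np.log(amp / (iso - c) - 1.0)
    return c + amp / (1.0 + np.exp((np.asarray(z_m, dtype=float) - z50) / width))


def _stations(spec, n_stations, niskin, x, lat, lon, times, z_star):
    if n_stations < 1:
        return [], pd.DataFrame(columns=["station_id", "x_km", "lat", "lon", "z_0p8_m"])
    frac = np.linspace(0.05, 0.95, n_stations)
    idx = np.clip((frac * (x.size - 1)).round().astype(int), 0, x.size - 1)
    depths = (
        np.asarray(NISKIN_LEVELS_M)
        if niskin
        else np.arange(0.0, spec.max_depth_m + 0.5, 1.0)
    )
    profiles = []
    rows = []
    for k, i in enumerate(idx):
        sid = f"st{k:03d}"
        do = logistic_do_profile(depths, float(z_star[i]))
        profiles.append(
            DOProfile(
                station_id=sid,
                lat=float(lat[i]),
                lon=float(lon[i]),
                time=times[i],
                depths_m=depths,
                do_ml_l=do,
                source=NISKIN_DISCRETE if niskin else CTDO_CONTINUOUS,
                zone="inshore" if x[i] < spec.length_km / 2 else "offshore",
            )
        )
        rows.append(
            {
                "station_id": sid,
                "x_km": float(x[i]),
                "lat": float(lat[i]),
                "lon": float(lon[i]),
                "z_0p8_m": float(z_star[i]),
            }
        )
    return profiles, pd.DataFrame(rows)


def generate_stations(spec: SceneSpec, n: int, niskin: bool = False) -> list[DOProfile]:
    """DO stations along the track, sampling the scene's logistic profiles.

    Continuous stations sample every metre; Niskin stations sample the fixed
    bottle levels, degrading the precision of any interpolated isoline depth.
    """
    if n < 1:
        raise ValueError("need n >= 1 stations")
    x = spec.x_km()
    lat, lon, times = _track(spec)
    z_star = z_star_field(spec, x)
    profiles, _ = _stations(spec, n, niskin, x, lat, lon, times, z_star)
    return profiles
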