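"""Noise removal, resampling to common elementary cells and twilight removal.

Background noise in an echogram grows with range because of time-varied gain
and absorption; it is modelled as ``N(R) = 20 log10(R) + 2 alpha R + offset``
with ``R`` the range below the transducer in metres, ``alpha`` the absorption
coefficient (dB m^-1) and ``offset`` the noise at 1 m.  The modelled field is
subtracted cell-by-cell in the linear domain ("linear minus"); cells at or
below the noise field become no-data.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .echogram import BiFrequencyEchogram, Echogram, PingMeta, TWILIGHT


@dataclass(frozen=True)
class NoiseModel:
    """Range-dependent background-noise model for one frequency."""

    alpha_db_per_m: float
    offset_db: float

    def __post_init__(self):
        if self.alpha_db_per_m < 0:
            raise ValueError("absorption coefficient must be >= 0")
        if self.offset_db >= 0:
            warnings.warn(
                f"noise offset {self.offset_db} dB >= 0 is unphysical for real instruments",
                stacklevel=2,
            )


def noise_field(ranges_m, model: NoiseModel) -> np.ndarray:
    """Noise level N(R) = 20 log10(R) + 2 alpha R + offset, elementwise in dB."""
    r = np.asarray(ranges_m, dtype=float)
    if np.any(r <= 0):
        raise ValueError("ranges must be > 0 m")
    return 20.0 * np.log10(r) + 2.0 * model.alpha_db_per_m * r + model.offset_db


def linear_minus(sv_db: np.ndarray, noise_db: np.ndarray) -> np.ndarray:
    """Subtract a noise field from Sv in the linear domain.

    ``noise_db`` broadcasts against the trailing (depth) axis of ``sv_db``.
    Cells with Sv <= N have no linear remainder and become NaN (no-data);
    masking is the contract, not an error.
    """
    sv = np.asarray(sv_db, dtype=float)
    noise = np.broadcast_to(np.asarray(noise_db, dtype=float), sv.shape)
    out = np.full(sv.shape, np.nan)
    with np.errstate(invalid="ignore"):
        above = sv > noise
    if np.any(above):
        diff = 10.0 ** (sv[above] / 10.0) - 10.0 ** (noise[above] / 10.0)
        with np.errstate(divide="ignore"):
            res = 10.0 * np.log10(diff)
        out[above] = np.where(np.isfinite(res), res, np.nan)  # underflowed remainder
    return out


def remove_noise(e: Echogram, model: NoiseModel) -> Echogram:
    """Apply :func:`linear_minus` with ranges taken below the transducer.

    Bins whose centre lies at or above the transducer face have no defined
    range and are masked.
    """
    ranges = e.depth_centers - e.transducer_depth_m
    ok = ranges > 0
    noise = np.full(e.n_bins, np.inf)  # infinite noise masks in-air bins
    noise[ok] = noise_field(ranges[ok], model)
    return e.with_sv(linear_minus(e.sv_db, noise))


def fit_noise_offset(e: Echogram, alpha_db_per_m: float, deepest_fraction: float = 0.1) -> NoiseModel:
    """Least-squares offset estimate from the deepest bins of an echogram.

    Extension helper: assumes the deepest ``deepest_fraction`` of bins are
    signal-free so that Sv there is noise; the offset is the mean residual
    Sv - 20 log10(R) - 2 alpha R over those bins.
    """
    n_tail = max(1, int(round(deepest_fraction * e.n_bins)))
    ranges = e.depth_centers[-n_tail:] - e.transducer_depth_m
    sv = e.sv_db[:, -n_tail:]
    resid = sv - (20.0 * np.log10(ranges) + 2.0 * alpha_db_per_m * ranges)
    return NoiseModel(alpha_db_per_m, float(np.nanmean(resid)))


def resample(e: Echogram, cell_height_m: float = 0.75, pings_per_cell: int = 1) -> Echogram:
    """Average an echogram onto common elementary cells.

    Output cells are ``pings_per_cell`` pings long and ``cell_height_m`` high,
    with cell tops aligned to the surface (depth 0).  Averaging is the
    arithmetic mean of member cells in the linear domain; no-data members are
    excluded and all-no-data cells stay no-data.  A partial bottom cell (not
    fully covered by native samples) is dropped.
    """
    if not (np.isfinite(cell_height_m) and cell_height_m > 0):
        raise ValueError("cell_height_m must be a positive number")
    if cell_height_m < e.bin_height_m - 1e-9:
        raise ValueError(
            f"cell_height_m ({cell_height_m}) must be >= native bin height ({e.bin_height_m})"
        )
    if pings_per_cell < 1:
        raise ValueError("pings_per_cell must be >= 1")

    centers = e.depth_centers
    # drop output cells whose bottom edge exceeds the sampled range
    n_out = int(np.floor((e.depth_edges[-1] + 1e-9) / cell_height_m))
    out_edges = np.arange(n_out + 1) * cell_height_m
    sv_lin = e.sv_linear

    # group pings
    n_groups = e.n_pings // pings_per_cell
    lin_sum = np.zeros((n_groups, n_out))
    lin_cnt = np.zeros((n_groups, n_out))
    member = np.floor(centers / cell_height_m).astype(int)
    for j in range(n_out):
        cols = np.flatnonzero(member == j)
        if cols.size == 0:
            continue
        block = sv_lin[: n_groups * pings_per_cell, cols].reshape(n_groups, -1)
        lin_sum[:, j] = np.nansum(block, axis=1)
        lin_cnt[:, j] = np.sum(np.isfinite(block), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(lin_cnt > 0, lin_sum / np.maximum(lin_cnt, 1), np.nan)
        out_db = 10.0 * np.log10(mean)

    if pings_per_cell == 1:
        pings = e.pings
    else:
        pings = []
        for g in range(n_groups):
            block = e.pings[g * pings_per_cell : (g + 1) * pings_per_cell]
            pings.append(
                PingMeta(
                    index=g,
                    time=block[0].time,
                    lat=float(np.mean([p.lat for p in block])),
                    lon=float(np.mean([p.lon for p in block])),
                    diel=block[0].diel,
                )
            )
    return Echogram(e.frequency_khz, out_db, out_edges, pings, e.transducer_depth_m)


def preprocess_bifrequency(
    b: BiFrequencyEchogram,
    noise38: NoiseModel | None = None,
    noise120: NoiseModel | None = None,
    cell_height_m: float = 0.75,
    pings_per_cell: int = 1,
) -> BiFrequencyEchogram:
    """Noise-remove (optional) and resample both frequencies identically."""
    e38, e120 = b.e38, b.e120
    if noise38 is not None:
        e38 = remove_noise(e38, noise38)
    if noise120 is not None:
        e120 = remove_noise(e120, noise120)
    return BiFrequencyEchogram(
        resample(e38, cell_height_m, pings_per_cell),
        resample(e120, cell_height_m, pings_per_cell),
    )


def drop_twilight(b: BiFrequencyEchogram) -> BiFrequencyEchogram:
    """Remove twilight pings from both frequencies identically.

    The depth statistic is undefined while mesopelagic organisms migrate
    through the OMZ boundary, so twilight pings are excluded upstream of it.
    """
    diel = b.e38.diel
    if any(d is None for d in diel):
        raise ValueError("diel labels must be assigned before twilight removal")
    keep = diel != TWILIGHT
    if not np.any(keep):
        warnings.warn("all pings are twilight; result is an empty echogram", stacklevel=2)
    return b.select_pings(keep)
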