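"""Continuous Morlet wavelet analysis of Z_VEEC space series.

The boundary-depth series d(x) is resampled to uniform along-track spacing,
demeaned, and convolved with scaled Morlet atoms psi0(eta) = pi^{-1/4}
e^{i omega0 eta} e^{-eta^2/2} (omega0 = 6), normalized so every scale has
unit energy: W(s, x_n) = sum_m d_m sqrt(dx/s) psi0*((x_m - x_n)/s).  The
convolution is evaluated in the Fourier domain (zero-padded, so it equals
direct convolution to rounding error).  Energy is displayed as the adjusted
power |W|^2/s, which makes equal-amplitude oscillations at different scales
equally powerful.  A cone of influence removes positions whose transform is
affected by the series edges (e-folding distance sqrt(2) s), and an AR(1)
red-noise background provides pointwise significance.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft
import scipy.stats
import xarray as xr

DEFAULT_OMEGA0 = 6.0
DEFAULT_DJ = 0.125
DEFAULT_DX_KM = 0.1


class PreconditionError(ValueError):
    """Raised when a series violates a CWT precondition."""


def fourier_factor(omega0: float = DEFAULT_OMEGA0) -> float:
    """Equivalent Fourier wavelength per unit scale: (4 pi)/(w0 + sqrt(2 + w0^2))."""
    return 4.0 * np.pi / (omega0 + np.sqrt(2.0 + omega0**2))


def scale_to_wavelength(scales, omega0: float = DEFAULT_OMEGA0):
    return np.asarray(scales, dtype=float) * fourier_factor(omega0)


def dyadic_scales(
    n: int, dx: float, dj: float = DEFAULT_DJ, s0: float | None = None
) -> np.ndarray:
    """Dyadic scale set s0 * 2^(j dj), from 2 dx up to the series length."""
    if s0 is None:
        s0 = 2.0 * dx
    jmax = int(np.floor(np.log2(n * dx / s0) / dj))
    return s0 * 2.0 ** (dj * np.arange(jmax + 1))


def _morlet_atom(eta: np.ndarray, omega0: float) -> np.ndarray:
    return np.pi**-0.25 * np.exp(1j * omega0 * eta) * np.exp(-0.5 * eta**2)


def morlet_cwt(
    d: np.ndarray,
    dx: float,
    scales: np.ndarray,
    omega0: float = DEFAULT_OMEGA0,
) -> np.ndarray:
    """Morlet CWT coefficients, shape (n_scales, n_points).

    The series must be evenly spaced with no gaps (NaNs); demeaning/
    detrending is the caller's responsibility (see :func:`analyze_series`).
    The Fourier-domain evaluation is zero-padded beyond the widest atom's
    support, so it matches direct convolution to numerical precision.
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 1:
        raise PreconditionError("series must be 1-D")
    if np.any(~np.isfinite(d)):
        raise PreconditionError("series has gaps; fill or split before the CWT")
    scales = np.asarray(scales, dtype=float)
    n = d.size
    # pad past the widest atom's effective support (amplitude < 1e-8 at 6 s)
    halfwidth = int(np.ceil(6.0 * scales.max() / dx))
    m = scipy.fft.next_fast_len(n + 2 * halfwidth)
    fd = scipy.fft.fft(d, m)
    offsets = np.arange(-halfwidth, halfwidth + 1)
    out = np.empty((scales.size, n), dtype=complex)
    for k, s in enumerate(scales):
        psi = _morlet_atom(offsets * dx / s, omega0) * np.sqrt(dx / s)
        kern = np.zeros(m, dtype=complex)
        kern[offsets % m] = psi
        # cross-correlation: W[n] = sum_m d[m] conj(psi[m - n])
        w = scipy.fft.ifft(fd * np.conj(scipy.fft.fft(kern)))
        out[k] = w[:n]
    return out


def adjusted_power(W: np.ndarray, scales: np.ndarray) -> np.ndarray:
    """Adjusted power spectrum |W|^2 / s (bias-corrected across scales)."""
    scales = np.asarray(scales, dtype=float)
    return (np.abs(W) ** 2) / scales[:, None]


def cone_of_influence(n: int, dx: float) -> np.ndarray:
    """Maximum trustworthy scale per position: min distance to an edge / sqrt(2).

    Piecewise linear with slope +-dx/sqrt(2); zero at the endpoints and
    largest at the series midpoint.
    """
    x = np.arange(n) * dx
    return np.minimum(x, (n - 1) * dx - x) / np.sqrt(2.0)


def red_noise_significance(
    W: np.ndarray,
    d: np.ndarray,
    scales: np.ndarray,
    dx: float,
    level: float = 0.95,
    omega0: float = DEFAULT_OMEGA0,
) -> np.ndarray:
    """Pointwise significance of |W|^2 against an AR(1) background.

    The background spectrum is the normalized AR(1) (red-noise) spectrum at
    the Fourier frequency equivalent to each scale, with lag-1
    autocorrelation estimated from the series; |W|^2 is chi^2 with 2 degrees
    of freedom about sigma^2 P(f), so a cell is significant when |W|^2
    exceeds sigma^2 P(f) chi2_2(level)/2.
    """
    d = np.asarray(d, dtype=float)
    if d.size < 8:
        raise PreconditionError("series too short to estimate lag-1 autocorrelation")
    dd = d - d.mean()
    denom = float(np.dot(dd, dd))
    if denom == 0:
        return np.zeros_like(np.abs(W), dtype=bool)
    alpha = float(np.dot(dd[:-1], dd[1:]) / denom)
    alpha = float(np.clip(alpha, 0.0, 0.999))
    sigma2 = float(np.var(d))
    freqs = 1.0 / scale_to_wavelength(scales, omega0)  # cycles per km
    pk = (1.0 - alpha**2) / (1.0 + alpha**2 - 2.0 * alpha * np.cos(2.0 * np.pi * freqs * dx))
    chi2 = scipy.stats.chi2.ppf(level, df=2) / 2.0
    threshold = sigma2 * pk * chi2
    return (np.abs(W) ** 2) > threshold[:, None]


@dataclass
class WaveletSpectrum:
    """Adjusted Morlet power of a space series with COI and significance."""

    positions_km: np.ndarray
    scales_km: np.ndarray
    power_adj: np.ndarray  # (n_scales, n_positions)
    coi_km: np.ndarray  # max trustworthy scale per position
    signif: np.ndarray | None = None

    @property
    def wavelengths_km(self) -> np.ndarray:
        return scale_to_wavelength(self.scales_km)

    def in_cone(self) -> np.ndarray:
        """Boolean grid of cells whose scale lies within the COI."""
        return self.scales_km[:, None] <= self.coi_km[None, :]

    def to_netcdf(self, path) -> None:
        data = {
            "power_adj": (("scale_km", "position_km"), self.power_adj),
            "coi_km": ("position_km", self.coi_km),
        }
        if self.signif is not None:
            data["signif"] = (("scale_km", "position_km"), self.signif.astype(np.int8))
        ds = xr.Dataset(
            data, coords={"position_km": self.positions_km, "scale_km": self.scales_km}
        )
        ds.to_netcdf(path, engine="scipy")


def resample_uniform(
    distance_km: np.ndarray, values: np.ndarray, dx_km: float = DEFAULT_DX_KM
) -> tuple[np.ndarray, np.ndarray]:
    """Linearly resample an along-track series to uniform spacing.

    Invalid (NaN) samples are dropped before interpolation; ping spacing
    varies with vessel speed so this is required ahead of the CWT.
    """
    distance_km = np.asarray(distance_km, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(values) & np.isfinite(distance_km)
    if ok.sum() < 2:
        raise PreconditionError("need >= 2 valid samples to resample")
    x = np.arange(distance_km[ok].min(), distance_km[ok].max(), dx_km)
    return x, np.interp(x, distance_km[ok], values[ok])


def analyze_series(
    distance_km: np.ndarray,
    values: np.ndarray,
    dx_km: float = DEFAULT_DX_KM,
    omega0: float = DEFAULT_OMEGA0,
    dj: float = DEFAULT_DJ,
    detrend: bool = False,
    significance_level: float | None = 0.95,
) -> WaveletSpectrum:
    """Full wavelet pipeline: uniform resample, demean, CWT, adjust, COI.

    Mean removal is the default; linear detrending is available by flag.
    """
    x, d = resample_uniform(distance_km, values, dx_km)
    if detrend:
        coef = np.polyfit(x, d, 1)
        d = d - np.polyval(coef, x)
    else:
        d = d - d.mean()
    scales = dyadic_scales(d.size, dx_km, dj)
    W = morlet_cwt(d, dx_km, scales, omega0)
    power = adjusted_power(W, scales)
    coi = cone_of_influence(d.size, dx_km)
    signif = None
    if significance_level is not None and d.size >= 8:
        signif = red_noise_significance(W, d, scales, dx_km, significance_level, omega0)
    return WaveletSpectrum(
        positions_km=x, scales_km=scales, power_adj=power, coi_km=coi, signif=signif
    )
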