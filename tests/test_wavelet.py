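"""Morlet CWT, adjusted power, cone of influence and red-noise significance."""
import numpy as np
import pytest

from veec.wavelet import (
    PreconditionError,
    adjusted_power,
    analyze_series,
    cone_of_influence,
    dyadic_scales,
    fourier_factor,
    morlet_cwt,
    red_noise_significance,
    resample_uniform,
    scale_to_wavelength,
)

OMEGA0 = 6.0


def direct_cwt(d, dx, scales, omega0=OMEGA0):
    """Independent oracle: brute-force convolution sum."""
    n = d.size
    out = np.zeros((len(scales), n), complex)
    for k, s in enumerate(scales):
        for i in range(n):
            eta = (np.arange(n) - i) * dx / s
            psi = np.pi**-0.25 * np.exp(1j * omega0 * eta) * np.exp(-0.5 * eta**2)
            out[k, i] = np.sum(d * np.conj(psi)) * np.sqrt(dx / s)
    return out


class TestMorletCWT:
    def test_zero_series_zero_coefficients(self):
        scales = dyadic_scales(64, 0.5)
        W = morlet_cwt(np.zeros(64), 0.5, scales)
        np.testing.assert_allclose(np.abs(W), 0.0)

    def test_matches_direct_convolution(self):
        rng = np.random.default_rng(8)
        d = rng.standard_normal(80)
        dx = 0.25
        scales = dyadic_scales(80, dx)
        W = morlet_cwt(d, dx, scales)
        Wd = direct_cwt(d, dx, scales)
        rel = np.max(np.abs(W - Wd)) / np.max(np.abs(Wd))
        assert rel < 1e-6

    def test_cosine_peak_at_matching_scale(self):
        # wavelength 10 km: |W| peaks where the equivalent Fourier
        # wavelength (4 pi / (w0 + sqrt(2 + w0^2)) per unit scale) is 10 km
        dx = 0.1
        n = 1024
        x = np.arange(n) * dx
        d = np.cos(2.0 * np.pi * x / 10.0)
        scales = dyadic_scales(n, dx)
        W = morlet_cwt(d, dx, scales)
        mid = slice(n // 4, 3 * n // 4)
        mean_amp = np.abs(W[:, mid]).mean(axis=1)
        peak_wavelength = scale_to_wavelength(scales[np.argmax(mean_amp)])
        step = 2.0**0.125
        assert 10.0 / step <= peak_wavelength <= 10.0 * step

    def test_impulse_envelope_efolding(self):
        n, dx = 257, 1.0
        d = np.zeros(n)
        d[n // 2] = 1.0
        s = 5.0 * np.sqrt(2.0)  # sqrt(2) * s = 10 samples exactly
        W = morlet_cwt(d, dx, np.array([s]))[0]
        centre = np.abs(W[n // 2])
        at_efold = np.abs(W[n // 2 + 10])
        assert at_efold / centre == pytest.approx(np.exp(-1.0), rel=1e-9)

    def test_linearity(self):
        rng = np.random.default_rng(9)
        d1, d2 = rng.standard_normal(64), rng.standard_normal(64)
        scales = dyadic_scales(64, 1.0)
        Wsum = morlet_cwt(2.0 * d1 - 3.0 * d2, 1.0, scales)
        Wparts = 2.0 * morlet_cwt(d1, 1.0, scales) - 3.0 * morlet_cwt(d2, 1.0, scales)
        np.testing.assert_allclose(Wsum, Wparts, atol=1e-12)

    def test_translation_covariance_interior(self):
        rng = np.random.default_rng(10)
        base = rng.standard_normal(40)
        n, k = 200, 7
        d1 = np.zeros(n)
        d1[60:100] = base
        d2 = np.zeros(n)
        d2[60 + k : 100 + k] = base
        scales = np.array([2.0, 4.0, 8.0])
        W1 = morlet_cwt(d1, 1.0, scales)
        W2 = morlet_cwt(d2, 1.0, scales)
        np.testing.assert_allclose(W2[:, 60 + k : 100 + k], W1[:, 60:100], atol=1e-10)

    def test_gaps_rejected(self):
        d = np.zeros(32)
        d[3] = np.nan
        with pytest.raises(PreconditionError):
            morlet_cwt(d, 1.0, np.array([2.0]))


class TestAdjustedPower:
    def test_definition_ratio(self):
        W = np.ones((2, 4), complex)
        p = adjusted_power(W, np.array([5.0, 10.0]))
        assert p[0, 0] / p[1, 0] == pytest.approx(2.0)

    def test_zero_power(self):
        p = adjusted_power(np.zeros((2, 3), complex), np.array([1.0, 2.0]))
        np.testing.assert_allclose(p, 0.0)

    def test_white_noise_raw_power_flat_across_scales(self):
        # E|W|^2 = sigma^2 at every scale for white noise under the unit-energy
        # normalization, so the time-mean raw power is scale-flat (and the
        # adjusted power decays exactly as 1/s).
        rng = np.random.default_rng(11)
        n, dx = 512, 1.0
        scales = dyadic_scales(n, dx)[:20]
        acc = np.zeros(scales.size)
        reps = 200
        for _ in range(reps):
            d = rng.standard_normal(n)
            W = morlet_cwt(d, dx, scales)
            coi = cone_of_influence(n, dx)
            inc = scales[:, None] <= coi[None, :]
            raw = np.abs(W) ** 2
            acc += np.array([raw[k, inc[k]].mean() for k in range(scales.size)])
        mean_power = acc / reps
        slope = np.polyfit(np.log(scales), np.log(mean_power), 1)[0]
        assert abs(slope) < 0.05  # flat in log-log across scales


class TestConeOfInfluence:
    def test_endpoints_zero_midpoint_max(self):
        coi = cone_of_influence(101, 0.5)
        assert coi[0] == 0.0 and coi[-1] == 0.0
        assert np.argmax(coi) == 50

    def test_piecewise_linear_slope(self):
        dx = 0.5
        coi = cone_of_influence(100, dx)
        first_half = np.diff(coi[:50])
        np.testing.assert_allclose(first_half, dx / np.sqrt(2.0), rtol=1e-12)


class TestRedNoiseSignificance:
    def test_zero_series_nothing_significant(self):
        n, dx = 64, 1.0
        scales = dyadic_scales(n, dx)
        d = np.zeros(n)
        W = morlet_cwt(d, dx, scales)
        sig = red_noise_significance(W, d, scales, dx)
        assert not sig.any()

    def test_short_series_rejected(self):
        with pytest.raises(PreconditionError):
            red_noise_significance(np.zeros((1, 4), complex), np.zeros(4), np.array([2.0]), 1.0)

    def test_ar1_false_positive_rate_calibrated(self):
        """Pure AR(1) noise: ~5% of in-cone cells significant at the 95% level."""
        rng = np.random.default_rng(13)
        n, dx, alpha = 300, 1.0, 0.5
        scales = dyadic_scales(n, dx)
        coi = cone_of_influence(n, dx)
        inc = scales[:, None] <= coi[None, :]
        rates = []
        for _ in range(100):
            e = rng.standard_normal(n)
            d = np.empty(n)
            d[0] = e[0]
            for i in range(1, n):
                d[i] = alpha * d[i - 1] + e[i]
            d = d - d.mean()
            W = morlet_cwt(d, dx, scales)
            sig = red_noise_significance(W, d, scales, dx, 0.95)
            rates.append(sig[inc].mean())
        assert np.mean(rates) == pytest.approx(0.05, abs=0.02)

    def test_injected_sinusoid_significant_band(self):
        rng = np.random.default_rng(14)
        dx, n = 0.1, 1200
        x = np.arange(n) * dx
        d = 3.0 * np.sin(2.0 * np.pi * x / 10.0) + 0.3 * rng.standard_normal(n)
        d = d - d.mean()
        scales = dyadic_scales(n, dx)
        W = morlet_cwt(d, dx, scales)
        sig = red_noise_significance(W, d, scales, dx, 0.95)
        k = int(np.argmin(np.abs(scale_to_wavelength(scales) - 10.0)))
        coi = cone_of_influence(n, dx)
        interior = scales[k] <= coi
        assert sig[k, interior].mean() > 0.9  # contiguous band at the 10-km scale


class TestAnalyzeSeries:
    def test_resample_uniform_drops_gaps(self):
        dist = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        vals = np.array([1.0, np.nan, 3.0, 4.0, 5.0])
        x, d = resample_uniform(dist, vals, 0.5)
        assert np.all(np.isfinite(d))

    def test_two_component_peak_recovery(self):
        """3-km and 10-km injected components appear as adjusted-power peaks
        at those wavelengths, inside the cone, within one dyadic step."""
        dx = 0.1
        x = np.arange(0, 60.0, 0.05)  # irregular-ish fine track, 60 km
        z = 50.0 + 6.0 * np.sin(2 * np.pi * x / 10.0) + 2.5 * np.sin(2 * np.pi * x / 3.0)
        spec = analyze_series(x, z, dx_km=dx, significance_level=None)
        inc = spec.in_cone()
        prof = np.array(
            [
                spec.power_adj[k, inc[k]].mean() if inc[k].any() else 0.0
                for k in range(spec.scales_km.size)
            ]
        )
        lam = spec.wavelengths_km
        peaks = [
            k
            for k in range(1, lam.size - 1)
            if prof[k] >= prof[k - 1] and prof[k] >= prof[k + 1] and prof[k] > 0.05 * prof.max()
        ]
        peak_lams = sorted(lam[k] for k in peaks)
        step = 2.0**0.125
        assert any(3.0 / step <= v <= 3.0 * step for v in peak_lams)
        assert any(10.0 / step <= v <= 10.0 * step for v in peak_lams)
        # the 10-km component dominates
        assert lam[int(np.argmax(prof))] == pytest.approx(10.0, rel=0.15)


def test_fourier_factor_value():
    # (4 pi)/(6 + sqrt(38)) = 1.033 per unit scale for omega0 = 6
    assert fourier_factor(6.0) == pytest.approx(1.033, abs=1e-3)
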