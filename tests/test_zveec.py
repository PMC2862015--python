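"""Cumulative-backscatter depth statistic and its series assembly."""
import numpy as np
import pytest

import veec
from veec.preprocess import drop_twilight, preprocess_bifrequency
from veec.zveec import (
    along_track_resolution_m,
    cumulative_profile,
    threshold_scan,
    zveec_from_profile,
    zveec_series,
)

from conftest import make_bi


def uniform_profile(n_cells=100, depth=100.0, value=1e-7):
    edges = np.linspace(0.0, depth, n_cells + 1)
    other = np.full(n_cells, value)
    fish = np.zeros(n_cells)
    return cumulative_profile(fish, other, edges)


class TestCumulativeProfile:
    def test_point_mass_jumps_at_cell(self):
        edges = np.arange(0.0, 41.0, 1.0)
        other = np.zeros(40)
        other[19] = 1e-6  # cell 19-20 m
        c = cumulative_profile(np.zeros(40), other, edges)
        assert c.cum_fraction[18] == 0.0
        assert c.cum_fraction[19] == 1.0

    def test_uniform_column_is_linear(self):
        c = uniform_profile()
        np.testing.assert_allclose(c.cum_fraction, c.depths / 100.0, rtol=1e-12)
        assert c.cum_fraction[-1] == pytest.approx(1.0)

    def test_weighted_fish_column_hand_value(self):
        # 50 uniform 1-m zoo cells of s each, one fish cell of 1e4*s at 10 m:
        # with weight 1e-3 the weighted total is 60 s
        edges = np.arange(0.0, 51.0, 1.0)
        s = 1e-8
        other = np.full(50, s)
        fish = np.zeros(50)
        fish[9] = 1e4 * s  # cell 9-10 m
        c = cumulative_profile(fish, other, edges, fish_weight=1e-3)
        assert c.cum_fraction[-1] == pytest.approx(1.0)
        # at 50 m everything is in; at 9 m: 9s of 60s
        assert c.cum_fraction[8] == pytest.approx(9.0 / 60.0)

    def test_all_nodata_raises(self):
        with pytest.raises(ValueError):
            cumulative_profile(np.full(3, np.nan), np.full(3, np.nan), np.arange(4.0))

    def test_nondecreasing_ends_at_one(self):
        rng = np.random.default_rng(0)
        other = rng.random(30) * 1e-7
        c = cumulative_profile(np.zeros(30), other, np.arange(31.0))
        assert np.all(np.diff(c.cum_fraction) >= 0)
        assert c.cum_fraction[-1] == pytest.approx(1.0, abs=1e-12)


class TestZveecFromProfile:
    def test_uniform_column_inverse_cdf(self):
        c = uniform_profile()
        assert zveec_from_profile(c, 0.98) == pytest.approx(98.0, abs=1e-9)

    def test_point_mass_any_threshold(self):
        edges = np.arange(0.0, 41.0, 1.0)
        other = np.zeros(40)
        other[19] = 1e-6
        c = cumulative_profile(np.zeros(40), other, edges)
        for t in (0.5, 0.9, 0.98):
            z = zveec_from_profile(c, t)
            assert 19.0 <= z <= 20.0  # inside the occupied cell

    def test_fish_weight_moves_crossing(self):
        edges = np.arange(0.0, 51.0, 1.0)
        s = 1e-8
        other = np.full(50, s)
        fish = np.zeros(50)
        fish[9] = 1e4 * s
        weighted = cumulative_profile(fish, other, edges, fish_weight=1e-3)
        # 0.98 * 60 s = 58.8 s -> crossed 0.8 through the 48-49 m cell
        assert zveec_from_profile(weighted, 0.98) == pytest.approx(48.8, abs=1e-9)
        unweighted = cumulative_profile(fish, other, edges, fish_weight=1.0)
        z1 = zveec_from_profile(unweighted, 0.98)
        assert 9.0 <= z1 <= 10.0  # crossing inside the fish cell

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(1)
        other = rng.random(60) * 1e-7
        c = cumulative_profile(np.zeros(60), other, np.arange(61.0))
        zs = [zveec_from_profile(c, t) for t in (0.5, 0.8, 0.95, 0.98, 0.99)]
        assert np.all(np.diff(zs) >= 0)

    def test_threshold_domain_checked(self):
        c = uniform_profile()
        for bad in (0.0, 1.0, 1.5, -0.1):
            with pytest.raises(ValueError):
                zveec_from_profile(c, bad)


class TestZveecSeries:
    def test_flat_scene_recovery(self, flat_scene):
        spec, bi, profiles, truth = flat_scene
        prep = drop_twilight(preprocess_bifrequency(bi))
        s = zveec_series(prep)
        assert np.all(s.valid)
        assert np.all(np.abs(s.z_veec_m - truth.z_star_m) <= 0.75)

    def test_single_frequency_agreement(self, flat_scene):
        """120 kHz no-fish channel alone matches the combined estimate."""
        spec, bi, profiles, truth = flat_scene
        prep = drop_twilight(preprocess_bifrequency(bi))
        combined = zveec_series(prep)
        single = zveec_series(prep, fish_weight=0.0)  # other (120) channel only
        assert np.all(np.abs(combined.z_veec_m - single.z_veec_m) <= 0.75)

    def test_along_track_step_matches_speed(self, flat_scene):
        spec, bi, profiles, truth = flat_scene
        prep = drop_twilight(preprocess_bifrequency(bi))
        s = zveec_series(prep)
        steps = np.diff(s.distance_km) * 1000.0
        assert np.median(steps) == pytest.approx(5.14, abs=0.02)

    def test_empty_survey_gives_empty_series(self):
        bi = make_bi(np.zeros((0, 2)) - 70.0, np.zeros((0, 2)) - 65.0, [0.0, 0.75, 1.5])
        s = zveec_series(bi)
        assert s.n_pings == 0

    def test_nodata_ping_marked_invalid(self):
        sv38 = np.array([[-75.0, -75.0], [np.nan, np.nan]])
        sv120 = np.array([[-65.0, -65.0], [np.nan, np.nan]])
        bi = make_bi(sv38, sv120, [0.0, 0.75, 1.5])
        s = zveec_series(bi)
        assert s.valid.tolist() == [True, False]
        assert np.isnan(s.z_veec_m[1])

    def test_to_frame_columns(self, flat_scene):
        spec, bi, profiles, truth = flat_scene
        prep = drop_twilight(preprocess_bifrequency(bi))
        df = zveec_series(prep).to_frame()
        assert list(df.columns) == [
            "ping_index", "time_iso", "lat", "lon", "diel", "distance_km", "z_veec_m", "valid",
        ]


class TestThresholdScan:
    def test_uniform_column_scan(self):
        # uniform layer over 0-100 m: thresholds map to their own depths
        edges = np.linspace(0.0, 100.0, 134)
        sv120 = np.full((3, 133), -75.0)
        sv38 = np.full((3, 133), -85.0)
        bi = make_bi(sv38, sv120, edges)
        scan = threshold_scan(bi)
        for t, series in scan.items():
            np.testing.assert_allclose(series.z_veec_m, 100.0 * t, atol=0.8)

    def test_deep_sparse_scatterer_makes_99_erratic(self):
        spec = veec.SceneSpec(
            length_km=6.0,
            z_star_start_m=48.0,
            z_star_end_m=52.0,
            seed=9,
            deep_scatterer_ping_fraction=0.2,
        )
        bi, _, _ = veec.generate_scene(spec)
        prep = drop_twilight(preprocess_bifrequency(bi))
        scan = threshold_scan(prep)
        v98 = np.nanvar(scan[0.98].z_veec_m)
        v99 = np.nanvar(scan[0.99].z_veec_m)
        assert v99 >= 2.0 * v98


def test_along_track_resolution_value():
    # 1 ping/s at 10 knots: 10 * 1852 / 3600 = 5.144 m
    assert along_track_resolution_m(10.0, 1.0) == pytest.approx(5.144, abs=5e-3)
    with pytest.raises(ValueError):
        along_track_resolution_m(10.0, 0.0)


def test_fish_weight_robustness(school_scene):
    """Without dense schools, the weight barely matters (<1 m for >=95% of pings)."""
    spec, bi, profiles, truth = school_scene
    prep = drop_twilight(preprocess_bifrequency(bi))
    w_small = zveec_series(prep, fish_weight=1e-3)
    w_one = zveec_series(prep, fish_weight=1.0)
    frac = np.mean(np.abs(w_small.z_veec_m - w_one.z_veec_m) < 1.0)
    assert frac >= 0.95
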