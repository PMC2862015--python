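"""Shared fixtures: small synthetic scenes and hand-built echograms."""
from __future__ import annotations

import datetime as dt

import numpy as np
import pytest

import veec
from veec.echogram import BiFrequencyEchogram, Echogram, PingMeta
from veec.preprocess import drop_twilight, preprocess_bifrequency


def make_pings(n, start="2008-02-10T17:00:00", lat=-8.0, lon=-79.0, dlon=-5e-5, diel="day"):
    t0 = dt.datetime.fromisoformat(start)
    return [
        PingMeta(i, t0 + dt.timedelta(seconds=i), lat, lon + i * dlon, diel) for i in range(n)
    ]


def make_echogram(sv_db, depth_edges, frequency=120.0, diel="day", **kwargs):
    sv_db = np.asarray(sv_db, dtype=float)
    pings = make_pings(sv_db.shape[0], diel=diel, **kwargs)
    return Echogram(frequency, sv_db, np.asarray(depth_edges, dtype=float), pings)


def make_bi(sv38, sv120, depth_edges, diel="day"):
    e38 = make_echogram(sv38, depth_edges, frequency=38.0, diel=diel)
    e120 = make_echogram(sv120, depth_edges, frequency=120.0, diel=diel)
    return BiFrequencyEchogram(e38, e120)


@pytest.fixture(scope="session")
def flat_scene():
    """Flat 50 m oxycline, no noise/speckle/jitter/schools: the closure case."""
    spec = veec.SceneSpec(
        length_km=2.0,
        z_star_start_m=50.0,
        z_star_end_m=50.0,
        undulations=(),
        speckle_db=0.0,
        base_jitter_sd_m=0.0,
        n_schools=0,
        seed=11,
    )
    return spec, *veec.generate_scene(spec, n_stations=4)


@pytest.fixture(scope="session")
def school_scene():
    """Scene with fish schools and speckle (no background noise)."""
    # school density matches the validation survey (~0.23 schools per km)
    spec = veec.SceneSpec(
        length_km=8.0,
        z_star_start_m=40.0,
        z_star_end_m=55.0,
        n_schools=2,
        seed=5,
    )
    return spec, *veec.generate_scene(spec, n_stations=8)


@pytest.fixture(scope="session")
def validation_survey():
    """The full-size validation survey: 5000 pings, 96 stations, 20-120 m oxycline."""
    spec = veec.SceneSpec(
        length_km=25.7,
        z_star_start_m=20.0,
        z_star_end_m=120.0,
        n_schools=6,
        noise_offset_db={38: -140.0, 120: -140.0},
        seed=1,
    )
    bi, profiles, truth = veec.generate_scene(spec, n_stations=96)
    noise38 = veec.NoiseModel(spec.noise_alpha_db_per_m[38], -140.0)
    noise120 = veec.NoiseModel(spec.noise_alpha_db_per_m[120], -140.0)
    prep = drop_twilight(preprocess_bifrequency(bi, noise38, noise120))
    series = veec.zveec_series(prep)
    return spec, prep, profiles, truth, series
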