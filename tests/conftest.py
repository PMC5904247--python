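"""Shared fixtures: small controlled synthetic movies."""

import numpy as np
import pytest

from charaph import synthetic_imaging as si


@pytest.fixture(scope="session")
def three_event_movie():
    """Noise-free 128×128 movie with three well-separated transient spots."""
    config = si.ImagingConfig(
        frame_count=360,
        image_size=(128, 128),
        gain=50.0,
        offset=200.0,
        noise=si.NoiseModel(photon=False, read_sigma=0.0),
        seed=7,
    )
    scen = si.scenario("saline")
    # onsets sit after the detector's default 50-frame baseline window
    events = [
        si.GroundTruthEvent(0, (34.0, 30.0), 15.0, 84.0, 25.0, 130.0),
        si.GroundTruthEvent(1, (90.0, 40.0), 15.0, 96.0, 50.0, 190.0),
        si.GroundTruthEvent(2, (60.0, 95.0), 15.0, 150.0, 25.0, 130.0),
    ]
    result = si.render_movie(scen, config, events=events)
    return result, config


@pytest.fixture(scope="session")
def empty_movie():
    """Noise-free movie with no events and no bands."""
    config = si.ImagingConfig(
        frame_count=80,
        image_size=(64, 64),
        noise=si.NoiseModel(photon=False, read_sigma=0.0),
        seed=0,
    )
    scen = si.scenario("saline")
    result = si.render_movie(scen, config, events=[])
    return result, config


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
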