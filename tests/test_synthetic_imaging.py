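"""Synthetic movie generator: FITC response, scenarios, noise, determinism."""

import numpy as np
import pytest

from charaph import synthetic_imaging as si


def _tiny_config(**kwargs):
    defaults = dict(
        frame_count=50,
        image_size=(64, 64),
        noise=si.NoiseModel(photon=False, read_sigma=0.0),
        seed=1,
    )
    defaults.update(kwargs)
    return si.ImagingConfig(**defaults)


def test_fitc_monotone_then_flat():
    ph = np.linspace(5.0, 7.5, 100)
    values = si.FITC.intensity(ph, gain=50.0, offset=200.0)
    assert np.all(np.diff(values) > 0)
    high = si.FITC.intensity(np.array([7.5, 8.5, 9.5, 14.0]), 50.0, 200.0)
    assert np.all(high == high[0])  # saturation: pH is unreadable up there
    # continuity at the knee
    assert si.FITC.intensity(7.5 - 1e-9, 50.0, 200.0) == pytest.approx(
        high[0], rel=1e-9
    )


def test_saturation_hides_peak_ph_at_spot_center():
    """Rendered center intensity is identical for peak pH 8.5 and 9.5:
    above the FITC knee the dye cannot distinguish them."""
    scen = si.scenario("saline")
    config = _tiny_config()

    def center_trace(ph):
        ev = [si.GroundTruthEvent(0, (32.0, 32.0), 15.0, 2.4, 12.0, 24.0, peak_ph=ph)]
        stack = si.render_movie(scen, config, events=ev).stack
        return stack[:, 32, 32]

    a, b = center_trace(8.5), center_trace(9.5)
    peak_frame = 12  # envelope reaches 1 at t = 14.4 s
    assert a[peak_frame] == b[peak_frame]
    assert a[peak_frame] == a[peak_frame + 1]  # flat over the saturated top


def test_same_seed_same_bytes(tmp_path):
    scen = si.scenario("saline_zncl2")
    config = si.ImagingConfig(frame_count=40, image_size=(64, 64), seed=11)
    r1 = si.render_movie(scen, config)
    r2 = si.render_movie(scen, config)
    assert np.array_equal(r1.stack, r2.stack)
    art1 = si.write_movie(tmp_path / "a", r1, config, scen)
    art2 = si.write_movie(tmp_path / "b", r2, config, scen)
    assert art1["movie"]["sha256"] == art2["movie"]["sha256"]
    assert art1["events"]["sha256"] == art2["events"]["sha256"]


def test_different_seed_different_noise():
    scen = si.scenario("saline_zncl2")
    a = si.render_movie(scen, si.ImagingConfig(frame_count=5, image_size=(32, 32), seed=1))
    b = si.render_movie(scen, si.ImagingConfig(frame_count=5, image_size=(32, 32), seed=2))
    assert not np.array_equal(a.stack, b.stack)


@pytest.mark.parametrize("label", ["control_afw", "sorbitol"])
def test_control_scenarios_generate_no_events(label, rng):
    scen = si.scenario(label)
    config = _tiny_config(frame_count=1000)
    assert si.generate_events(scen, config, rng) == []


def test_saline_events_respect_onset_delay(rng):
    scen = si.scenario("saline")
    config = _tiny_config(frame_count=1500, image_size=(256, 256))
    for _ in range(10):
        events = si.generate_events(scen, config, rng)
        for ev in events:
            assert ev.onset_time >= 10.0 * 60.0
            assert ev.onset_time + ev.rise_time + ev.decay_time <= config.duration


def test_zn_scenario_event_rate_dies_within_minutes(rng):
    scen = si.scenario("saline_zncl2")
    config = _tiny_config(frame_count=2000, image_size=(256, 256))
    onsets = [
        ev.onset_time
        for _ in range(10)
        for ev in si.generate_events(scen, config, rng)
    ]
    assert onsets  # some early events exist across seeds
    assert max(onsets) < 10 * scen.zn_decay_s


def test_events_mutually_separated(rng):
    scen = si.scenario("saline", spot_rate=20.0, onset_delay_range=(0.5, 1.0))
    config = _tiny_config(frame_count=600, image_size=(256, 256))
    events = si.generate_events(scen, config, rng)
    assert len(events) >= 3
    radius_px = 15.0 / config.pixel_size
    for i, a in enumerate(events):
        for b in events[i + 1:]:
            dist = np.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
            assert dist >= 3.0 * radius_px


def test_ph_field_background_and_peak():
    scen = si.scenario("saline")
    config = _tiny_config()
    ev = si.GroundTruthEvent(0, (32.0, 32.0), 15.0, 12.0, 24.0, 48.0)
    before = si.ph_field(scen, config, 6.0, [ev])
    assert np.allclose(before, config.background_ph)
    at_peak = si.ph_field(scen, config, 36.0, [ev])  # envelope exactly 1
    assert at_peak[32, 32] == pytest.approx(ev.peak_ph, rel=1e-9)


def test_control_field_is_bands_only():
    scen = si.scenario("control_afw")
    config = _tiny_config(image_size=(64, 256))
    field = si.ph_field(scen, config, 30.0)
    band = scen.bands[0]
    inside = field[:, band.center_col]
    assert np.all(inside == band.ph)
    assert np.all(field[:, :100] == config.background_ph)


def test_peak_frame_arithmetic_on_the_frame_grid():
    """A 25 s rise sampled at 1.2 s frames peaks 21 frames after onset."""
    scen = si.scenario("saline")
    config = _tiny_config(frame_count=200)
    ev = si.GroundTruthEvent(0, (32.0, 32.0), 15.0, 12.0, 25.0, 130.0)
    result = si.render_movie(scen, config, events=[ev])
    row = result.events_table.iloc[0]
    onset_frame = int(np.ceil(ev.onset_time / config.frame_interval))
    assert row.peak_frame == onset_frame + round(25.0 / 1.2)


def test_photon_noise_variance_grows_with_mean():
    """Temporal variance of a flat region scales with its mean intensity
    when photon noise is on (checked inside vs outside a bright band)."""
    scen = si.scenario("control_afw")
    config = si.ImagingConfig(
        frame_count=100,
        image_size=(64, 256),
        gain=400.0,
        offset=100.0,
        noise=si.NoiseModel(photon=True, read_sigma=0.0),
        seed=5,
    )
    stack = si.render_movie(scen, config).stack.astype(float)
    band_col = scen.bands[0].center_col
    var_band = stack[:, :, band_col].var(axis=0).mean()
    var_bg = stack[:, :, 10].var(axis=0).mean()
    mean_band = stack[:, :, band_col].mean()
    mean_bg = stack[:, :, 10].mean()
    assert mean_band > mean_bg
    assert var_band > 1.5 * var_bg


def test_bit_depth_and_clipping():
    scen = si.scenario("saline")
    config = _tiny_config(gain=1e6, offset=6e4, frame_count=3)
    ev = [si.GroundTruthEvent(0, (32.0, 32.0), 15.0, 0.0, 1.2, 2.4)]
    result = si.render_movie(scen, config, events=ev)
    assert result.stack.dtype == np.uint16
    assert result.clipped_pixels > 0
    cfg32 = _tiny_config(bit_depth=32, frame_count=3)
    assert si.render_movie(scen, cfg32, events=ev).stack.dtype == np.float32


def test_config_for_snr_amplitude_ratio():
    for snr in (3.0, 5.0, 10.0):
        cfg = si.config_for_snr(snr, frame_count=10)
        amplitude = cfg.gain * (si.FITC.linear_high - cfg.background_ph)
        center_mean = cfg.offset + cfg.gain * (
            si.FITC.linear_high - si.FITC.linear_low
        )
        sigma = np.sqrt(center_mean + cfg.noise.read_sigma**2)
        assert amplitude / sigma == pytest.approx(snr, rel=1e-9)


def test_ground_truth_visibility_matches_ten_percent_rule(three_event_movie):
    result, config = three_event_movie
    table = result.events_table
    assert len(table) == 3
    for _, row in table.iterrows():
        assert row.visible_onset_frame <= row.peak_frame <= row.visible_end_frame
        vis = result.visibility_table.query("event_id == @row.event_id")
        assert vis.frame.min() == row.visible_onset_frame
        assert vis.frame.max() == row.visible_end_frame


def test_config_validation():
    with pytest.raises(ValueError):
        si.ImagingConfig(frame_count=0)
    with pytest.raises(ValueError):
        si.ImagingConfig(frame_count=10, frame_interval=0.0)
    with pytest.raises(ValueError):
        si.ImagingConfig(frame_count=10, bit_depth=8)
    with pytest.raises(ValueError):
        si.scenario("brine")
    with pytest.raises(ValueError):
        si.GroundTruthEvent(0, (0, 0), 15.0, -1.0, 25.0, 130.0)
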