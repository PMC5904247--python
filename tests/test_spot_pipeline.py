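"""Spot detection, tracking, kinetics recovery, kymographs, projections."""

import numpy as np
import pytest

from charaph import synthetic_imaging as si
from charaph import spot_pipeline as sp


def test_background_model_constant_stack():
    stack = np.full((20, 16, 16), 37.0)
    baseline, sigma = sp.background_model(stack, 10)
    assert np.all(baseline == 37.0)
    assert np.all(sigma == sp._SIGMA_FLOOR)


def test_background_model_single_frame_window():
    stack = np.arange(2 * 4 * 4, dtype=float).reshape(2, 4, 4)
    baseline, _ = sp.background_model(stack, 1)
    assert np.array_equal(baseline, stack[0])


def test_background_model_rejects_short_stack():
    with pytest.raises(ValueError, match="baseline_frames"):
        sp.background_model(np.zeros((5, 4, 4)), 10)


def test_background_model_matches_rendered_background(three_event_movie):
    result, config = three_event_movie
    baseline, _ = sp.background_model(result.stack.astype(float), 15)
    expected = config.offset + config.gain * (config.background_ph - 5.0)
    assert np.allclose(baseline, expected, atol=1.0)


def test_detect_three_events_at_their_peaks(three_event_movie):
    result, config = three_event_movie
    detection = sp.detect_spots(result.stack, pixel_size=config.pixel_size)
    for _, row in result.events_table.iterrows():
        regions = detection.regions[int(row.peak_frame)]
        near = [
            r for r in regions
            if np.hypot(r.centroid[0] - row.row, r.centroid[1] - row.col) < 10
        ]
        assert len(near) == 1
    # no detections at all before the first physical onset
    first = int(result.events_table.onset_s.min() / config.frame_interval)
    assert all(not detection.regions[k] for k in range(first))


def test_empty_movie_detects_nothing(empty_movie):
    result, config = empty_movie
    detection = sp.detect_spots(result.stack, pixel_size=config.pixel_size)
    assert all(not regions for regions in detection.regions)
    assert sp.link_tracks(detection, pixel_size=config.pixel_size) == []


def test_min_area_filter_dominates(three_event_movie):
    result, config = three_event_movie
    params = sp.DetectionParams(min_area=1e6)
    detection = sp.detect_spots(result.stack, params, config.pixel_size)
    assert all(not regions for regions in detection.regions)


def test_tracks_recover_events_and_lifetimes_noise_free(three_event_movie):
    result, config = three_event_movie
    detection = sp.detect_spots(result.stack, pixel_size=config.pixel_size)
    tracks = sp.link_tracks(
        detection, frame_interval=config.frame_interval,
        pixel_size=config.pixel_size,
    )
    assert len(tracks) == 3
    match = sp.match_tracks_to_events(
        tracks, result.events_table, config.frame_interval, config.pixel_size
    )
    assert match.recall == 1.0 and match.precision == 1.0
    assert match.matches.lifetime_error_frames.abs().max() <= 2
    for t in tracks:
        assert t.onset_frame <= t.peak_frame <= t.end_frame
        assert t.lifetime == pytest.approx(
            (t.end_frame - t.onset_frame) * config.frame_interval
        )
        assert (
            t.rise_time + t.decay_time
            <= t.lifetime + 2 * config.frame_interval
        )


def test_rise_and_decay_recovery_with_noise():
    """Movies with the two observed kinetic classes (25/130 s and 50/190 s)
    yield rise and decay times within ±3 frames of ground truth at
    amplitude SNR 5."""
    for seed, (rise, decay) in ((3, (25.0, 130.0)), (4, (50.0, 190.0))):
        config = si.config_for_snr(
            5.0, frame_count=400, image_size=(128, 128), seed=seed
        )
        events = [
            si.GroundTruthEvent(0, (35.0, 35.0), 15.0, 72.0, rise, decay),
            si.GroundTruthEvent(1, (90.0, 85.0), 15.0, 120.0, rise, decay),
        ]
        result = si.render_movie(si.scenario("saline"), config, events=events)
        detection = sp.detect_spots(result.stack, pixel_size=config.pixel_size)
        tracks = sp.link_tracks(
            detection, frame_interval=config.frame_interval,
            pixel_size=config.pixel_size,
        )
        match = sp.match_tracks_to_events(
            tracks, result.events_table, config.frame_interval,
            config.pixel_size,
        )
        assert match.recall == 1.0
        truth = result.events_table.set_index("event_id")
        for _, m in match.matches.iterrows():
            track = tracks[int(m.track_id)]
            row = truth.loc[m.event_id]
            assert abs(track.rise_time - row.rise_obs_s) <= 3 * config.frame_interval
            assert abs(track.decay_time - row.decay_obs_s) <= 3 * config.frame_interval


def test_simultaneous_distant_events_never_merge():
    config = si.ImagingConfig(
        frame_count=220, image_size=(128, 128),
        noise=si.NoiseModel(photon=False, read_sigma=0.0), seed=2,
    )
    events = [
        si.GroundTruthEvent(0, (30.0, 30.0), 15.0, 72.0, 25.0, 130.0),
        si.GroundTruthEvent(1, (95.0, 95.0), 15.0, 72.0, 25.0, 130.0),
    ]
    result = si.render_movie(si.scenario("saline"), config, events=events)
    detection = sp.detect_spots(result.stack, pixel_size=config.pixel_size)
    tracks = sp.link_tracks(detection, pixel_size=config.pixel_size)
    assert len(tracks) == 2


def test_detection_translation_equivariant(three_event_movie):
    result, config = three_event_movie
    shifted = np.roll(result.stack, shift=(6, -9), axis=(1, 2))
    base = sp.detect_spots(result.stack, pixel_size=config.pixel_size)
    moved = sp.detect_spots(shifted, pixel_size=config.pixel_size)
    tracks_a = sp.link_tracks(base, pixel_size=config.pixel_size)
    tracks_b = sp.link_tracks(moved, pixel_size=config.pixel_size)
    assert len(tracks_a) == len(tracks_b)
    ca = sorted((t.centroid for t in tracks_a))
    cb = sorted(((r - 6, c + 9) for r, c in (t.centroid for t in tracks_b)))
    for (ra, caa), (rb, cbb) in zip(ca, cb):
        assert abs(ra - rb) < 0.75 and abs(caa - cbb) < 0.75


def test_persistent_spot_classification():
    config = si.ImagingConfig(
        frame_count=400, image_size=(64, 64),
        noise=si.NoiseModel(photon=False, read_sigma=0.0), seed=2,
    )
    ev = si.GroundTruthEvent(
        0, (32.0, 32.0), 15.0, 72.0, 25.0, 1.0, persistent=True
    )
    result = si.render_movie(si.scenario("saline"), config, events=[ev])
    detection = sp.detect_spots(result.stack, pixel_size=config.pixel_size)
    tracks = sp.link_tracks(
        detection, frame_interval=config.frame_interval,
        pixel_size=config.pixel_size,
    )
    assert len(tracks) == 1
    assert tracks[0].classification == "persistent"  # outlives 300 s cutoff


def test_kymograph_static_column():
    stack = np.zeros((30, 40, 50))
    stack[:, :, 17] = 9.0
    kymo = sp.kymograph(stack, axis=1)
    assert kymo.data.shape == (50, 30)
    assert np.all(kymo.data[17] == 9.0)
    assert np.all(kymo.data[[0, 1, 40]] == 0.0)


def test_kymograph_blob_extent_equals_visible_lifetime(three_event_movie):
    result, config = three_event_movie
    row = result.events_table.iloc[0]
    kymo = sp.kymograph(result.stack.astype(float), axis=0)
    trace = kymo.data[int(round(row.row))]
    background = np.median(trace)
    amp = trace.max() - background
    lit = np.nonzero(trace - background >= 0.1 * amp)[0]
    extent = lit[-1] - lit[0]
    truth = row.visible_end_frame - row.visible_onset_frame
    # center-pixel max and disk-mean conventions differ by a few frames
    # around the FITC saturation knee
    assert abs(extent - truth) <= 6


def test_kymograph_of_zero_stack_is_zero():
    kymo = sp.kymograph(np.zeros((5, 8, 8)), axis=0)
    assert not kymo.data.any()


def test_kymograph_line_mode_and_validation():
    stack = np.zeros((4, 16, 16))
    stack[:, 8, 8] = 5.0
    kymo = sp.kymograph(stack, line=((8, 0), (8, 15)), linewidth=3)
    assert kymo.data.shape[1] == 4
    assert kymo.data.max() == 5.0
    with pytest.raises(ValueError, match="outside"):
        sp.kymograph(stack, line=((0, 0), (99, 99)))
    with pytest.raises(ValueError):
        sp.kymograph(stack, axis=2)


def test_z_project_properties(three_event_movie):
    result, _ = three_event_movie
    stack = result.stack
    proj = sp.z_project(stack)
    assert np.array_equal(sp.z_project(stack[:1]), stack[0])  # idempotent
    assert np.all(proj >= stack.max(axis=0) - 0)  # pixelwise max bound
    # three non-overlapping events leave three disjoint bright regions
    from skimage import measure as skmeasure

    mask = proj > proj.min() + 0.5 * (proj.max() - proj.min())
    labels = skmeasure.label(mask, connectivity=2)
    assert labels.max() == 3
    with pytest.raises(ValueError):
        sp.z_project(np.zeros((0, 4, 4)))
    with pytest.raises(ValueError):
        sp.z_project(np.zeros((4, 4)))


def test_tracks_table_round_trip(three_event_movie):
    result, config = three_event_movie
    detection = sp.detect_spots(result.stack, pixel_size=config.pixel_size)
    tracks = sp.link_tracks(
        detection, frame_interval=config.frame_interval,
        pixel_size=config.pixel_size,
    )
    table = sp.tracks_table(tracks, config.frame_interval)
    assert len(table) == 3
    assert set(table.classification) == {"transient"}
    assert (table.lifetime_s > 0).all()


def test_detection_params_validation():
    for kwargs in (
        {"baseline_frames": 0},
        {"k_sigma": 0.0},
        {"min_area": -1.0},
        {"min_duration": 0},
        {"max_gap": -1},
    ):
        with pytest.raises(ValueError):
            sp.DetectionParams(**kwargs)
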