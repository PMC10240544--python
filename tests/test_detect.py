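"""Nuclei detection: planted-disk recovery, coordinate transforms, marking."""

import numpy as np
import pytest

from simscope import (
    DetectionParams,
    MacroPosition,
    TileStore,
    ValidationError,
    detect_nuclei,
    generate_synthetic_sample,
    image_to_stage,
    place_separated_nuclei,
    scan_and_mark,
)
from simscope.stage import axes_from_depot, move_to

from conftest import attach_sample

PARAMS = DetectionParams(radius_min_px=10.0, radius_max_px=30.0)


def test_blank_image_yields_no_detections():
    assert detect_nuclei(np.full((128, 128), 500, dtype=np.uint16), PARAMS) == []


def test_noise_only_image_yields_no_detections():
    rng = np.random.default_rng(1)
    noise = (400 + rng.normal(0, 30, (256, 256))).astype(np.uint16)
    assert detect_nuclei(noise, PARAMS) == []


def test_degenerate_params_rejected():
    with pytest.raises(ValidationError):
        DetectionParams(blur_sigma_px=0.0)
    with pytest.raises(ValidationError):
        DetectionParams(radius_min_px=20.0, radius_max_px=10.0)


def test_five_planted_disks_recovered_within_two_pixels():
    centres = [(80.0, 80.0), (250.0, 90.0), (400.0, 180.0), (120.0, 300.0), (330.0, 380.0)]
    sample, truth = generate_synthetic_sample(
        480, 480, 1, [(x, y, 20.0, 1200.0) for x, y in centres], seed=21
    )
    dets = detect_nuclei(sample.data[0], PARAMS)
    assert len(dets) == 5
    for t in truth:
        best = min(
            np.hypot(d.centre_px[1] - t.x_px, d.centre_px[0] - t.y_px)
            for d in dets
        )
        assert best <= 2.0


def test_small_disk_excluded_by_radius_filter():
    sample, _ = generate_synthetic_sample(
        200, 200, 1, [(100.0, 100.0, 4.0, 1500.0)], seed=2
    )
    dets = detect_nuclei(sample.data[0], PARAMS)  # radius_min = 10
    assert dets == []


def test_raising_circularity_floor_never_adds_detections():
    nuclei = place_separated_nuclei(512, 512, 6, seed=8, min_separation_px=90.0)
    sample, _ = generate_synthetic_sample(512, 512, 1, nuclei, seed=9)
    counts = [
        len(detect_nuclei(sample.data[0],
                          DetectionParams(radius_min_px=10.0, radius_max_px=30.0,
                                          circularity_min=c)))
        for c in (0.0, 0.5, 0.8, 0.95, 1.0)
    ]
    assert counts == sorted(counts, reverse=True)


def test_detection_is_deterministic():
    sample, _ = generate_synthetic_sample(
        300, 300, 1, [(150.0, 150.0, 18.0, 1000.0)], seed=5
    )
    a = detect_nuclei(sample.data[0], PARAMS)
    b = detect_nuclei(sample.data[0], PARAMS)
    assert a == b


def test_sensor_centre_pixel_maps_to_tile_centre():
    centre = MacroPosition(100.0, 100.0, 7.0)
    pos = image_to_stage((256.0, 256.0), centre, 1.0, (512, 512))
    assert pos.as_tuple() == pytest.approx((100.0, 100.0, 7.0))


def test_corner_pixel_transform_arithmetic():
    pos = image_to_stage((0.0, 0.0), MacroPosition(100.0, 100.0, 0.0), 1.0, (512, 512))
    assert (pos.x_um, pos.y_um) == pytest.approx((100.0 - 256.0, 100.0 - 256.0))


def test_out_of_sensor_pixel_rejected():
    with pytest.raises(ValidationError):
        image_to_stage((600.0, 10.0), MacroPosition(), 1.0, (512, 512))


def test_detect_then_transform_recovers_planted_stage_position(sim_depot):
    sample, truth = generate_synthetic_sample(
        700, 700, 3, [(350.0, 330.0, 20.0, 1400.0)], seed=13
    )
    attach_sample(sim_depot, sample)
    axes = axes_from_depot(sim_depot)
    stage_at = MacroPosition(340.0, 345.0, 0.0)
    move_to(axes, stage_at)
    from simscope import snap

    image = snap(sim_depot, exposure_ms=10.0)
    dets = detect_nuclei(image, PARAMS)
    assert len(dets) == 1
    cam = sim_depot.device_for("camera:camera")
    pos = image_to_stage(
        dets[0].centre_px, stage_at, cam.state.pixel_size_um, cam.state.sensor_shape
    )
    assert np.hypot(pos.x_um - truth[0].x_um, pos.y_um - truth[0].y_um) <= 2.0


def test_scan_and_mark_recovers_separated_nuclei(sim_depot):
    # 3x3 mosaic of the 512 px sensor centred at (768, 768): tile edges
    # fall at 0/512/1024/1536; keep nuclei away from them.
    boundaries = [0.0, 512.0, 1024.0, 1536.0]
    nuclei = place_separated_nuclei(
        1536, 1536, 8, seed=31,
        region=(256.0, 1280.0, 256.0, 1280.0),
        avoid_x=boundaries, avoid_y=boundaries,
        min_separation_px=130.0,
    )
    sample, truth = generate_synthetic_sample(1536, 1536, 3, nuclei, seed=32)
    attach_sample(sim_depot, sample)
    store = TileStore()
    result = scan_and_mark(
        store, sim_depot, MacroPosition(768.0, 768.0, 0.0), 9, PARAMS
    )
    assert result.error is None
    assert len(store.marked_points) >= 7
    matched = 0
    for t in truth:
        dists = [
            np.hypot(p.position.x_um - t.x_um, p.position.y_um - t.y_um)
            for p in store.marked_points
        ]
        if dists and min(dists) <= 2.0:
            matched += 1
    assert matched >= 7
    # no spurious mark far from every planted nucleus
    for p in store.marked_points:
        nearest = min(
            np.hypot(p.position.x_um - t.x_um, p.position.y_um - t.y_um)
            for t in truth
        )
        assert nearest <= 2 * 25.0


def test_scan_and_mark_zero_nuclei_gives_zero_marks(sim_depot):
    sample, _ = generate_synthetic_sample(1536, 1536, 3, [], seed=40)
    attach_sample(sim_depot, sample)
    store = TileStore()
    scan_and_mark(store, sim_depot, MacroPosition(768.0, 768.0, 0.0), 4, PARAMS)
    assert store.marked_points == []
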