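"""Detection stage: thresholding, merging blur, component finding, patches."""

import numpy as np
import pytest

from octtm import (
    CI_LARGE_STAGE,
    TM,
    DetectionParams,
    PhantomConfig,
    binarize,
    detect_objects,
    extract_patch,
    find_objects,
    generate_phantom,
    smooth,
)

from conftest import bruteforce_components, noise_free_config


def test_binarize_examples():
    img = np.array([[10, 200], [128, 129]], dtype=np.uint8)
    np.testing.assert_array_equal(
        binarize(img, 128), np.array([[False, True], [False, True]])
    )
    assert not binarize(np.zeros((4, 4), np.uint8), 0).any()
    rng = np.random.default_rng(0)
    assert not binarize(rng.integers(0, 256, (8, 8)).astype(np.uint8), 255).any()


def test_smooth_identity_and_merging():
    img = np.zeros((9, 9), dtype=bool)
    img[4, 2] = img[4, 6] = True  # two dots, gap of 3 px
    assert smooth(img, 0) is not None
    np.testing.assert_array_equal(smooth(img, 0), img)
    merged = smooth(img, 2)
    assert len(bruteforce_components(merged)) == 1
    assert len(bruteforce_components(smooth(img, 1))) == 2
    assert not smooth(np.zeros((5, 5), bool), 3).any()


def test_find_objects_area_filtering():
    img = np.zeros((30, 30), dtype=bool)
    img[:10, :10] = True          # area 100
    img[20:21, 20:25] = True      # area 5
    params = DetectionParams(threshold=0, blur=0, min_area=50)
    objs = find_objects(img, params)
    assert len(objs) == 1 and objs[0].area == 100

    found = find_objects(img, DetectionParams(0, 0, 1))
    assert sorted(o.area for o in found) == [5, 100]
    # descending area ordering
    assert [o.area for o in found] == [100, 5]

    capped = find_objects(img, DetectionParams(0, 0, 1, max_area=50))
    assert [o.area for o in capped] == [5]


def test_find_objects_degenerate_inputs():
    params = DetectionParams(0, 0, 1)
    assert find_objects(np.zeros((6, 6), bool), params) == []
    full = find_objects(np.ones((6, 8), bool), params)
    assert len(full) == 1
    assert full[0].bbox == (0, 0, 8, 6)
    assert full[0].area == 48


def test_detect_objects_pipeline_order():
    """blur=0 detection equals binarize -> find_objects exactly."""
    rng = np.random.default_rng(7)
    img = (rng.random((40, 40)) * 255).astype(np.uint8)
    params = DetectionParams(threshold=128, blur=0, min_area=2)
    direct = find_objects(binarize(img, 128), params)
    composed = detect_objects(img, params)
    assert len(direct) == len(composed)
    for a, b in zip(direct, composed):
        assert a.bbox == b.bbox and a.area == b.area

    assert detect_objects(img, DetectionParams(255, 2, 1)) == []


def test_membrane_slice_detects_single_tm_object():
    """On a noise-free phantom slice the coarse stage finds exactly one
    object and it covers the membrane band almost completely."""
    vol, lab = generate_phantom(noise_free_config(seed=2, with_structures=False))
    y = vol.n_slices // 2
    objs = detect_objects(vol.slice(y), CI_LARGE_STAGE, y)
    assert len(objs) == 1
    canvas = np.zeros(vol.slice(y).shape, dtype=bool)
    objs[0].paint(canvas)
    tm = lab.labels[y] == TM
    assert (canvas & tm).sum() / tm.sum() >= 0.99


def test_extract_patch_geometry_and_values():
    rng = np.random.default_rng(3)
    img = (rng.random((50, 60)) * 255).astype(np.uint8)
    from octtm import DetectedObject

    obj = DetectedObject(0, (10, 20, 30, 20), np.ones((20, 30), bool), 600)
    patch = extract_patch(img, obj, pad=0)
    assert patch.shape == (20, 30)
    np.testing.assert_array_equal(patch, img[20:40, 10:40])  # original values

    clamped = extract_patch(img, obj, pad=100)
    assert clamped.shape == (50, 60)

    outside = DetectedObject(0, (50, 20, 30, 20), np.ones((20, 30), bool), 600)
    with pytest.raises(ValueError):
        extract_patch(img, outside, pad=0)


def test_params_validation():
    with pytest.raises(ValueError):
        DetectionParams(threshold=300, blur=0, min_area=1)
    with pytest.raises(ValueError):
        DetectionParams(threshold=0, blur=-1, min_area=1)
    with pytest.raises(ValueError):
        DetectionParams(threshold=0, blur=0, min_area=0)
    with pytest.raises(ValueError):
        DetectionParams(threshold=0, blur=0, min_area=10, max_area=10)


def test_object_mask_is_single_component():
    vol, _ = generate_phantom(PhantomConfig.ci(seed=21))
    for y in (0, 15, 40):
        for obj in detect_objects(vol.slice(y), CI_LARGE_STAGE, y):
            comps = bruteforce_components(obj.mask)
            assert len(comps) == 1
            assert obj.area >= CI_LARGE_STAGE.min_area
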