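"""Phantom generator: determinism, label discipline, component toggles."""

import numpy as np
import pytest
from skimage import measure

from octtm import (
    ARTIFACT,
    BACKGROUND,
    DEEP_STRUCTURE,
    TM,
    NON_TM_LABEL,
    TM_LABEL,
    DetectedObject,
    LabelVolume,
    PhantomConfig,
    auto_label_object,
    generate_phantom,
)
from octtm.phantom import (
    DeepStructureConfig,
    FixedPatternConfig,
    MembraneConfig,
    SaturationConfig,
)

from conftest import noise_free_config


def test_same_seed_bit_identical():
    cfg = PhantomConfig.ci(seed=42)
    v1, l1 = generate_phantom(cfg)
    v2, l2 = generate_phantom(cfg)
    np.testing.assert_array_equal(v1.voxels, v2.voxels)
    np.testing.assert_array_equal(l1.labels, l2.labels)


def test_different_seeds_differ():
    v1, _ = generate_phantom(PhantomConfig.ci(seed=1))
    v2, _ = generate_phantom(PhantomConfig.ci(seed=2))
    assert (v1.voxels != v2.voxels).any()


def test_noise_free_nonzero_voxels_are_tissue():
    """With noise and artifacts off, every nonzero voxel is membrane or a
    deep structure."""
    vol, lab = generate_phantom(noise_free_config(seed=9))
    nz = vol.voxels > 0
    tissue = (lab.labels == TM) | (lab.labels == DEEP_STRUCTURE)
    assert not (nz & ~tissue).any()


def test_labels_total_and_within_range(ci_phantom):
    vol, lab = ci_phantom
    assert lab.shape == vol.voxels.shape
    assert set(np.unique(lab.labels)) <= {BACKGROUND, TM, DEEP_STRUCTURE, ARTIFACT}


def test_membrane_label_precedence(ci_phantom):
    """Every voxel rendered as membrane keeps the TM label even where a
    saturation line crosses it: TM voxel count per slice never drops where
    lines are present."""
    _, lab = ci_phantom
    per_slice_tm = (lab.labels == TM).sum(axis=(1, 2))
    # membrane spans every slice; its label is never displaced by artifacts
    assert (per_slice_tm > 0).all()


def test_membrane_continuity_per_slice(ci_phantom):
    """The TM label forms one 8-connected component in every slice."""
    _, lab = ci_phantom
    for y in range(lab.shape[0]):
        _, n = measure.label(lab.labels[y] == TM, connectivity=2, return_num=True)
        assert n == 1


@pytest.mark.parametrize(
    "overrides, gone_label",
    [
        (dict(deep_structures=DeepStructureConfig(count=0)), DEEP_STRUCTURE),
        (dict(fixed_pattern=FixedPatternConfig(count=0),
              saturation_lines=SaturationConfig(count=0)), ARTIFACT),
        (dict(membrane=None), TM),
    ],
)
def test_disabling_component_removes_label(overrides, gone_label):
    _, lab = generate_phantom(PhantomConfig.ci(seed=3, **overrides))
    assert not (lab.labels == gone_label).any()


def test_geometry_validation():
    with pytest.raises(ValueError):
        PhantomConfig(geometry=(4, 160, 128))
    with pytest.raises(ValueError):
        PhantomConfig.ci(membrane=MembraneConfig(thickness_px=0))
    with pytest.raises(ValueError):
        PhantomConfig.ci(speckle=-0.1)


def _toy_object(mask):
    h, w = mask.shape
    return DetectedObject(0, (0, 0, w, h), mask, int(mask.sum()))


def test_auto_label_pure_and_mixed_objects():
    labels = np.zeros((1, 10, 10), dtype=np.uint8)
    labels[0, :6, :] = TM          # top 60 px are membrane
    labels[0, 6:, :] = ARTIFACT
    lv = LabelVolume(labels)

    all_tm = DetectedObject(0, (0, 0, 10, 6), np.ones((6, 10), bool), 60)
    assert auto_label_object(all_tm, lv) == TM_LABEL

    all_art = DetectedObject(0, (0, 6, 10, 4), np.ones((4, 10), bool), 40)
    assert auto_label_object(all_art, lv) == NON_TM_LABEL

    # 60% overlap at threshold 0.5 -> TM; brute-force count on the toy mask
    whole = _toy_object(np.ones((10, 10), dtype=bool))
    overlap = sum(
        1 for i in range(10) for j in range(10) if labels[0, i, j] == TM
    ) / 100.0
    assert overlap == 0.6
    assert auto_label_object(whole, lv, tm_overlap_fraction=0.5) == TM_LABEL
    assert auto_label_object(whole, lv, tm_overlap_fraction=0.7) == NON_TM_LABEL


def test_auto_label_out_of_bounds():
    lv = LabelVolume(np.zeros((1, 5, 5), dtype=np.uint8))
    bad = DetectedObject(3, (0, 0, 2, 2), np.ones((2, 2), bool), 4)
    with pytest.raises(IndexError):
        auto_label_object(bad, lv)
    wide = DetectedObject(0, (4, 4, 2, 2), np.ones((2, 2), bool), 4)
    with pytest.raises(IndexError):
        auto_label_object(wide, lv)
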