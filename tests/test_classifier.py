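"""Patch corpus handling, augmentation, sample splits, training accounting."""

import numpy as np
import pytest

from octtm import (
    NON_TM_LABEL,
    TM_LABEL,
    PatchDataset,
    augment_dataset,
    augment_rotations,
    build_model,
    make_split,
    predict,
    standardize_patch,
    train,
)
from octtm.classifier import DEFAULT_ANGLES, evaluate_patches
from octtm.nn import PatchCNN

TINY_ARCH = {
    "input_size": [16, 16],
    "conv_blocks": [{"filters": 4, "kernel": 3}],
    "dense_units": 8,
    "dropout": 0.0,
}


def toy_dataset(n_tm=30, n_other=30, size=(16, 16), seed=0):
    """Separable toy corpus: bright membrane-ish patches vs dark ones."""
    rng = np.random.default_rng(seed)
    patches, labels, ids = [], [], []
    for i in range(n_tm):
        patches.append((0.7 + 0.3 * rng.random(size)).astype(np.float32))
        labels.append(TM_LABEL)
        ids.append(f"tm{i}")
    for i in range(n_other):
        patches.append((0.3 * rng.random(size)).astype(np.float32))
        labels.append(NON_TM_LABEL)
        ids.append(f"bg{i}")
    return PatchDataset(np.stack(patches), labels, ids)


# ---- standardization and augmentation ------------------------------------

def test_standardize_aspect_and_range():
    patch = np.full((30, 90), 200, dtype=np.uint8)
    out = standardize_patch(patch, (64, 64))
    assert out.shape == (64, 64)
    assert 0.0 <= out.min() and out.max() <= 1.0
    # aspect preserved: a 1:3 patch scales to 21x64 and is zero-padded
    rows = np.where(out.sum(axis=1) > 0)[0]
    assert 18 <= len(rows) <= 24
    assert out[0].sum() == 0 and out[-1].sum() == 0


def test_augment_identity_and_square_symmetries():
    rng = np.random.default_rng(1)
    patch = rng.random((32, 32)).astype(np.float32)
    only_zero = augment_rotations(patch, [0])
    assert len(only_zero) == 1
    assert only_zero[0] is patch

    out = augment_rotations(patch, [0, 90, 180, 270])
    assert len(out) == 4
    np.testing.assert_array_equal(out[2], patch[::-1, ::-1])  # 180 = double flip
    np.testing.assert_array_equal(out[1], np.rot90(patch))

    with pytest.raises(ValueError):
        augment_rotations(patch, [])


def test_rotate_then_unrotate_recovers_center():
    # smooth test image: interpolation error, not aliasing, is what's bounded
    zz, xx = np.mgrid[0:40, 0:40] / 40.0
    patch = 0.5 + 0.4 * np.sin(2 * np.pi * zz) * np.cos(2 * np.pi * xx)
    rot = augment_rotations(patch, [17])[0]
    back = augment_rotations(rot, [-17])[0]
    inner = slice(10, 30)
    assert np.abs(back[inner, inner] - patch[inner, inner]).max() < 0.05


def test_augment_dataset_grows_tm_class_only():
    ds = toy_dataset(n_tm=5, n_other=7)
    aug = augment_dataset(ds, angles=DEFAULT_ANGLES)
    counts = aug.class_counts()
    assert counts[TM_LABEL] == 5 * len(DEFAULT_ANGLES)  # |angles|-1 extra copies
    assert counts[NON_TM_LABEL] == 7
    assert len(set(aug.ids)) == len(aug.ids)


# ---- sample splits --------------------------------------------------------

def test_split_pools_validation_per_sample():
    ds = toy_dataset(n_tm=60, n_other=60)
    split = make_split(ds, sample_size=20, train_per_sample=15, n_samples=5, seed=0)
    assert split.n_samples == 5
    assert len(split.val_ids) == 5 * (20 - 15)
    assert len(split.train_ids) == 5 * 15
    assert not set(split.train_ids) & set(split.val_ids)


def test_split_determinism_and_replacement():
    ds = toy_dataset(n_tm=30, n_other=30)
    s1 = make_split(ds, 20, 15, 3, seed=4)
    s2 = make_split(ds, 20, 15, 3, seed=4)
    assert s1.samples == s2.samples and s1.val_ids == s2.val_ids

    with pytest.warns(UserWarning, match="reused"):
        big = make_split(ds, 20, 18, 10, seed=0)  # needs 180 train ids from 40
    assert big.n_samples == 10
    assert not set(big.train_ids) & set(big.val_ids)


def test_split_edge_cases():
    ds = toy_dataset(n_tm=5, n_other=5)
    with pytest.warns(UserWarning, match="empty validation"):
        split = make_split(ds, sample_size=10, train_per_sample=10, n_samples=1, seed=0)
    assert split.val_ids == []
    with pytest.raises(ValueError):
        make_split(PatchDataset(np.zeros((0, 8, 8), np.float32), [], []), 10, 8, 1)
    with pytest.raises(ValueError):
        make_split(ds, sample_size=10, train_per_sample=1, n_samples=2)  # val pool > data


# ---- training -------------------------------------------------------------

def test_training_on_separable_toy_reaches_perfect_train_accuracy():
    ds = toy_dataset(n_tm=40, n_other=40)
    split = make_split(ds, sample_size=20, train_per_sample=16, n_samples=3, seed=0)
    model = build_model(input_size=(16, 16), arch_config=TINY_ARCH, seed=0)
    model, curves = train(model, ds, split, epochs_per_sample=8, seed=0, lr=5e-3)
    assert len(curves) == 3
    assert len(curves.val_accuracy) == 3
    assert curves.train_accuracy[-1] == 1.0
    x, y = ds.take(split.val_ids)
    acc, _ = evaluate_patches(model, x, y)
    assert acc == 1.0


def test_training_is_deterministic():
    ds = toy_dataset(n_tm=20, n_other=20)
    split = make_split(ds, 10, 8, 2, seed=1)

    def run():
        model = build_model((16, 16), TINY_ARCH, seed=2)
        _, curves = train(model, ds, split, epochs_per_sample=1, seed=3)
        return curves

    c1, c2 = run(), run()
    assert c1.val_accuracy == c2.val_accuracy
    assert c1.train_loss == c2.train_loss


def test_training_requires_both_classes():
    ds = toy_dataset(n_tm=20, n_other=0)
    with pytest.warns(UserWarning):
        split = make_split(ds, 10, 10, 2, seed=0)
    model = build_model((16, 16), TINY_ARCH, seed=0)
    with pytest.raises(ValueError, match="only"):
        train(model, ds, split)


# ---- prediction -----------------------------------------------------------

class _ConstantModel:
    input_size = (16, 16)

    def __init__(self, p):
        self.p = p

    def predict_proba(self, x):
        return np.full(len(x), self.p)


def test_predict_tie_goes_to_tm():
    patches = [np.zeros((16, 16), np.float32)]
    assert predict(_ConstantModel(0.5), patches)[0][1] == TM_LABEL
    assert predict(_ConstantModel(0.499), patches)[0][1] == NON_TM_LABEL
    assert predict(PatchCNN(TINY_ARCH), []) == []


def test_predict_resizes_nonconforming_patches():
    model = PatchCNN(TINY_ARCH, seed=0)
    out = predict(model, [np.random.default_rng(0).random((40, 25))])
    assert len(out) == 1 and 0.0 <= out[0][0] <= 1.0
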