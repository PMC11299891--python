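"""Patch classification: datasets, augmentation, sample splits, training.

Two instances of the same small CNN run in the segmentation pipeline: a
"large-stage" network classifying whole detected objects and a "small-stage"
network classifying sub-objects found inside candidate membrane patches.
Both are trained here with the same accounting scheme: the corpus is divided
into fixed-size *samples*, a fixed fraction of every sample is pooled into a
validation set that never changes during the run, and after each sample's
training images are consumed the model records accuracy and loss on that
sample and on the pooled validation set.  The resulting four curves per run
are the overfitting diagnostic the training harness exports.

Class imbalance is addressed only by rotation augmentation of the (rarer)
membrane patches; there is no loss reweighting.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage import transform as sktransform

from .nn import DEFAULT_ARCH, PatchCNN, bce_with_logits
from .phantom import NON_TM_LABEL, TM_LABEL

__all__ = [
    "DEFAULT_ANGLES",
    "PatchDataset",
    "SampleSplit",
    "TrainingCurves",
    "ClassifierModel",
    "standardize_patch",
    "augment_rotations",
    "augment_dataset",
    "make_split",
    "build_model",
    "train",
    "continue_training",
    "evaluate_patches",
    "predict",
]

#: default augmentation angles (degrees); 0 keeps the original
DEFAULT_ANGLES = (0, 15, -15, 30, -30, 90, 180, 270)

ClassifierModel = PatchCNN


def standardize_patch(patch: np.ndarray, input_size: tuple[int, int] = (64, 64)) -> np.ndarray:
    """Aspect-preserving resize + zero-pad to ``input_size``, scaled to [0,1].

    Detected objects come as rectangles of arbitrary size; the network wants
    a fixed square.  The patch is scaled by the limiting edge, centred, and
    padded with zeros.
    """
    patch = np.asarray(patch, dtype=np.float64)
    if patch.ndim != 2:
        raise ValueError("patch must be a 2D grayscale image")
    if patch.max(initial=0.0) > 1.0:
        patch = patch / 255.0
    h, w = patch.shape
    th, tw = input_size
    s = min(th / h, tw / w)
    nh, nw = max(int(round(h * s)), 1), max(int(round(w * s)), 1)
    resized = sktransform.resize(
        patch, (nh, nw), order=1, mode="constant", anti_aliasing=(s < 1.0),
        preserve_range=True,
    )
    out = np.zeros((th, tw), dtype=np.float32)
    z0, x0 = (th - nh) // 2, (tw - nw) // 2
    out[z0 : z0 + nh, x0 : x0 + nw] = resized
    return out


def augment_rotations(patch: np.ndarray, angles) -> list[np.ndarray]:
    """One rotated copy per angle, same output shape, zeros beyond bounds.

    Angle 0 returns the input itself; multiples of 90 degrees on square
    patches use exact array rotations (no interpolation); other angles
    rotate about the centre with bilinear interpolation.
    """
    angles = list(angles)
    if not angles:
        raise ValueError("angle list must be nonempty")
    patch = np.asarray(patch)
    square = patch.shape[0] == patch.shape[1]
    out = []
    for angle in angles:
        a = angle % 360
        if a == 0:
            out.append(patch)
        elif a % 90 == 0 and (square or a == 180):
            out.append(np.rot90(patch, k=a // 90).copy())
        else:
            out.append(
                sktransform.rotate(
                    patch.astype(np.float64), angle, resize=False, order=1,
                    mode="constant", cval=0.0, preserve_range=True,
                ).astype(patch.dtype if patch.dtype == np.float32 else np.float64)
            )
    return out


@dataclass
class PatchDataset:
    """Fixed-size patches with binary labels and unique provenance ids."""

    patches: np.ndarray                      # (N, h, w) float32 in [0,1]
    labels: list[str] = field(default_factory=list)
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.patches = np.asarray(self.patches, dtype=np.float32)
        if self.patches.ndim != 3:
            raise ValueError("patches must be (N, h, w)")
        if not (len(self.patches) == len(self.labels) == len(self.ids)):
            raise ValueError("patches, labels and ids must align")
        if any(lb not in (TM_LABEL, NON_TM_LABEL) for lb in self.labels):
            raise ValueError("labels must be TM or non-TM")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("provenance ids must be unique")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def input_size(self) -> tuple[int, int]:
        return self.patches.shape[1:3]

    @property
    def y(self) -> np.ndarray:
        return np.array([1.0 if lb == TM_LABEL else 0.0 for lb in self.labels],
                        dtype=np.float32)

    def class_counts(self) -> dict[str, int]:
        return {
            TM_LABEL: sum(lb == TM_LABEL for lb in self.labels),
            NON_TM_LABEL: sum(lb == NON_TM_LABEL for lb in self.labels),
        }

    def index_of(self) -> dict[str, int]:
        return {pid: i for i, pid in enumerate(self.ids)}

    def take(self, ids: list[str]) -> tuple[np.ndarray, np.ndarray]:
        idx = self.index_of()
        sel = [idx[i] for i in ids]
        return self.patches[sel], self.y[sel]

    # -- directory interchange (one .npy per patch + labels.csv) ----------
    def save(self, patches_dir: str | Path, labels_csv: str | Path) -> None:
        patches_dir = Path(patches_dir)
        patches_dir.mkdir(parents=True, exist_ok=True)
        with open(labels_csv, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id", "label"])
            for pid, lb, patch in zip(self.ids, self.labels, self.patches):
                np.save(patches_dir / f"{pid}.npy", patch)
                writer.writerow([pid, lb])

    @classmethod
    def load(cls, patches_dir: str | Path, labels_csv: str | Path) -> "PatchDataset":
        patches_dir = Path(patches_dir)
        ids, labels, patches = [], [], []
        with open(labels_csv, newline="") as fh:
            for row in csv.DictReader(fh):
                ids.append(row["id"])
                labels.append(row["label"])
                patches.append(np.load(patches_dir / f"{row['id']}.npy"))
        return cls(np.stack(patches), labels, ids)


def augment_dataset(dataset: PatchDataset, angles=DEFAULT_ANGLES,
                    which: str = TM_LABEL) -> PatchDataset:
    """Replace every ``which``-labeled patch with one copy per angle.

    Grows the ``which`` class by exactly ``len(angles) - 1`` copies per
    original (angle 0 keeps the original); other patches pass through.
    """
    patches, labels, ids = [], [], []
    for patch, lb, pid in zip(dataset.patches, dataset.labels, dataset.ids):
        if lb == which:
            for angle, rot in zip(angles, augment_rotations(patch, angles)):
                patches.append(np.asarray(rot, dtype=np.float32))
                labels.append(lb)
                ids.append(pid if angle % 360 == 0 else f"{pid}-rot{angle}")
        else:
            patches.append(patch)
            labels.append(lb)
            ids.append(pid)
    return PatchDataset(np.stack(patches), labels, ids)


@dataclass
class SampleSplit:
    """Sample-wise training schedule with a fixed pooled validation set."""

    samples: list[list[str]]        # train ids, one list per sample
    val_ids: list[str]
    sample_size: int = 182
    train_per_sample: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        flat = set(self.train_ids)
        if flat & set(self.val_ids):
            raise ValueError("train and validation ids must be disjoint")
        expected = self.n_samples * (self.sample_size - self.train_per_sample)
        if len(self.val_ids) != expected:
            raise ValueError(
                f"validation pool has {len(self.val_ids)} ids, expected {expected}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def train_ids(self) -> list[str]:
        return [pid for sample in self.samples for pid in sample]


def make_split(
    dataset: PatchDataset,
    sample_size: int = 182,
    train_per_sample: int = 150,
    n_samples: int = 45,
    seed: int = 0,
) -> SampleSplit:
    """Partition a dataset into training samples and one pooled validation set.

    Each of ``n_samples`` samples contributes ``train_per_sample`` ids to
    training and ``sample_size - train_per_sample`` to a validation pool that
    is fixed for the whole run.  When the dataset is too small to fill every
    sample without reuse, training ids are drawn with replacement across
    samples (never within one) and a warning is emitted; validation ids are
    always unique and never appear in training.
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    if not (0 < train_per_sample <= sample_size) or n_samples < 1:
        raise ValueError("need 0 < train_per_sample <= sample_size and n_samples >= 1")
    rng = np.random.default_rng(seed)
    perm = [dataset.ids[i] for i in rng.permutation(len(dataset))]
    val_n = n_samples * (sample_size - train_per_sample)
    if val_n >= len(dataset):
        raise ValueError(
            f"dataset of {len(dataset)} cannot spare {val_n} validation images"
        )
    if val_n == 0:
        warnings.warn("empty validation pool: train_per_sample == sample_size")
    val_ids = perm[:val_n]
    pool = perm[val_n:]
    need = n_samples * train_per_sample
    if len(pool) >= need:
        samples = [pool[i * train_per_sample : (i + 1) * train_per_sample]
                   for i in range(n_samples)]
    else:
        if len(pool) < train_per_sample:
            raise ValueError(
                f"training pool of {len(pool)} cannot fill a sample of {train_per_sample}"
            )
        warnings.warn(
            f"training pool of {len(pool)} ids reused across samples to fill "
            f"{n_samples} samples of {train_per_sample}"
        )
        samples = [
            [pool[j] for j in rng.choice(len(pool), train_per_sample, replace=False)]
            for _ in range(n_samples)
        ]
    return SampleSplit(samples, val_ids, sample_size, train_per_sample, seed)


@dataclass
class TrainingCurves:
    """Per-sample training/validation accuracy and loss series."""

    train_accuracy: list[float] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.train_accuracy)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["sample", "train_acc", "train_loss", "val_acc", "val_loss"])
            for i in range(len(self)):
                writer.writerow([
                    i + 1, self.train_accuracy[i], self.train_loss[i],
                    self.val_accuracy[i], self.val_loss[i],
                ])

    def plot(self, path: str | Path) -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        x = np.arange(1, len(self) + 1)
        fig, (ax_a, ax_l) = plt.subplots(1, 2, figsize=(9, 3.2))
        ax_a.plot(x, self.train_accuracy, label="training")
        ax_a.plot(x, self.val_accuracy, label="validation")
        ax_a.set(xlabel="sample", ylabel="accuracy", ylim=(0, 1.02))
        ax_a.legend()
        ax_l.plot(x, self.train_loss, label="training")
        ax_l.plot(x, self.val_loss, label="validation")
        ax_l.set(xlabel="sample", ylabel="loss (BCE)")
        ax_l.legend()
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def build_model(input_size: tuple[int, int] = (64, 64), arch_config: dict | None = None,
                seed: int = 0) -> ClassifierModel:
    """Construct the default patch CNN (seeded, untrained)."""
    arch = dict(DEFAULT_ARCH if arch_config is None else arch_config)
    arch["input_size"] = list(input_size)
    return PatchCNN(arch, seed=seed)


def evaluate_patches(model: ClassifierModel, x: np.ndarray, y: np.ndarray,
                     cutoff: float = 0.5) -> tuple[float, float]:
    """(accuracy, BCE loss) of the model on patches ``x`` with targets ``y``."""
    if len(x) == 0:
        return float("nan"), float("nan")
    probs = model.predict_proba(x)
    acc = float(np.mean((probs >= cutoff) == (np.asarray(y) > 0.5)))
    logits = np.log(np.clip(probs, 1e-12, 1 - 1e-12) /
                    np.clip(1 - probs, 1e-12, 1.0))
    return acc, bce_with_logits(logits, y)


def _fit_ids(model, dataset, ids, rng, lr, batch_size) -> None:
    x, y = dataset.take(ids)
    order = rng.permutation(len(ids))
    for i in range(0, len(order), batch_size):
        sel = order[i : i + batch_size]
        model.train_batch(x[sel], y[sel], lr=lr)


def train(
    model: ClassifierModel,
    dataset: PatchDataset,
    split: SampleSplit,
    epochs_per_sample: int = 1,
    seed: int = 0,
    lr: float = 1e-3,
    batch_size: int = 32,
) -> tuple[ClassifierModel, TrainingCurves]:
    """Train through the split's samples in order, recording curves.

    After each sample's training images are consumed the model is scored on
    that sample (training accuracy/loss) and on the fixed pooled validation
    set.  Deterministic for fixed seeds under single-threaded execution.

    Raises
    ------
    ValueError
        If the training ids do not contain both label classes.
    """
    idx = dataset.index_of()
    missing = [pid for pid in split.train_ids + split.val_ids if pid not in idx]
    if missing:
        raise ValueError(f"split references unknown ids, e.g. {missing[:3]}")
    train_labels = {dataset.labels[idx[pid]] for pid in split.train_ids}
    if train_labels != {TM_LABEL, NON_TM_LABEL}:
        raise ValueError(f"training data contains only {sorted(train_labels)}")

    rng = np.random.default_rng(seed)
    val_x, val_y = dataset.take(split.val_ids)
    curves = TrainingCurves()
    for sample_ids in split.samples:
        for _ in range(epochs_per_sample):
            _fit_ids(model, dataset, sample_ids, rng, lr, batch_size)
        sx, sy = dataset.take(sample_ids)
        t_acc, t_loss = evaluate_patches(model, sx, sy)
        v_acc, v_loss = evaluate_patches(model, val_x, val_y)
        curves.train_accuracy.append(t_acc)
        curves.train_loss.append(t_loss)
        curves.val_accuracy.append(v_acc)
        curves.val_loss.append(v_loss)
    return model, curves


def continue_training(
    model: ClassifierModel,
    dataset: PatchDataset,
    ids: list[str],
    max_epochs: int = 25,
    patience: int = 3,
    seed: int = 0,
    lr: float = 1e-3,
    batch_size: int = 32,
) -> float:
    """Keep training on ``ids`` until their accuracy plateaus (overfit regime).

    Returns the final accuracy on the pool.  Stops early once accuracy
    reaches 1.0 or fails to improve for ``patience`` consecutive epochs.
    """
    rng = np.random.default_rng(seed)
    x, y = dataset.take(ids)
    best, stale = -1.0, 0
    acc, _ = evaluate_patches(model, x, y)
    for _ in range(max_epochs):
        if acc >= 1.0:
            break
        _fit_ids(model, dataset, ids, rng, lr, batch_size)
        acc, _ = evaluate_patches(model, x, y)
        if acc > best + 1e-12:
            best, stale = acc, 0
        else:
            stale += 1
            if stale >= patience:
                break
    return acc


def predict(model: ClassifierModel, patches, cutoff: float = 0.5):
    """TM probabilities and labels at ``cutoff`` (a tie goes to TM).

    Patches not matching the model's input size are standardized first.
    """
    if len(patches) == 0:
        return []
    std = [
        p if tuple(np.shape(p)) == model.input_size else standardize_patch(p, model.input_size)
        for p in patches
    ]
    probs = model.predict_proba(np.stack(std).astype(np.float32))
    return [(float(p), TM_LABEL if p >= cutoff else NON_TM_LABEL) for p in probs]
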