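"""Standard desk-scale experiments on the synthetic phantom.

These harnesses reproduce, at a size a single CPU handles in minutes, the
measurements a full clinical study would make on real volumes: object-level
identification accuracy of the complete two-stage pipeline on held-out
volumes, and the per-stage training/validation accuracy curves of the patch
classifiers.  All problem sizes live here, in one place:

* phantom geometry: the CI preset, 64 slices of 160 (depth) x 128 (width);
* pipeline accuracy: classifiers trained on 4 phantom volumes, scored on
  every object detected across 4 held-out volumes;
* classifier curves: a coarse-stage corpus from 6 phantom volumes with
  rotation-augmented membrane patches, split into samples of 91 images of
  which 75 train (the same ~18% pooled holdout ratio as a 150-of-182
  sample), trained sample by sample and then to plateau.

Every random choice derives from one base seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import classifier as clf
from .evaluate import EvalReport, dice, object_accuracy
from .objdet import CI_LARGE_STAGE, CI_SMALL_STAGE, DetectionParams
from .phantom import PhantomConfig, generate_phantom
from .pipeline import (
    CNNObjectClassifier,
    PipelineConfig,
    build_patch_corpora,
    segment_volume,
)

__all__ = [
    "ExperimentSizes",
    "build_stage_corpora",
    "train_stage_model",
    "classifier_curves_experiment",
    "pipeline_accuracy_experiment",
]

# sample accounting at desk scale: same holdout ratio as 150-of-182
CI_SAMPLE_SIZE = 91
CI_TRAIN_PER_SAMPLE = 75


@dataclass
class ExperimentSizes:
    """Problem sizes for the desk-scale experiments."""

    n_train_volumes: int = 4
    n_eval_volumes: int = 4
    n_corpus_volumes: int = 6
    sample_size: int = CI_SAMPLE_SIZE
    train_per_sample: int = CI_TRAIN_PER_SAMPLE
    epochs_per_sample: int = 2
    plateau_epochs: int = 25
    large_params: DetectionParams = field(default_factory=lambda: CI_LARGE_STAGE)
    small_params: DetectionParams = field(default_factory=lambda: CI_SMALL_STAGE)
    patch_pad: int = 6


def _dataset_from_items(items) -> clf.PatchDataset:
    patches = np.stack([it[0] for it in items])
    return clf.PatchDataset(patches, [it[1] for it in items], [it[2] for it in items])


def build_stage_corpora(
    phantom_seeds, sizes: ExperimentSizes | None = None
) -> tuple[clf.PatchDataset, clf.PatchDataset]:
    """Generate phantoms and auto-label their detected objects into the
    coarse- and fine-stage patch corpora."""
    sizes = sizes or ExperimentSizes()
    large_items, small_items = [], []
    for seed in phantom_seeds:
        vol, labels = generate_phantom(PhantomConfig.ci(seed=seed))
        li, si = build_patch_corpora(
            vol, labels, sizes.large_params, sizes.small_params,
            patch_pad=sizes.patch_pad, id_prefix=f"p{seed}",
        )
        large_items += li
        small_items += si
    return _dataset_from_items(large_items), _dataset_from_items(small_items)


def _auto_samples(n_items: int, sizes: ExperimentSizes) -> int:
    """As many samples as the corpus supports, at least one."""
    return max(n_items // sizes.sample_size, 1)


def train_stage_model(
    dataset: clf.PatchDataset,
    seed: int,
    sizes: ExperimentSizes | None = None,
    augment: bool = True,
    to_plateau: bool = True,
):
    """Train one stage classifier with the standard accounting; returns
    ``(model, curves, split, dataset_used)``."""
    sizes = sizes or ExperimentSizes()
    if augment:
        dataset = clf.augment_dataset(dataset)
    split = clf.make_split(
        dataset,
        sample_size=sizes.sample_size,
        train_per_sample=sizes.train_per_sample,
        n_samples=_auto_samples(len(dataset), sizes),
        seed=seed,
    )
    model = clf.build_model(seed=seed)
    model, curves = clf.train(
        model, dataset, split,
        epochs_per_sample=sizes.epochs_per_sample, seed=seed,
    )
    if to_plateau:
        clf.continue_training(
            model, dataset, split.train_ids,
            max_epochs=sizes.plateau_epochs, seed=seed + 1,
        )
    return model, curves, split, dataset


def classifier_curves_experiment(seed: int, sizes: ExperimentSizes | None = None) -> dict:
    """Coarse-stage training diagnostics (validation and training accuracy).

    Builds the corpus from ``n_corpus_volumes`` phantoms, augments the
    membrane patches, trains sample by sample recording curves, then keeps
    training the pool to its plateau.  Returns final accuracies in percent.
    """
    sizes = sizes or ExperimentSizes()
    base = int(seed) % 2**20
    phantom_seeds = [base * 100 + k for k in range(1, sizes.n_corpus_volumes + 1)]
    large, _ = build_stage_corpora(phantom_seeds, sizes)
    model, curves, split, used = train_stage_model(
        large, seed=base, sizes=sizes, augment=True, to_plateau=False,
    )
    val_x, val_y = used.take(split.val_ids)
    val_acc, val_loss = clf.evaluate_patches(model, val_x, val_y)
    train_acc = clf.continue_training(
        model, used, split.train_ids, max_epochs=sizes.plateau_epochs, seed=base + 1,
    )
    final_val_acc, _ = clf.evaluate_patches(model, val_x, val_y)
    return {
        "validation_accuracy_pct": 100.0 * val_acc,
        "validation_accuracy_after_plateau_pct": 100.0 * final_val_acc,
        "training_pool_accuracy_pct": 100.0 * train_acc,
        "validation_loss": val_loss,
        "n_patches": len(used),
        "n_validation": len(split.val_ids),
        "n_samples": split.n_samples,
        "curves": curves,
    }


def pipeline_accuracy_experiment(seed: int, sizes: ExperimentSizes | None = None) -> dict:
    """Full two-stage pipeline accuracy on held-out phantom volumes.

    Trains both stage classifiers on auto-labeled corpora from
    ``n_train_volumes`` phantoms, segments ``n_eval_volumes`` unseen
    phantoms, and scores every detected object's final label against the
    ground-truth label volumes.
    """
    sizes = sizes or ExperimentSizes()
    base = int(seed) % 2**20
    train_seeds = [base * 100 + k for k in range(1, sizes.n_train_volumes + 1)]
    eval_seeds = [base * 100 + 1000 + k for k in range(1, sizes.n_eval_volumes + 1)]

    large_ds, small_ds = build_stage_corpora(train_seeds, sizes)
    large_model, _, _, _ = train_stage_model(large_ds, seed=base, sizes=sizes, augment=True)
    # the fine-stage corpus is majority-membrane, so augmenting the TM class
    # would deepen the imbalance rather than correct it
    small_sizes = ExperimentSizes(
        **{**sizes.__dict__, "sample_size": 40, "train_per_sample": 33}
    )
    small_model, _, _, _ = train_stage_model(
        small_ds, seed=base + 7, sizes=small_sizes, augment=False,
    )

    config = PipelineConfig(
        large_params=sizes.large_params,
        small_params=sizes.small_params,
        large_classifier=CNNObjectClassifier(large_model),
        small_classifier=CNNObjectClassifier(small_model),
        patch_pad=sizes.patch_pad,
    )

    reports: list[EvalReport] = []
    dices: list[float] = []
    n_objects = n_correct = 0
    for es in eval_seeds:
        vol, labels = generate_phantom(PhantomConfig.ci(seed=es))
        result = segment_volume(vol, config)
        objs = [rec.obj for rec in result.all_objects()]
        report = object_accuracy(objs, labels)
        report.volume_dice = dice(result.tm_masks, labels.tm_mask())
        reports.append(report)
        dices.append(report.volume_dice)
        n_objects += report.n_objects
        n_correct += report.n_correct
    return {
        "object_accuracy_pct": 100.0 * n_correct / n_objects,
        "n_objects": n_objects,
        "n_correct": n_correct,
        "mean_volume_dice": float(np.mean(dices)),
        "per_volume": [r.to_json() for r in reports],
        "config": config,
    }
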