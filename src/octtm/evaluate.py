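"""Evaluation metrics: object-level identification accuracy and mask overlap.

Object accuracy mirrors the manual audit a human reviewer would perform on
a segmented stack — every detected object's final TM/non-TM call is checked
against ground truth — automated here via the phantom's label volume.  Dice
is the standard overlap statistic for the voxel masks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import LabelVolume, TM_LABEL, auto_label_object

__all__ = ["EvalReport", "object_accuracy", "dice"]


@dataclass
class EvalReport:
    """Object-level confusion counts plus optional volume overlap."""

    n_objects: int
    n_correct: int
    tm_true_positive: int
    tm_false_positive: int
    tm_false_negative: int
    tm_true_negative: int
    volume_dice: float | None = None

    @property
    def object_accuracy(self) -> float:
        return self.n_correct / self.n_objects

    @property
    def tm_accuracy(self) -> float:
        """Accuracy restricted to objects whose true class is TM."""
        n_tm = self.tm_true_positive + self.tm_false_negative
        return self.tm_true_positive / n_tm if n_tm else float("nan")

    @property
    def non_tm_accuracy(self) -> float:
        n = self.tm_true_negative + self.tm_false_positive
        return self.tm_true_negative / n if n else float("nan")

    def to_json(self) -> dict:
        return {
            "n_objects": self.n_objects,
            "n_correct": self.n_correct,
            "object_accuracy": self.object_accuracy,
            "tm_accuracy": self.tm_accuracy,
            "non_tm_accuracy": self.non_tm_accuracy,
            "tm_true_positive": self.tm_true_positive,
            "tm_false_positive": self.tm_false_positive,
            "tm_false_negative": self.tm_false_negative,
            "tm_true_negative": self.tm_true_negative,
            "volume_dice": self.volume_dice,
        }


def object_accuracy(
    predicted, truth: LabelVolume, tm_overlap_fraction: float = 0.5
) -> EvalReport:
    """Score predicted object labels against the ground-truth label volume.

    ``predicted`` is any iterable of :class:`~octtm.objdet.DetectedObject`
    with their ``label`` field set; each object's true class comes from
    :func:`~octtm.phantom.auto_label_object`.  Order-invariant.

    Raises
    ------
    ValueError
        If the object list is empty (accuracy would be undefined).
    """
    objects = list(predicted)
    if not objects:
        raise ValueError("cannot score an empty object list")
    tp = fp = fn = tn = 0
    for obj in objects:
        if obj.label is None:
            raise ValueError("every object needs a predicted label")
        true = auto_label_object(obj, truth, tm_overlap_fraction)
        if true == TM_LABEL:
            if obj.label == TM_LABEL:
                tp += 1
            else:
                fn += 1
        else:
            if obj.label == TM_LABEL:
                fp += 1
            else:
                tn += 1
    return EvalReport(len(objects), tp + tn, tp, fp, fn, tn)


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice coefficient 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        return 1.0
    return 2.0 * int(np.logical_and(a, b).sum()) / total
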