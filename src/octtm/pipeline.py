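"""Two-stage segmentation pipeline and 3D reconstruction.

Per slice the pipeline runs: coarse detection -> CNN classification of every
detected object -> for each object accepted as membrane, fine detection
inside its (padded) patch -> CNN classification of the sub-objects -> the
slice mask is the union of accepted sub-object masks mapped back to slice
coordinates, restricted to the pixels that are actually above the fine
threshold (so the blur halo around an object does not leak into the mask).
An object rejected at the coarse stage contributes nothing
downstream.  Slices are processed independently; the volume mask times the
input volume is the reconstructed membrane-only stack.

The classifier slot is pluggable: a trained CNN adapter for real runs, or a
ground-truth oracle (the phantom's auto-labeler) to isolate detection-stage
errors from classification errors in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classifier import ClassifierModel, standardize_patch
from .objdet import (
    DetectedObject,
    DetectionParams,
    binarize,
    detect_objects,
    extract_patch,
)
from .phantom import LabelVolume, NON_TM_LABEL, TM_LABEL, auto_label_object
from .volume import BScanVolume

__all__ = [
    "CNNObjectClassifier",
    "OracleObjectClassifier",
    "PipelineConfig",
    "ObjectRecord",
    "SegmentationResult",
    "segment_slice",
    "segment_volume",
    "reconstruct",
    "summed_voxel_projection",
    "build_patch_corpora",
    "rle_encode",
    "rle_decode",
]


class CNNObjectClassifier:
    """Classify detected objects with a trained patch CNN.

    Each object's padded bounding box is cropped from the original slice,
    standardized to the network input size, and scored.
    """

    def __init__(self, model: ClassifierModel, cutoff: float = 0.5):
        self.model = model
        self.cutoff = cutoff

    def classify(self, slice_img: np.ndarray, objects: list[DetectedObject],
                 pad: int) -> list[tuple[float, str]]:
        if not objects:
            return []
        patches = [
            standardize_patch(extract_patch(slice_img, obj, pad), self.model.input_size)
            for obj in objects
        ]
        probs = self.model.predict_proba(np.stack(patches))
        return [(float(p), TM_LABEL if p >= self.cutoff else NON_TM_LABEL) for p in probs]


class OracleObjectClassifier:
    """Ground-truth classifier backed by a phantom label volume.

    Substituting it for a trained CNN makes every classification decision
    perfect, so any end-to-end segmentation error left is attributable to
    the detection stages alone.
    """

    def __init__(self, labels: LabelVolume, tm_overlap_fraction: float = 0.5):
        self.labels = labels
        self.tm_overlap_fraction = tm_overlap_fraction

    def classify(self, slice_img: np.ndarray, objects: list[DetectedObject],
                 pad: int) -> list[tuple[float, str]]:
        out = []
        for obj in objects:
            label = auto_label_object(obj, self.labels, self.tm_overlap_fraction)
            out.append((1.0 if label == TM_LABEL else 0.0, label))
        return out


@dataclass
class PipelineConfig:
    """Everything the two-stage pipeline needs for one run."""

    large_params: DetectionParams
    small_params: DetectionParams
    large_classifier: CNNObjectClassifier | OracleObjectClassifier
    small_classifier: CNNObjectClassifier | OracleObjectClassifier
    patch_pad: int = 6
    probability_cutoff: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.probability_cutoff < 1.0):
            raise ValueError("probability_cutoff must lie in (0, 1)")
        if self.patch_pad < 0:
            raise ValueError("patch_pad must be >= 0")
        sizes = {
            c.model.input_size
            for c in (self.large_classifier, self.small_classifier)
            if isinstance(c, CNNObjectClassifier)
        }
        if len(sizes) > 1:
            raise ValueError("large and small models must share input_size")
        for c in (self.large_classifier, self.small_classifier):
            if isinstance(c, CNNObjectClassifier):
                c.cutoff = self.probability_cutoff


@dataclass
class ObjectRecord:
    """One detected object with its stage, score and final label."""

    stage: str                   # "large" | "small"
    obj: DetectedObject

    def to_json(self) -> dict:
        x, z, w, h = self.obj.bbox
        return {
            "stage": self.stage,
            "slice": self.obj.slice_index,
            "bbox": [x, z, w, h],
            "area": self.obj.area,
            "probability": self.obj.probability,
            "label": self.obj.label,
            "mask_rle": rle_encode(self.obj.mask),
        }

    @classmethod
    def from_json(cls, data: dict) -> "ObjectRecord":
        x, z, w, h = data["bbox"]
        mask = rle_decode(data["mask_rle"], (h, w))
        obj = DetectedObject(data["slice"], (x, z, w, h), mask, data["area"],
                             data["label"], data["probability"])
        return cls(data["stage"], obj)


@dataclass
class SegmentationResult:
    """Per-slice membrane masks, the masked volume, and all object records."""

    tm_masks: np.ndarray                      # (n_slices, depth, width) bool
    masked_volume: BScanVolume
    per_slice_objects: list[list[ObjectRecord]] = field(default_factory=list)

    def all_objects(self) -> list[ObjectRecord]:
        return [rec for recs in self.per_slice_objects for rec in recs]

    def records_json(self) -> list[dict]:
        return [rec.to_json() for rec in self.all_objects()]


def rle_encode(mask: np.ndarray) -> list[int]:
    """Row-major run lengths, alternating zero/one runs, starting with zeros."""
    flat = np.asarray(mask, dtype=bool).ravel()
    if flat.size == 0:
        return []
    changes = np.flatnonzero(np.diff(flat)) + 1
    bounds = np.concatenate(([0], changes, [flat.size]))
    runs = np.diff(bounds).tolist()
    if flat[0]:
        runs = [0] + runs
    return [int(r) for r in runs]


def rle_decode(runs: list[int], shape: tuple[int, int]) -> np.ndarray:
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    pos, value = 0, False
    for run in runs:
        if value:
            flat[pos : pos + run] = True
        pos += run
        value = not value
    return flat.reshape(shape)


def _patch_origin(slice_shape: tuple[int, int], obj: DetectedObject,
                  pad: int) -> tuple[int, int]:
    depth, width = slice_shape
    x, z, _, _ = obj.bbox
    return max(x - pad, 0), max(z - pad, 0)


def segment_slice(
    slice_img: np.ndarray, config: PipelineConfig, slice_index: int = 0
) -> tuple[np.ndarray, list[ObjectRecord]]:
    """Segment one B-scan; returns (full-extent mask, object records)."""
    slice_img = np.asarray(slice_img)
    mask = np.zeros(slice_img.shape, dtype=bool)
    records: list[ObjectRecord] = []

    large_objs = detect_objects(slice_img, config.large_params, slice_index)
    if not large_objs:
        return mask, records
    scored = config.large_classifier.classify(slice_img, large_objs, config.patch_pad)
    for obj, (prob, label) in zip(large_objs, scored):
        obj.probability, obj.label = prob, label
        records.append(ObjectRecord("large", obj))

    for obj in large_objs:
        if obj.label != TM_LABEL:
            continue  # strict gating: rejected coarse objects go no further
        patch = extract_patch(slice_img, obj, config.patch_pad)
        x0, z0 = _patch_origin(slice_img.shape, obj, config.patch_pad)
        small_objs = [
            s.offset(x0, z0)
            for s in detect_objects(patch, config.small_params, slice_index)
        ]
        if not small_objs:
            continue
        small_scored = config.small_classifier.classify(slice_img, small_objs,
                                                        config.patch_pad)
        for sobj, (prob, label) in zip(small_objs, small_scored):
            sobj.probability, sobj.label = prob, label
            records.append(ObjectRecord("small", sobj))
            if label == TM_LABEL:
                sobj.paint(mask)
    # the accepted-object footprint is a stencil: keep only the bright
    # pixels inside it, not the merging halo the blur step added
    if mask.any():
        mask &= binarize(slice_img, config.small_params.threshold)
    return mask, records


def segment_volume(volume: BScanVolume, config: PipelineConfig) -> SegmentationResult:
    """Apply :func:`segment_slice` to every slice independently."""
    masks = np.zeros(volume.voxels.shape, dtype=bool)
    per_slice: list[list[ObjectRecord]] = []
    for y in range(volume.n_slices):
        mask, records = segment_slice(volume.slice(y), config, y)
        masks[y] = mask
        per_slice.append(records)
    return SegmentationResult(masks, reconstruct(volume, masks), per_slice)


def reconstruct(volume: BScanVolume, tm_masks: np.ndarray) -> BScanVolume:
    """Voxelwise product of the volume with the masks (dtype preserved)."""
    tm_masks = np.asarray(tm_masks, dtype=bool)
    if tm_masks.shape != volume.voxels.shape:
        raise ValueError(
            f"mask shape {tm_masks.shape} != volume shape {volume.voxels.shape}"
        )
    return BScanVolume(np.where(tm_masks, volume.voxels, 0).astype(volume.voxels.dtype),
                       volume.extent_mm)


def summed_voxel_projection(volume: BScanVolume) -> np.ndarray:
    """Sum intensities along depth and rescale to an 8-bit (Y, X) image."""
    sums = volume.voxels.astype(np.float64).sum(axis=1)
    peak = sums.max()
    if peak > 0:
        sums = sums * (255.0 / peak)
    return sums.round().astype(np.uint8)


def build_patch_corpora(
    volume: BScanVolume,
    labels: LabelVolume,
    large_params: DetectionParams,
    small_params: DetectionParams,
    patch_pad: int = 6,
    input_size: tuple[int, int] = (64, 64),
    tm_overlap_fraction: float = 0.5,
    id_prefix: str = "v0",
):
    """Detect objects on a labeled phantom and auto-label them into corpora.

    Runs the coarse stage on every slice and the fine stage inside every
    coarse object whose ground-truth label is TM — exactly the population of
    objects each classifier will face at segmentation time.  Returns
    ``(large_items, small_items)`` where each item is
    ``(standardized patch, label, provenance id)``.
    """
    large_items, small_items = [], []
    for y in range(volume.n_slices):
        slice_img = volume.slice(y)
        for i, obj in enumerate(detect_objects(slice_img, large_params, y)):
            label = auto_label_object(obj, labels, tm_overlap_fraction)
            patch = standardize_patch(extract_patch(slice_img, obj, patch_pad), input_size)
            large_items.append((patch, label, f"{id_prefix}-y{y}-L{i}"))
            if label != TM_LABEL:
                continue
            raw_patch = extract_patch(slice_img, obj, patch_pad)
            x0, z0 = _patch_origin(slice_img.shape, obj, patch_pad)
            for j, sobj in enumerate(detect_objects(raw_patch, small_params, y)):
                sobj = sobj.offset(x0, z0)
                slabel = auto_label_object(sobj, labels, tm_overlap_fraction)
                spatch = standardize_patch(extract_patch(slice_img, sobj, patch_pad),
                                           input_size)
                small_items.append((spatch, slabel, f"{id_prefix}-y{y}-L{i}-S{j}"))
    return large_items, small_items
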