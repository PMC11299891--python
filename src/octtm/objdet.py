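"""Classical object detection on B-scans: threshold, blur, size filtering.

A detection stage turns one grayscale B-scan into a list of "objects" —
connected aggregations of above-threshold pixels surviving an area filter.
The same three-parameter machinery runs twice in the segmentation pipeline:
a coarse pass over whole slices (high threshold, wide blur, large minimum
area) and a fine pass inside candidate membrane patches (lower threshold,
narrow blur).

The blur step operates on the *binary* image: a box blur followed by
re-binarization at any-nonzero, which is exactly a morphological dilation
with a (2r+1)x(2r+1) square.  It exists purely to merge fragments closer
than 2r pixels into one object; object areas and masks are measured on the
blurred (dilated) binary image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

__all__ = [
    "DetectionParams",
    "DetectedObject",
    "binarize",
    "smooth",
    "find_objects",
    "detect_objects",
    "extract_patch",
    "LARGE_STAGE_DEFAULTS",
    "SMALL_STAGE_DEFAULTS",
    "CI_LARGE_STAGE",
    "CI_SMALL_STAGE",
]


@dataclass(frozen=True)
class DetectionParams:
    """Parameters of one detection stage.

    threshold: pixels strictly above this 0-255 intensity count as bright.
    blur: merging radius in px; fragments within 2*blur px join into one object.
    min_area / max_area: inclusive area band (px^2) an object must fall in.
    """

    threshold: int
    blur: int
    min_area: int
    max_area: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.threshold <= 255):
            raise ValueError(f"threshold must be in 0-255, got {self.threshold}")
        if self.blur < 0:
            raise ValueError("blur must be >= 0")
        if self.min_area < 1:
            raise ValueError("min_area must be >= 1")
        if self.max_area is not None and self.max_area <= self.min_area:
            raise ValueError("max_area must exceed min_area")


# Full-geometry defaults (417x669 slices).  The CI presets are calibrated for
# the small phantom geometry (160x128 slices); at that scale the fine stage
# needs a lower area floor so sub-patch artifact fragments clear the filter.
LARGE_STAGE_DEFAULTS = DetectionParams(threshold=40, blur=3, min_area=500)
SMALL_STAGE_DEFAULTS = DetectionParams(threshold=25, blur=1, min_area=550)
CI_LARGE_STAGE = DetectionParams(threshold=40, blur=2, min_area=120)
CI_SMALL_STAGE = DetectionParams(threshold=25, blur=1, min_area=60)


@dataclass
class DetectedObject:
    """One connected bright region on one slice.

    ``bbox`` is ``(corner_x, corner_z, width, height)`` in pixel units,
    half-open, in the coordinate frame of the image the object was detected
    on.  ``mask`` is the object's binary footprint cropped to the bbox and
    ``area`` its true-pixel count.
    """

    slice_index: int
    bbox: tuple[int, int, int, int]
    mask: np.ndarray
    area: int
    label: str | None = None
    probability: float | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        x, z, w, h = self.bbox
        if self.mask.shape != (h, w):
            raise ValueError(f"mask shape {self.mask.shape} != bbox extent ({h}, {w})")
        if self.area != int(self.mask.sum()):
            raise ValueError("area must equal the mask's true-pixel count")

    def offset(self, dx: int, dz: int) -> "DetectedObject":
        """Return a copy translated by (dx, dz) — e.g. patch -> slice coords."""
        x, z, w, h = self.bbox
        return DetectedObject(
            self.slice_index, (x + dx, z + dz, w, h), self.mask, self.area,
            self.label, self.probability,
        )

    def paint(self, canvas: np.ndarray) -> None:
        """OR the object's mask into a full-extent binary canvas."""
        x, z, w, h = self.bbox
        canvas[z : z + h, x : x + w] |= self.mask


def binarize(image: np.ndarray, threshold: int) -> np.ndarray:
    """White (True) where intensity strictly exceeds ``threshold``."""
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("image must be 2D")
    return image > threshold


def smooth(binary: np.ndarray, blur: int) -> np.ndarray:
    """Merge fragments within 2*blur px; ``blur=0`` is the identity."""
    binary = np.asarray(binary, dtype=bool)
    if blur == 0:
        return binary
    structure = np.ones((2 * blur + 1, 2 * blur + 1), dtype=bool)
    return ndimage.binary_dilation(binary, structure=structure)


def find_objects(
    binary: np.ndarray, params: DetectionParams, slice_index: int = 0
) -> list[DetectedObject]:
    """Connected components (8-connectivity) of ``binary`` inside the area band.

    Objects come back sorted by descending area, ties broken by
    (corner_z, corner_x) for reproducibility.
    """
    binary = np.asarray(binary, dtype=bool)
    labeled, n_comp = measure.label(binary, connectivity=2, return_num=True)
    objects: list[DetectedObject] = []
    for region in measure.regionprops(labeled):
        area = int(region.area)
        if area < params.min_area:
            continue
        if params.max_area is not None and area > params.max_area:
            continue
        z0, x0, z1, x1 = region.bbox
        mask = region.image
        objects.append(
            DetectedObject(slice_index, (x0, z0, x1 - x0, z1 - z0), mask, area)
        )
    objects.sort(key=lambda o: (-o.area, o.bbox[1], o.bbox[0]))
    return objects


def detect_objects(
    slice_img: np.ndarray, params: DetectionParams, slice_index: int = 0
) -> list[DetectedObject]:
    """Run one full detection stage: binarize -> smooth -> find_objects."""
    return find_objects(smooth(binarize(slice_img, params.threshold), params.blur),
                        params, slice_index)


def extract_patch(slice_img: np.ndarray, obj: DetectedObject, pad: int = 0) -> np.ndarray:
    """Crop the object's bbox, expanded by ``pad`` px and clamped to bounds,
    from the ORIGINAL (unthresholded) slice."""
    slice_img = np.asarray(slice_img)
    depth, width = slice_img.shape
    x, z, w, h = obj.bbox
    if x < 0 or z < 0 or x + w > width or z + h > depth:
        raise ValueError(f"bbox {obj.bbox} outside slice extent ({depth}, {width})")
    x0, z0 = max(x - pad, 0), max(z - pad, 0)
    x1, z1 = min(x + w + pad, width), min(z + h + pad, depth)
    return slice_img[z0:z1, x0:x1]
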