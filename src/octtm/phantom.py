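"""Synthetic middle-ear OCT phantom with voxel-level ground truth.

The phantom emulates the structures a B-scan of the middle ear actually
shows, so every downstream stage (detection, classification, reconstruction)
can be trained and scored without clinical data:

* the tympanic membrane (TM): a thin, smoothly curved bright band whose depth
  follows a quadratic profile in X and drifts slowly across slices (Y);
* deeper anatomy: ossicle/cochlea-like ellipsoidal blobs strictly below the
  membrane, some placed within a few pixels of it so that coarse detection
  merges them with the TM while fine detection separates them;
* fixed-pattern noise: bright horizontal lines at constant depth rows near
  the top of every slice (internal device reflections);
* saturation artifacts: bright vertical full-depth lines persisting over a
  run of consecutive slices (detector saturation at strong reflectors);
* multiplicative log-normal speckle and additive Gaussian background noise.

Every voxel carries exactly one ground-truth label with the precedence
TM > deep structure > artifact > background.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .volume import BScanVolume

__all__ = [
    "BACKGROUND",
    "TM",
    "DEEP_STRUCTURE",
    "ARTIFACT",
    "TM_LABEL",
    "NON_TM_LABEL",
    "MembraneConfig",
    "DeepStructureConfig",
    "FixedPatternConfig",
    "SaturationConfig",
    "PhantomConfig",
    "LabelVolume",
    "generate_phantom",
    "auto_label_object",
]

# label codes, in increasing storage value; semantic precedence is
# TM > DEEP_STRUCTURE > ARTIFACT > BACKGROUND
BACKGROUND = 0
TM = 1
DEEP_STRUCTURE = 2
ARTIFACT = 3

# object-level class names used across the package
TM_LABEL = "TM"
NON_TM_LABEL = "non-TM"


@dataclass
class MembraneConfig:
    """Curved bright band model of the tympanic membrane.

    Depth profile: ``z(x, y) = apex(y) + curvature_frac * depth * u(x)^2``
    with ``u`` the normalized lateral offset from the apex column, and the
    apex depth drifting linearly by ``drift_frac * depth`` across the stack.
    """

    apex_depth_frac: float = 0.35   # apex depth as fraction of depth_px
    curvature_frac: float = 0.15    # extra depth at the lateral edges
    drift_frac: float = 0.10        # apex depth drift across the whole stack
    thickness_px: int = 9
    intensity_mean: float = 200.0
    intensity_sd: float = 15.0
    x_margin_frac: float = 0.10     # membrane spans x in [margin, 1 - margin]


@dataclass
class DeepStructureConfig:
    """Ellipsoidal bright blobs beneath the membrane."""

    count: int = 10
    radius_x_px: tuple[int, int] = (4, 9)
    radius_y_slices: tuple[int, int] = (3, 7)
    radius_z_px: tuple[int, int] = (4, 9)
    gap_px: tuple[int, int] = (3, 10)   # clearance below the membrane band
    intensity: tuple[float, float] = (120.0, 190.0)


@dataclass
class FixedPatternConfig:
    """Horizontal line artifacts at fixed depth rows near the image top."""

    count: int = 3
    depth_frac: float = 0.10            # lines live in the top fraction of rows
    thickness_px: tuple[int, int] = (1, 2)
    intensity: tuple[float, float] = (160.0, 220.0)


@dataclass
class SaturationConfig:
    """Vertical full-depth line artifacts over runs of consecutive slices."""

    count: int = 4
    width_px: tuple[int, int] = (1, 3)
    run_frac: tuple[float, float] = (0.2, 0.5)  # run length as stack fraction
    intensity: tuple[float, float] = (235.0, 255.0)


@dataclass
class PhantomConfig:
    """Full phantom description; ``seed`` makes generation deterministic."""

    geometry: tuple[int, int, int] = (417, 669, 417)  # (n_slices, depth_px, width_px)
    membrane: MembraneConfig | None = field(default_factory=MembraneConfig)
    deep_structures: DeepStructureConfig = field(default_factory=DeepStructureConfig)
    fixed_pattern: FixedPatternConfig = field(default_factory=FixedPatternConfig)
    saturation_lines: SaturationConfig = field(default_factory=SaturationConfig)
    speckle: float = 0.25               # log-normal sigma; 0 disables
    background_sd: float = 5.0          # additive Gaussian noise sd; 0 disables
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.geometry) != 3 or any(g < 8 for g in self.geometry):
            raise ValueError(f"geometry components must all be >= 8, got {self.geometry}")
        if self.membrane is not None:
            m = self.membrane
            if m.thickness_px < 1:
                raise ValueError("membrane thickness must be >= 1 px")
            if not (0.0 <= m.intensity_mean <= 255.0):
                raise ValueError("membrane intensity must lie in 0-255")
        for comp in (self.deep_structures, self.fixed_pattern, self.saturation_lines):
            if comp.count < 0:
                raise ValueError("component counts must be >= 0")
            lo, hi = comp.intensity
            if not (0.0 <= lo <= hi <= 255.0):
                raise ValueError("component intensities must lie in 0-255")
        if self.speckle < 0 or self.background_sd < 0:
            raise ValueError("noise strengths must be >= 0")

    @property
    def n_slices(self) -> int:
        return self.geometry[0]

    @classmethod
    def ci(cls, seed: int = 0, **overrides) -> "PhantomConfig":
        """Small-geometry preset (64 slices of 160x128) for desk-scale runs.

        Membrane thickness and blob radii are rescaled with the geometry so
        the coarse stage keeps the membrane band majority-TM inside its own
        (dilated) object mask and the blobs stay clearly smaller than the
        band.
        """
        params = dict(
            geometry=(64, 160, 128),
            membrane=MembraneConfig(thickness_px=12),
            deep_structures=DeepStructureConfig(
                count=10, radius_x_px=(3, 6), radius_y_slices=(3, 7),
                radius_z_px=(3, 6), gap_px=(3, 10),
            ),
            seed=seed,
        )
        params.update(overrides)
        return cls(**params)

    def replace(self, **changes) -> "PhantomConfig":
        return dataclasses.replace(self, **changes)


@dataclass
class LabelVolume:
    """Voxelwise ground-truth labels paired with a :class:`BScanVolume`."""

    labels: np.ndarray  # uint8, same shape as the paired volume

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 3:
            raise ValueError("labels must be 3D")
        if self.labels.max(initial=0) > ARTIFACT:
            raise ValueError("labels must be in {0..3}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def tm_mask(self) -> np.ndarray:
        return self.labels == TM


def _membrane_depth_surface(cfg: PhantomConfig) -> np.ndarray | None:
    """Center-line depth z(y, x) of the membrane band; NaN outside its x-range."""
    if cfg.membrane is None:
        return None
    n, depth, width = cfg.geometry
    m = cfg.membrane
    y = np.arange(n, dtype=np.float64)[:, None]
    x = np.arange(width, dtype=np.float64)[None, :]
    x0 = m.x_margin_frac * (width - 1)
    x1 = (1.0 - m.x_margin_frac) * (width - 1)
    xc = 0.5 * (x0 + x1)
    half = max(0.5 * (x1 - x0), 1.0)
    apex = (m.apex_depth_frac + m.drift_frac * (y / max(n - 1, 1) - 0.5)) * depth
    z = apex + m.curvature_frac * depth * ((x - xc) / half) ** 2
    z[:, (x[0] < x0) | (x[0] > x1)] = np.nan
    return z


def generate_phantom(config: PhantomConfig) -> tuple[BScanVolume, LabelVolume]:
    """Render the phantom volume and its label volume.

    Deterministic given ``config.seed``: the same config yields bit-identical
    output on every call.
    """
    n, depth, width = config.geometry
    rng = np.random.default_rng(config.seed)

    zmem = _membrane_depth_surface(config)

    # ---- volume-level random layout -------------------------------------
    fp = config.fixed_pattern
    fp_rows = []
    top = max(int(fp.depth_frac * depth), 1)
    for _ in range(fp.count):
        row = int(rng.integers(0, top))
        thick = int(rng.integers(fp.thickness_px[0], fp.thickness_px[1] + 1))
        inten = float(rng.uniform(*fp.intensity))
        fp_rows.append((row, thick, inten))

    sat = config.saturation_lines
    sat_lines = []
    for _ in range(sat.count):
        x = int(rng.integers(0, width))
        w = int(rng.integers(sat.width_px[0], sat.width_px[1] + 1))
        run = int(np.ceil(rng.uniform(*sat.run_frac) * n))
        y0 = int(rng.integers(0, max(n - run, 0) + 1))
        inten = float(rng.uniform(*sat.intensity))
        sat_lines.append((x, w, y0, y0 + run, inten))

    ds = config.deep_structures
    blobs = []
    for _ in range(ds.count):
        rx = int(rng.integers(ds.radius_x_px[0], ds.radius_x_px[1] + 1))
        ry = int(rng.integers(ds.radius_y_slices[0], ds.radius_y_slices[1] + 1))
        rz = int(rng.integers(ds.radius_z_px[0], ds.radius_z_px[1] + 1))
        cx = int(rng.integers(rx, width - rx))
        cy = int(rng.integers(0, n))
        gap = int(rng.integers(ds.gap_px[0], ds.gap_px[1] + 1))
        if zmem is not None:
            ys = slice(max(cy - ry, 0), min(cy + ry + 1, n))
            xs = slice(max(cx - rx, 0), min(cx + rx + 1, width))
            local = zmem[ys, xs]
            floor_z = float(np.nanmax(local)) if np.isfinite(local).any() else 0.3 * depth
            floor_z += config.membrane.thickness_px / 2.0
        else:
            floor_z = 0.3 * depth
        cz = int(min(floor_z + gap + rz, depth - rz - 2))
        inten = float(rng.uniform(*ds.intensity))
        blobs.append((cx, cy, cz, rx, ry, rz, inten))

    # ---- per-slice rendering --------------------------------------------
    voxels = np.empty((n, depth, width), dtype=np.uint8)
    labels = np.zeros((n, depth, width), dtype=np.uint8)
    zgrid = np.arange(depth, dtype=np.float64)[:, None]
    xgrid = np.arange(width, dtype=np.float64)[None, :]

    for y in range(n):
        img = np.zeros((depth, width), dtype=np.float64)
        lab = labels[y]

        for row, thick, inten in fp_rows:
            img[row : row + thick, :] = np.maximum(img[row : row + thick, :], inten)
            lab[row : row + thick, :] = ARTIFACT
        for x, w, y0, y1, inten in sat_lines:
            if y0 <= y < y1:
                img[:, x : x + w] = np.maximum(img[:, x : x + w], inten)
                lab[:, x : x + w] = ARTIFACT

        for cx, cy, cz, rx, ry, rz, inten in blobs:
            if abs(y - cy) >= ry:
                continue
            s = np.sqrt(1.0 - ((y - cy) / ry) ** 2)
            if s * rx < 1.0 or s * rz < 1.0:
                continue
            mask = ((xgrid - cx) / (rx * s)) ** 2 + ((zgrid - cz) / (rz * s)) ** 2 <= 1.0
            img[mask] = np.maximum(img[mask], inten)
            lab[mask] = DEEP_STRUCTURE

        if zmem is not None:
            m = config.membrane
            band = np.abs(zgrid - zmem[y][None, :]) <= m.thickness_px / 2.0
            band &= np.isfinite(zmem[y])[None, :]
            jitter = rng.normal(m.intensity_mean, m.intensity_sd, size=int(band.sum()))
            img[band] = np.maximum(img[band], np.clip(jitter, 0.0, 255.0))
            lab[band] = TM

        if config.speckle > 0:
            img *= np.exp(rng.normal(0.0, config.speckle, size=img.shape))
        if config.background_sd > 0:
            img += rng.normal(0.0, config.background_sd, size=img.shape)
        voxels[y] = np.clip(img, 0.0, 255.0).round().astype(np.uint8)

    return BScanVolume(voxels), LabelVolume(labels)


def auto_label_object(obj, labels: LabelVolume, tm_overlap_fraction: float = 0.5) -> str:
    """Assign an object its ground-truth class from the label volume.

    The object is called TM when at least ``tm_overlap_fraction`` of its mask
    pixels carry the TM label (majority vote by default, mirroring a human
    assigning one object one label).

    Raises
    ------
    IndexError
        If the object's slice index or bounding box falls outside ``labels``.
    """
    n, depth, width = labels.shape
    if not (0 <= obj.slice_index < n):
        raise IndexError(f"slice index {obj.slice_index} outside stack of {n}")
    x, z, w, h = obj.bbox
    if x < 0 or z < 0 or x + w > width or z + h > depth:
        raise IndexError(f"bbox {obj.bbox} outside slice extent ({depth}, {width})")
    window = labels.labels[obj.slice_index, z : z + h, x : x + w]
    frac = float(np.mean(window[obj.mask] == TM))
    return TM_LABEL if frac >= tm_overlap_fraction else NON_TM_LABEL
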