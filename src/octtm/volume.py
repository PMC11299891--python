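"""Volumetric B-scan I/O.

An OCT volume is an ordered stack of 2D grayscale B-scans.  The axis
convention used throughout the package is ``voxels[slice_y, depth_z, width_x]``:
the page index is the slow (Y) scan axis, page rows are depth (Z, row 0 is
shallow) and page columns are the lateral (X) axis.  Volumes travel on disk as
multi-page grayscale TIFF stacks, one page per B-scan, with an optional JSON
sidecar ``<name>.meta.json`` carrying the physical extents.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "BScanVolume",
    "VolumeIOError",
    "HeterogeneousStackError",
    "UnsupportedDtypeError",
    "read_volume",
    "write_volume",
]

#: default physical extents (x_mm, y_mm, z_mm) of a full clinical scan
DEFAULT_EXTENT_MM = (8.0, 8.0, 12.83)

_SUPPORTED_DTYPES = (np.uint8, np.uint16)


class VolumeIOError(IOError):
    """Base error for volume reading/writing problems."""


class HeterogeneousStackError(VolumeIOError):
    """Raised when TIFF pages differ in shape or dtype."""


class UnsupportedDtypeError(VolumeIOError):
    """Raised when the stack is not 8-bit or 16-bit unsigned grayscale."""


@dataclass
class BScanVolume:
    """An ordered stack of grayscale B-scans with physical-extent metadata.

    Parameters
    ----------
    voxels
        3D unsigned-integer array indexed ``(slice_y, depth_z, width_x)``.
    extent_mm
        Physical extents ``(x_mm, y_mm, z_mm)``.  Metadata only; no pipeline
        stage consumes them numerically.
    """

    voxels: np.ndarray
    extent_mm: tuple[float, float, float] = field(default=DEFAULT_EXTENT_MM)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3D, got shape {self.voxels.shape}")
        if self.voxels.dtype not in _SUPPORTED_DTYPES:
            raise UnsupportedDtypeError(
                f"unsupported dtype {self.voxels.dtype}; expected uint8 or uint16"
            )
        if min(self.voxels.shape) < 1:
            raise ValueError("all volume dimensions must be >= 1")
        if len(self.extent_mm) != 3 or any(e <= 0 for e in self.extent_mm):
            raise ValueError(f"extents must be three positive numbers, got {self.extent_mm}")
        self.extent_mm = tuple(float(e) for e in self.extent_mm)

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def depth_px(self) -> int:
        return self.voxels.shape[1]

    @property
    def width_px(self) -> int:
        return self.voxels.shape[2]

    def slice(self, y: int) -> np.ndarray:
        """Return the B-scan at stack position ``y`` (a (depth, width) view)."""
        return self.voxels[y]

    def to_uint8(self) -> "BScanVolume":
        """Return an 8-bit copy; 16-bit data are rescaled by max-value mapping.

        All detection thresholds in the package are defined on the 0-255
        scale, so 8-bit is the canonical working dtype.
        """
        if self.voxels.dtype == np.uint8:
            return self
        scaled = (self.voxels.astype(np.float64) * (255.0 / 65535.0)).round()
        return BScanVolume(scaled.astype(np.uint8), self.extent_mm)


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.stem + ".meta.json")


def read_volume(path: str | Path, to_uint8: bool = True) -> BScanVolume:
    """Read a multi-page grayscale TIFF stack as a :class:`BScanVolume`.

    Page order becomes slice order.  Extents come from the JSON sidecar when
    present, otherwise :data:`DEFAULT_EXTENT_MM`.  16-bit stacks are rescaled
    to 8-bit unless ``to_uint8=False``.

    Raises
    ------
    VolumeIOError
        If the file cannot be read.
    HeterogeneousStackError
        If pages differ in shape or dtype.
    UnsupportedDtypeError
        If pages are not unsigned 8/16-bit grayscale.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            shapes = {p.shape for p in tif.pages}
            dtypes = {p.dtype for p in tif.pages}
            if len(shapes) > 1 or len(dtypes) > 1:
                raise HeterogeneousStackError(
                    f"{path}: pages have shapes {sorted(shapes)} and dtypes {sorted(map(str, dtypes))}"
                )
            voxels = tif.asarray()
    except (HeterogeneousStackError, UnsupportedDtypeError):
        raise
    except (FileNotFoundError, OSError, ValueError) as exc:
        raise VolumeIOError(f"cannot read TIFF stack {path}: {exc}") from exc

    if voxels.ndim == 2:  # single-page stack
        voxels = voxels[None]
    if voxels.ndim != 3:
        raise UnsupportedDtypeError(f"{path}: expected grayscale pages, got shape {voxels.shape}")
    if voxels.dtype not in _SUPPORTED_DTYPES:
        raise UnsupportedDtypeError(f"{path}: unsupported dtype {voxels.dtype}")

    extent = DEFAULT_EXTENT_MM
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        extent = tuple(meta.get("extent_mm", DEFAULT_EXTENT_MM))

    vol = BScanVolume(voxels, extent)
    return vol.to_uint8() if to_uint8 else vol


def write_volume(volume: BScanVolume, path: str | Path, sidecar: bool = True) -> Path:
    """Write one lossless TIFF page per slice, preserving order and dtype."""
    path = Path(path)
    try:
        tifffile.imwrite(path, volume.voxels, photometric="minisblack")
    except (FileNotFoundError, PermissionError, OSError) as exc:
        raise VolumeIOError(f"cannot write TIFF stack {path}: {exc}") from exc
    if sidecar:
        _sidecar_path(path).write_text(
            json.dumps({"extent_mm": list(volume.extent_mm)}, indent=1)
        )
    return path
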