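"""Volume I/O: round trips, slice-order preservation, error taxonomy."""

import numpy as np
import pytest
import tifffile
from hypothesis import given, settings, strategies as st

from octtm import (
    BScanVolume,
    HeterogeneousStackError,
    UnsupportedDtypeError,
    VolumeIOError,
    generate_phantom,
    PhantomConfig,
    read_volume,
    write_volume,
)


@st.composite
def small_volumes(draw):
    n = draw(st.integers(1, 4))
    d = draw(st.integers(1, 12))
    w = draw(st.integers(1, 12))
    dtype = draw(st.sampled_from([np.uint8, np.uint16]))
    seed = draw(st.integers(0, 2**16))
    hi = 255 if dtype == np.uint8 else 65535
    data = np.random.default_rng(seed).integers(0, hi + 1, size=(n, d, w)).astype(dtype)
    return BScanVolume(data)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(vol=small_volumes())
def test_roundtrip_identity(vol, tmp_path_factory):
    """read(write(V)) preserves voxels, shape, dtype and slice order exactly."""
    path = tmp_path_factory.mktemp("vols") / "v.tiff"
    write_volume(vol, path)
    back = read_volume(path, to_uint8=False)
    assert back.voxels.dtype == vol.voxels.dtype
    np.testing.assert_array_equal(back.voxels, vol.voxels)


def test_slice_order_and_geometry(tmp_path):
    """Page order equals slice order; geometry attributes follow the array."""
    voxels = np.zeros((5, 9, 7), dtype=np.uint8)
    for i in range(5):
        voxels[i] = i * 10  # distinguishable pages
    path = write_volume(BScanVolume(voxels), tmp_path / "ordered.tiff")
    back = read_volume(path)
    assert (back.n_slices, back.depth_px, back.width_px) == (5, 9, 7)
    for i in range(5):
        assert back.slice(i).max() == i * 10


def test_default_scan_geometry_stack(tmp_path):
    """A default-geometry phantom round-trips as a 417-page stack of 417x669
    B-scans."""
    vol, _ = generate_phantom(PhantomConfig(seed=0))
    path = write_volume(vol, tmp_path / "full.tiff")
    with tifffile.TiffFile(path) as tif:
        assert len(tif.pages) == 417
    back = read_volume(path)
    assert back.n_slices == 417
    assert back.width_px == 417
    assert back.depth_px == 669


def test_sixteen_bit_rescaled_on_load(tmp_path):
    data = np.array([[[0, 65535], [32768, 100]]], dtype=np.uint16)
    path = write_volume(BScanVolume(data), tmp_path / "u16.tiff")
    back = read_volume(path)
    assert back.voxels.dtype == np.uint8
    assert back.voxels[0, 0, 1] == 255
    assert back.voxels[0, 1, 0] == 128


def test_error_taxonomy(tmp_path):
    with pytest.raises(VolumeIOError):
        read_volume(tmp_path / "missing.tiff")
    # heterogeneous page shapes
    hetero = tmp_path / "hetero.tiff"
    with tifffile.TiffWriter(hetero) as tw:
        tw.write(np.zeros((4, 5), dtype=np.uint8))
        tw.write(np.zeros((6, 7), dtype=np.uint8))
    with pytest.raises(HeterogeneousStackError):
        read_volume(hetero)
    # unsupported dtype
    floaty = tmp_path / "float.tiff"
    tifffile.imwrite(floaty, np.zeros((2, 4, 4), dtype=np.float32),
                     photometric="minisblack")
    with pytest.raises(UnsupportedDtypeError):
        read_volume(floaty)


def test_volume_invariants():
    with pytest.raises(ValueError):
        BScanVolume(np.zeros((0, 4, 4), dtype=np.uint8))
    with pytest.raises(ValueError):
        BScanVolume(np.zeros((2, 4, 4), dtype=np.uint8), extent_mm=(0, 8, 12.83))
    with pytest.raises(UnsupportedDtypeError):
        BScanVolume(np.zeros((2, 4, 4), dtype=np.int32))


def test_extent_sidecar_roundtrip(tmp_path):
    vol = BScanVolume(np.zeros((2, 4, 4), dtype=np.uint8), extent_mm=(1.0, 2.0, 3.0))
    path = write_volume(vol, tmp_path / "ext.tiff")
    assert read_volume(path).extent_mm == (1.0, 2.0, 3.0)
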