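"""Volume/mask containers, resampling, normalization, peritumoral rings."""

import numpy as np
import pytest

from perirad import (RingSpec, RoiMask, Volume, load_mask, load_volume,
                     make_peritumoral_ring, make_ring_set, normalize_gray,
                     resample_isotropic, resample_mask_isotropic, save_volume)
from perirad.image import GRAY_HI, GRAY_LO

import oracles as orc


def _ball_mask(n=20, r=5.0, spacing=(1.0, 1.0, 1.0)):
    g = [np.arange(n) * s for s in spacing]
    x, y, z = np.meshgrid(*g, indexing="ij")
    c = [(n - 1) * s / 2 for s in spacing]
    m = ((x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2) <= r ** 2
    return RoiMask(m, spacing)


# -- containers -------------------------------------------------------------

def test_volume_validation():
    with pytest.raises(ValueError, match="3-D"):
        Volume(np.zeros((4, 4)), (1, 1, 1))
    with pytest.raises(ValueError, match="non-finite"):
        Volume(np.full((2, 2, 2), np.nan), (1, 1, 1))
    with pytest.raises(ValueError, match="spacing"):
        Volume(np.zeros((2, 2, 2)), (1, 0, 1))
    v = Volume(np.zeros((2, 3, 4)), (0.9, 0.9, 2.0))
    assert v.shape == (2, 3, 4)
    assert not v.is_isotropic()
    assert Volume(np.zeros((2, 2, 2)), (1, 1, 1)).is_isotropic()


def test_mask_validation():
    with pytest.raises(ValueError, match="role"):
        RoiMask(np.ones((2, 2, 2)), (1, 1, 1), role="whole-breast")
    m = RoiMask(np.ones((2, 2, 2)), (1, 1, 1))
    assert m.n_voxels == 8 and not m.is_empty()
    assert RoiMask(np.zeros((2, 2, 2)), (1, 1, 1)).is_empty()


def test_ringspec_validation():
    with pytest.raises(ValueError, match="distance"):
        RingSpec(0.0)
    with pytest.raises(ValueError, match="mode"):
        RingSpec(2.0, mode="spherical")


# -- I/O --------------------------------------------------------------------

def test_nifti_roundtrip(tmp_path):
    rng = np.random.default_rng(0)
    vol = Volume(rng.random((6, 5, 4)) * 100, (0.9, 0.9, 2.0), (1.0, 2.0, 3.0))
    p = tmp_path / "v.nii.gz"
    save_volume(vol, p)
    back = load_volume(p)
    assert np.allclose(back.values, vol.values)
    assert back.spacing == pytest.approx(vol.spacing)
    assert back.origin == pytest.approx(vol.origin)

    mask = RoiMask(rng.random((6, 5, 4)) > 0.5, (0.9, 0.9, 2.0))
    pm = tmp_path / "m.nii.gz"
    save_volume(mask, pm)
    mback = load_mask(pm, role="peritumoral", ring_distance=4.0)
    assert np.array_equal(mback.values, mask.values)
    assert mback.role == "peritumoral" and mback.ring_distance == 4.0


# -- resampling -------------------------------------------------------------

def test_resample_spacing_and_extent():
    vol = Volume(np.random.default_rng(1).random((40, 40, 20)) * 100,
                 (0.9, 0.9, 2.0))
    out = resample_isotropic(vol, 1.0)
    assert out.spacing == (1.0, 1.0, 1.0)
    # size = round(extent / target) per axis
    assert out.shape == (36, 36, 40)


def test_resample_identity_when_isotropic():
    vol = Volume(np.zeros((4, 4, 4)), (1.0, 1.0, 1.0))
    assert resample_isotropic(vol, 1.0) is vol


def test_resample_mask_stays_binary_and_overlaps():
    mask = _ball_mask(n=24, r=6.0, spacing=(0.9, 0.9, 2.0))
    out = resample_mask_isotropic(mask, 1.0)
    assert out.values.dtype == bool
    assert out.spacing == (1.0, 1.0, 1.0)
    # volume approximately conserved (NN interpolation, coarse z)
    vol_in = mask.n_voxels * 0.9 * 0.9 * 2.0
    vol_out = out.n_voxels * 1.0
    assert vol_out == pytest.approx(vol_in, rel=0.2)


def test_resample_rejects_bad_target():
    vol = Volume(np.zeros((4, 4, 4)), (1, 1, 2))
    with pytest.raises(ValueError):
        resample_isotropic(vol, 0.0)
    with pytest.raises(ValueError):
        resample_mask_isotropic(RoiMask(np.ones((4, 4, 4)), (1, 1, 2)), -1.0)


# -- normalization ----------------------------------------------------------

def test_normalize_gray_bounds():
    vol = Volume(np.random.default_rng(2).random((8, 8, 8)) * 500 + 20,
                 (1, 1, 1))
    out = normalize_gray(vol)
    assert out.values.min() == pytest.approx(GRAY_LO)
    assert out.values.max() == pytest.approx(GRAY_HI)
    # order preserved
    flat_in = vol.values.ravel()
    flat_out = out.values.ravel()
    assert np.array_equal(np.argsort(flat_in), np.argsort(flat_out))


def test_normalize_gray_idempotent():
    vol = Volume(np.random.default_rng(3).random((6, 6, 6)) * 100, (1, 1, 1))
    once = normalize_gray(vol)
    twice = normalize_gray(once)
    assert np.allclose(once.values, twice.values)


def test_normalize_constant_volume_warns():
    vol = Volume(np.full((4, 4, 4), 7.0), (1, 1, 1))
    with pytest.warns(UserWarning, match="constant"):
        out = normalize_gray(vol)
    assert np.all(out.values == GRAY_LO)


# -- rings ------------------------------------------------------------------

def test_ring_empty_tumor_errors():
    empty = RoiMask(np.zeros((8, 8, 8)), (1, 1, 1))
    with pytest.raises(ValueError, match="empty tumor"):
        make_peritumoral_ring(empty, RingSpec(2.0))


def test_ring_matches_bruteforce_inplane_and_3d():
    mask = _ball_mask(n=14, r=3.2, spacing=(1.0, 1.0, 1.5))
    for mode, in_plane in (("in-plane", True), ("3d", False)):
        ring = make_peritumoral_ring(mask, RingSpec(2.0, mode))
        ref = orc.brute_ring(mask.values, 2.0, mask.spacing, in_plane)
        assert np.array_equal(ring.values, ref), mode
        assert ring.role == "peritumoral" and ring.ring_distance == 2.0


def test_ring_excludes_tumor_and_nests():
    mask = _ball_mask(n=26, r=5.0)
    rings = make_ring_set(mask, (2.0, 4.0, 6.0, 8.0))
    assert sorted(rings) == [2.0, 4.0, 6.0, 8.0]
    for d, r in rings.items():
        assert not (r.values & mask.values).any()
    assert (rings[2.0].values <= rings[4.0].values).all()
    assert (rings[4.0].values <= rings[6.0].values).all()
    assert (rings[6.0].values <= rings[8.0].values).all()
    assert rings[2.0].n_voxels < rings[8.0].n_voxels


def test_ring_fully_clipped_errors():
    # tumor fills the grid: no outside voxels remain for the ring
    full = RoiMask(np.ones((6, 6, 6)), (1, 1, 1))
    with pytest.raises(ValueError, match="clipped"):
        make_peritumoral_ring(full, RingSpec(2.0))


def test_inplane_ring_has_no_out_of_slice_voxels():
    # a single-slice tumor must produce a single-slice in-plane ring
    m = np.zeros((12, 12, 7), dtype=bool)
    m[4:8, 4:8, 3] = True
    ring = make_peritumoral_ring(RoiMask(m, (1, 1, 1)), RingSpec(2.0))
    assert ring.values[:, :, :3].sum() == 0
    assert ring.values[:, :, 4:].sum() == 0
    ring3d = make_peritumoral_ring(RoiMask(m, (1, 1, 1)), RingSpec(2.0, "3d"))
    assert ring3d.values[:, :, 2].sum() > 0
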