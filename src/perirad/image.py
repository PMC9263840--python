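"""Image containers and geometric preprocessing.

Volumes are scalar 3-D grids indexed ``values[x, y, z]`` with physical voxel
spacing in mm; axial slices are ``values[:, :, z]``.  The preprocessing
contract mirrors the usual two-center DCE-MRI harmonization: resample every
volume to isotropic 1 mm spacing, rescale gray values linearly onto
(1, 4097), and derive peritumoral ring masks at fixed physical distances
(2/4/6/8 mm by default) outside the tumor boundary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import SimpleITK as sitk
from scipy import ndimage

logger = logging.getLogger(__name__)

GRAY_LO = 1.0
GRAY_HI = 4097.0
DEFAULT_RING_DISTANCES = (2.0, 4.0, 6.0, 8.0)


@dataclass(frozen=True)
class Volume:
    """A 3-D scalar grid with physical spacing and origin (mm)."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 3:
            raise ValueError(f"expected a 3-D grid, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("volume contains non-finite values")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be > 0, got {self.spacing}")
        object.__setattr__(self, "values", v.astype(np.float64, copy=False))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def is_isotropic(self, tol: float = 1e-6) -> bool:
        s = self.spacing
        return abs(s[0] - s[1]) < tol and abs(s[1] - s[2]) < tol


@dataclass(frozen=True)
class RoiMask:
    """Binary mask on the same grid as its Volume.

    ``role`` is ``"intratumoral"`` or ``"peritumoral"``; peritumoral masks
    carry the ring distance in mm.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    role: str = "intratumoral"
    ring_distance: float | None = None

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 3:
            raise ValueError(f"expected a 3-D mask, got shape {v.shape}")
        if self.role not in ("intratumoral", "peritumoral"):
            raise ValueError(f"unknown mask role {self.role!r}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be > 0, got {self.spacing}")
        object.__setattr__(self, "values", v.astype(bool))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    def is_empty(self) -> bool:
        return not self.values.any()


@dataclass(frozen=True)
class RingSpec:
    """Peritumoral ring definition: physical distance and dilation mode.

    ``mode="in-plane"`` expands the tumor slice by slice in the axial plane
    (the default); ``mode="3d"`` uses the full 3-D Euclidean distance.
    """

    distance: float
    mode: str = "in-plane"

    def __post_init__(self):
        if self.distance <= 0:
            raise ValueError(f"ring distance must be > 0 mm, got {self.distance}")
        if self.mode not in ("in-plane", "3d"):
            raise ValueError(f"unknown ring mode {self.mode!r}")


# ---------------------------------------------------------------------------
# NIfTI I/O


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def save_volume(vol: Volume | RoiMask, path: str | Path) -> None:
    data = vol.values
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, _affine(vol.spacing, vol.origin))
    nib.save(img, str(path))


def load_volume(path: str | Path) -> Volume:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(o) for o in img.affine[:3, 3])
    return Volume(np.asarray(img.dataobj, dtype=np.float64), spacing, origin)


def load_mask(path: str | Path, role: str = "intratumoral",
              ring_distance: float | None = None) -> RoiMask:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(o) for o in img.affine[:3, 3])
    return RoiMask(np.asarray(img.dataobj) > 0.5, spacing, origin,
                   role=role, ring_distance=ring_distance)


# ---------------------------------------------------------------------------
# Resampling


def _sitk_from(values: np.ndarray, spacing, origin) -> sitk.Image:
    # SimpleITK arrays are indexed [z, y, x]; ours [x, y, z].
    img = sitk.GetImageFromArray(np.ascontiguousarray(values.T))
    img.SetSpacing(tuple(spacing))
    img.SetOrigin(tuple(origin))
    return img


def _resample(values: np.ndarray, spacing, origin, target: float,
              interpolator) -> tuple[np.ndarray, tuple]:
    img = _sitk_from(values, spacing, origin)
    old_size = np.array(img.GetSize(), dtype=float)
    old_spacing = np.array(img.GetSpacing())
    new_size = np.maximum(1, np.round(old_size * old_spacing / target)).astype(int)
    out = sitk.Resample(
        img,
        [int(n) for n in new_size],
        sitk.Transform(),
        interpolator,
        img.GetOrigin(),
        (target, target, target),
        img.GetDirection(),
        0.0,
        img.GetPixelID(),
    )
    return sitk.GetArrayFromImage(out).T.copy(), tuple(out.GetOrigin())


def resample_isotropic(volume: Volume, target_spacing: float = 1.0) -> Volume:
    """Resample to isotropic spacing with linear interpolation.

    Grid size is chosen as round(extent / target) per axis so the physical
    extent is preserved to within one voxel.
    """
    if target_spacing <= 0:
        raise ValueError(f"target spacing must be > 0, got {target_spacing}")
    if volume.spacing == (target_spacing,) * 3:
        return volume
    values, origin = _resample(volume.values, volume.spacing, volume.origin,
                               target_spacing, sitk.sitkLinear)
    return Volume(values, (target_spacing,) * 3, origin)


def resample_mask_isotropic(mask: RoiMask, target_spacing: float = 1.0) -> RoiMask:
    """Resample a binary mask with nearest-neighbor interpolation."""
    if target_spacing <= 0:
        raise ValueError(f"target spacing must be > 0, got {target_spacing}")
    if mask.spacing == (target_spacing,) * 3:
        return mask
    values, origin = _resample(mask.values.astype(np.uint8), mask.spacing,
                               mask.origin, target_spacing,
                               sitk.sitkNearestNeighbor)
    return RoiMask(values > 0, (target_spacing,) * 3, origin,
                   role=mask.role, ring_distance=mask.ring_distance)


# ---------------------------------------------------------------------------
# Gray-value normalization


def normalize_gray(volume: Volume, lo: float = GRAY_LO, hi: float = GRAY_HI) -> Volume:
    """Linearly map intensities so min -> lo and max -> hi.

    A constant volume carries no contrast to rescale; it maps to ``lo``
    everywhere with a warning.
    """
    v = volume.values
    vmin, vmax = float(v.min()), float(v.max())
    if vmax == vmin:
        warnings.warn("constant volume: normalization maps all voxels to lo",
                      stacklevel=2)
        return replace(volume, values=np.full_like(v, lo))
    out = lo + (v - vmin) * (hi - lo) / (vmax - vmin)
    return replace(volume, values=out)


# ---------------------------------------------------------------------------
# Peritumoral rings


def make_peritumoral_ring(tumor: RoiMask, spec: RingSpec) -> RoiMask:
    """Build the ring of voxels within ``spec.distance`` mm outside the tumor.

    In-plane mode measures distance per axial slice (slice-by-slice
    expansion); 3-D mode uses the volumetric Euclidean distance transform.
    Rings are clipped only at the grid boundary; heavy clipping (>20% of the
    ideal unclipped count cannot occur here since EDT is grid-limited) is
    approximated by warning when the tumor touches the boundary.
    """
    if tumor.is_empty():
        raise ValueError("cannot build a peritumoral ring around an empty tumor mask")
    sx, sy, sz = tumor.spacing
    t = tumor.values
    if spec.mode == "in-plane":
        dist = np.full(t.shape, np.inf)
        for z in range(t.shape[2]):
            sl = t[:, :, z]
            if not sl.any():
                continue
            dist[:, :, z] = ndimage.distance_transform_edt(~sl, sampling=(sx, sy))
    else:
        dist = ndimage.distance_transform_edt(~t, sampling=(sx, sy, sz))
    ring = (dist <= spec.distance + 1e-9) & ~t
    if not ring.any():
        raise ValueError(
            f"ring at {spec.distance} mm is entirely clipped away at the grid boundary")
    _warn_if_boundary_clipped(t, spec.distance, tumor.spacing)
    return RoiMask(ring, tumor.spacing, tumor.origin, role="peritumoral",
                   ring_distance=spec.distance)


def _warn_if_boundary_clipped(t: np.ndarray, distance: float, spacing) -> None:
    pad = [max(1, int(np.ceil(distance / s))) for s in spacing]
    for ax in range(3):
        idx_lo = [slice(None)] * 3
        idx_lo[ax] = slice(0, pad[ax])
        idx_hi = [slice(None)] * 3
        idx_hi[ax] = slice(-pad[ax], None)
        if t[tuple(idx_lo)].any() or t[tuple(idx_hi)].any():
            logger.warning("tumor within %g mm of grid boundary on axis %d; "
                           "ring may be partially clipped", distance, ax)
            return


def make_ring_set(tumor: RoiMask, distances: Sequence[float] = DEFAULT_RING_DISTANCES,
                  mode: str = "in-plane") -> dict[float, RoiMask]:
    """Rings at several distances; nested by construction (d1 < d2 => ring(d1) ⊂ ring(d2))."""
    return {d: make_peritumoral_ring(tumor, RingSpec(d, mode)) for d in distances}
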