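"""3-D shape descriptors of a binary mask: 14 features.

Mesh-based quantities (volume, surface area, sphericity) come from a
marching-cubes surface at the 0.5 iso-level of the padded mask.  Diameters
use physical voxel-center coordinates: the maximum 3-D diameter is the
largest pairwise distance between surface voxels (via the convex hull); the
three maximum 2-D diameters are the per-plane analogues.  Axis lengths are
4*sqrt(eigenvalue) of the coordinate covariance (PCA axes).

Conventions for degenerate masks: a single voxel has diameter 0, axis
lengths 0, and elongation/flatness 1; sphericity falls back to the mesh of
its cube surface.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist
from skimage import measure

SHAPE_NAMES = (
    "MeshVolume", "VoxelVolume", "SurfaceArea", "SurfaceVolumeRatio",
    "Sphericity", "Maximum3DDiameter", "Maximum2DDiameterSlice",
    "Maximum2DDiameterColumn", "Maximum2DDiameterRow", "MajorAxisLength",
    "MinorAxisLength", "LeastAxisLength", "Elongation", "Flatness",
)


def _mesh(mask: np.ndarray, spacing) -> tuple[float, float]:
    """(mesh volume, surface area) from a marching-cubes surface."""
    padded = np.pad(mask.astype(np.float64), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5,
                                                spacing=tuple(spacing))
    area = float(measure.mesh_surface_area(verts, faces))
    tri = verts[faces]
    vol = float(np.abs(np.einsum("ij,ij->i", tri[:, 0],
                                 np.cross(tri[:, 1], tri[:, 2])).sum()) / 6.0)
    return vol, area


def _max_pairwise(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    if len(points) > 10:
        try:
            points = points[ConvexHull(points).vertices]
        except QhullError:
            pass  # coplanar/collinear: brute force below
    return float(pdist(points).max())


def _surface_voxels(mask: np.ndarray) -> np.ndarray:
    from scipy import ndimage
    eroded = ndimage.binary_erosion(mask)
    return np.argwhere(mask & ~eroded)


def shape_features(mask_values: np.ndarray, spacing) -> dict[str, float]:
    mask = np.asarray(mask_values, dtype=bool)
    if not mask.any():
        raise ValueError("cannot compute shape features of an empty mask")
    spacing = np.asarray(spacing, dtype=np.float64)
    coords = np.argwhere(mask) * spacing
    n = len(coords)
    voxel_volume = float(n * spacing.prod())
    mesh_volume, area = _mesh(mask, spacing)

    surf = _surface_voxels(mask) * spacing
    max3d = _max_pairwise(surf)

    surf_idx = _surface_voxels(mask)
    diam_slice = _planar_diameter(surf_idx, spacing, fixed_axis=2)  # axial
    diam_col = _planar_diameter(surf_idx, spacing, fixed_axis=1)    # coronal
    diam_row = _planar_diameter(surf_idx, spacing, fixed_axis=0)    # sagittal

    if n > 1:
        cov = np.cov(coords, rowvar=False)
        ev = np.sort(np.clip(np.linalg.eigvalsh(cov), 0, None))[::-1]
    else:
        ev = np.zeros(3)
    major, minor, least = (4.0 * np.sqrt(ev)).tolist()
    elong = float(np.sqrt(ev[1] / ev[0])) if ev[0] > 0 else 1.0
    flat = float(np.sqrt(ev[2] / ev[0])) if ev[0] > 0 else 1.0

    sphericity = float((36.0 * np.pi * mesh_volume ** 2) ** (1.0 / 3.0) / area)
    return {
        "MeshVolume": mesh_volume,
        "VoxelVolume": voxel_volume,
        "SurfaceArea": area,
        "SurfaceVolumeRatio": area / mesh_volume,
        "Sphericity": sphericity,
        "Maximum3DDiameter": max3d,
        "Maximum2DDiameterSlice": diam_slice,
        "Maximum2DDiameterColumn": diam_col,
        "Maximum2DDiameterRow": diam_row,
        "MajorAxisLength": major,
        "MinorAxisLength": minor,
        "LeastAxisLength": least,
        "Elongation": elong,
        "Flatness": flat,
    }


def _planar_diameter(surf_idx: np.ndarray, spacing, fixed_axis: int) -> float:
    """Max in-plane pairwise distance over planes orthogonal to fixed_axis."""
    keep = [a for a in range(3) if a != fixed_axis]
    best = 0.0
    for v in np.unique(surf_idx[:, fixed_axis]):
        pts = surf_idx[surf_idx[:, fixed_axis] == v][:, keep] \
            * np.asarray(spacing)[keep]
        best = max(best, _max_pairwise(pts))
    return best
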