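"""Coordinate utilities: grid affines, sphere ROIs, MNI-Talairach mapping.

World coordinates follow the NIfTI convention (RAS, millimetres); voxel
indices are 0-based throughout.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "make_affine",
    "voxel_to_world",
    "world_to_voxel",
    "sphere_voxel_indices",
    "mni_to_talairach",
    "talairach_to_mni",
]


def make_affine(grid_dims: tuple[int, int, int], voxel_size_mm: float) -> np.ndarray:
    """Axis-aligned RAS affine placing the grid centre at the world origin."""
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    affine[:3, 3] = -(np.asarray(grid_dims, dtype=float) - 1.0) / 2.0 * voxel_size_mm
    return affine


def voxel_to_world(ijk: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """Map 0-based voxel indices (n, 3) to world mm coordinates."""
    ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
    return ijk @ affine[:3, :3].T + affine[:3, 3]


def world_to_voxel(xyz_mm: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """Map world mm coordinates to (fractional) voxel indices."""
    xyz = np.atleast_2d(np.asarray(xyz_mm, dtype=float))
    inv = np.linalg.inv(affine)
    return xyz @ inv[:3, :3].T + inv[:3, 3]


def sphere_voxel_indices(
    center_mm,
    radius_mm: float,
    mask: np.ndarray,
    affine: np.ndarray,
) -> np.ndarray:
    """All mask voxels whose centres lie within ``radius_mm`` (inclusive)
    of ``center_mm``; returns an (n, 3) array of 0-based indices.

    ``radius_mm = 0`` degenerates to the single nearest in-mask voxel.
    """
    mask = np.asarray(mask, dtype=bool)
    idx = np.argwhere(mask)
    centers = voxel_to_world(idx, affine)
    dist = np.linalg.norm(centers - np.asarray(center_mm, dtype=float), axis=1)
    if radius_mm == 0:
        return idx[[int(np.argmin(dist))]]
    inside = dist <= radius_mm + 1e-9
    return idx[inside]


# Brett's piecewise-affine MNI -> Talairach mapping: pure rotations/scalings
# about the origin, with separate matrices above and below the AC plane.
_BRETT_ABOVE = np.array(
    [[0.9900, 0.0, 0.0], [0.0, 0.9688, 0.0460], [0.0, -0.0485, 0.9189]]
)
_BRETT_BELOW = np.array(
    [[0.9900, 0.0, 0.0], [0.0, 0.9688, 0.0420], [0.0, -0.0485, 0.8390]]
)


def mni_to_talairach(coord_mm) -> np.ndarray:
    """Brett's piecewise-affine MNI -> Talairach-Tournoux transform."""
    xyz = np.asarray(coord_mm, dtype=float)
    single = xyz.ndim == 1
    pts = np.atleast_2d(xyz)
    if not np.all(np.isfinite(pts)):
        raise ValueError("coordinates must be finite")
    above = pts[:, 2] >= 0
    out = np.empty_like(pts)
    out[above] = pts[above] @ _BRETT_ABOVE.T
    out[~above] = pts[~above] @ _BRETT_BELOW.T
    return out[0] if single else out


def talairach_to_mni(coord_mm) -> np.ndarray:
    """Inverse of :func:`mni_to_talairach` (branch chosen by the sign of
    the resulting MNI z, which the transforms preserve at the AC plane)."""
    xyz = np.asarray(coord_mm, dtype=float)
    single = xyz.ndim == 1
    pts = np.atleast_2d(xyz)
    inv_above = np.linalg.inv(_BRETT_ABOVE)
    inv_below = np.linalg.inv(_BRETT_BELOW)
    cand_above = pts @ inv_above.T
    cand_below = pts @ inv_below.T
    out = np.where((cand_above[:, 2] >= 0)[:, None], cand_above, cand_below)
    return out[0] if single else out
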