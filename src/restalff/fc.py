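"""Seed-based functional connectivity.

A seed is a small sphere (default 6 mm diameter) centred on a peak
group-difference voxel.  Its mean time series and every voxel's series are
first residualized against the six rigid-body motion parameters (plus an
intercept); the voxel-wise Pearson correlation with the seed is then
Fisher z-transformed, and the per-subject z-maps enter within-group
one-sample and between-group two-sample t-tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .coords import sphere_voxel_indices, voxel_to_world
from .group_stats import StatMap, one_sample_t_map, two_sample_t_map

__all__ = [
    "SeedRoi",
    "FcMap",
    "resolve_sphere",
    "peak_difference_voxel",
    "extract_seed_series",
    "regress_out_nuisance",
    "fc_map_subject",
    "fisher_z",
    "inverse_fisher_z",
    "group_fc_maps",
]

_CLIP = 1.0 - 1e-7


@dataclass
class SeedRoi:
    """A spherical seed resolved to mask voxels on the analysis grid."""

    label: str
    center_mm: tuple[float, float, float]
    diameter_mm: float
    voxels: np.ndarray  # (n, 3) 0-based indices

    def __len__(self) -> int:
        return len(self.voxels)


@dataclass
class FcMap:
    values: np.ndarray  # 3D r- or z-map
    mask: np.ndarray
    seed_label: str
    subject_id: str | None = None
    space: str = "r"  # "r" or "z"
    affine: np.ndarray | None = field(default=None, repr=False)


def resolve_sphere(
    center_mm,
    diameter_mm: float,
    mask: np.ndarray,
    affine: np.ndarray,
    label: str = "seed",
) -> SeedRoi:
    """All mask voxels within ``diameter_mm / 2`` (inclusive) of the
    centre; the diameter is read literally, so 6 mm means radius 3 mm."""
    voxels = sphere_voxel_indices(center_mm, diameter_mm / 2.0, mask, affine)
    if len(voxels) == 0:
        raise ValueError(
            f"seed sphere at {tuple(np.asarray(center_mm, dtype=float))} "
            f"(diameter {diameter_mm} mm) resolves to no mask voxels"
        )
    return SeedRoi(label=label, center_mm=tuple(np.asarray(center_mm, dtype=float)),
                   diameter_mm=diameter_mm, voxels=voxels)


def peak_difference_voxel(stat_map: StatMap, region_voxels: np.ndarray) -> np.ndarray:
    """World coordinate (mm) of the max-|t| voxel within a search region;
    ties resolve to the lexicographically smallest voxel index."""
    region = np.asarray(region_voxels)
    if region.size == 0:
        raise ValueError("empty search region")
    tv = np.abs(stat_map.t_values[tuple(region.T)])
    best = tv.max()
    candidates = region[tv >= best - 1e-12]
    peak = candidates[np.lexsort(candidates.T[::-1])][0]
    if stat_map.affine is None:
        raise ValueError("StatMap has no affine; cannot report a world coordinate")
    return voxel_to_world(peak, stat_map.affine)[0]


def extract_seed_series(series4d: np.ndarray, roi: SeedRoi) -> np.ndarray:
    """Frame-wise mean time series over the seed's voxels."""
    data = np.asarray(series4d, dtype=float)
    if data.ndim != 4:
        raise ValueError("expected a 4D series")
    if (np.asarray(roi.voxels) >= np.array(data.shape[:3])).any():
        raise ValueError("seed voxels fall outside the series grid")
    return data[tuple(roi.voxels.T)].mean(axis=0)


def regress_out_nuisance(series: np.ndarray, motion_trace: np.ndarray) -> np.ndarray:
    """Residualize each row of ``series`` (or a single 1D series) against
    [intercept, 6 motion columns] by least squares.

    Linearly dependent design columns are dropped with a warning.
    """
    x = np.asarray(series, dtype=float)
    motion = np.asarray(motion_trace, dtype=float)
    t_len = x.shape[-1]
    if motion.shape[0] != t_len:
        raise ValueError(
            f"motion trace has {motion.shape[0]} rows but series has {t_len} frames"
        )
    design = np.column_stack([np.ones(t_len), motion])
    # Greedy rank filter keeps the intercept and any column that raises rank.
    keep = [0]
    for j in range(1, design.shape[1]):
        cand = design[:, keep + [j]]
        if np.linalg.matrix_rank(cand) == len(keep) + 1:
            keep.append(j)
    if len(keep) < design.shape[1]:
        warnings.warn(
            f"dropped {design.shape[1] - len(keep)} linearly dependent "
            "nuisance columns",
            stacklevel=2,
        )
        design = design[:, keep]
    coef, *_ = np.linalg.lstsq(design, x.reshape(-1, t_len).T, rcond=None)
    resid = x.reshape(-1, t_len) - (design @ coef).T
    return resid.reshape(x.shape)


def fc_map_subject(
    seed_series: np.ndarray,
    series4d: np.ndarray,
    mask: np.ndarray,
    seed_label: str = "seed",
    subject_id: str | None = None,
    affine: np.ndarray | None = None,
) -> FcMap:
    """Pearson r of every in-mask voxel's series with the seed series."""
    seed = np.asarray(seed_series, dtype=float)
    data = np.asarray(series4d, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if data.shape[:3] != mask.shape or data.shape[-1] != seed.size:
        raise ValueError("series, mask and seed series shapes are inconsistent")
    vox = data[mask]
    vox_c = vox - vox.mean(axis=-1, keepdims=True)
    seed_c = seed - seed.mean()
    seed_norm = np.linalg.norm(seed_c)
    if seed_norm == 0:
        raise ValueError("seed series has zero variance")
    norms = np.linalg.norm(vox_c, axis=-1)
    zero_var = norms == 0
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} zero-variance voxels assigned r = 0",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (vox_c @ seed_c) / (norms * seed_norm)
    r = np.where(zero_var, 0.0, r)
    r = np.clip(r, -1.0, 1.0)
    values = np.zeros(mask.shape, dtype=float)
    values[mask] = r
    return FcMap(values=values, mask=mask, seed_label=seed_label,
                 subject_id=subject_id, space="r", affine=affine)


def fisher_z(r):
    """Fisher's variance-stabilizing transform z = atanh(r).

    |r| >= 1 (a seed's own voxels) is clipped to keep z finite.
    """
    r = np.asarray(r, dtype=float)
    if (np.abs(r) >= 1).any():
        warnings.warn("|r| >= 1 clipped before Fisher z", stacklevel=2)
        r = np.clip(r, -_CLIP, _CLIP)
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def inverse_fisher_z(z):
    out = np.tanh(np.asarray(z, dtype=float))
    return float(out) if out.ndim == 0 else out


def fc_z_map(fc_map: FcMap) -> FcMap:
    """Convert an r-space FcMap to z-space."""
    if fc_map.space != "r":
        return fc_map
    values = np.zeros_like(fc_map.values)
    values[fc_map.mask] = fisher_z(fc_map.values[fc_map.mask])
    return FcMap(values=values, mask=fc_map.mask, seed_label=fc_map.seed_label,
                 subject_id=fc_map.subject_id, space="z", affine=fc_map.affine)


def group_fc_maps(
    z_maps,
    groups,
    mask: np.ndarray,
    voxel_p_threshold: float | None = 0.01,
    affine: np.ndarray | None = None,
) -> dict[str, StatMap]:
    """Within-group one-sample t-maps (z vs 0) and the between-group
    two-sample map (group B minus group A)."""
    values = [m.values if isinstance(m, FcMap) else np.asarray(m, dtype=float) for m in z_maps]
    groups = list(groups)
    if len(values) != len(groups):
        raise ValueError("one group label per z-map required")
    maps_a = [v for v, g in zip(values, groups) if g == "A"]
    maps_b = [v for v, g in zip(values, groups) if g == "B"]
    if len(maps_a) < 2 or len(maps_b) < 2:
        raise ValueError("need >= 2 subjects per group")
    return {
        "one_sample_A": one_sample_t_map(maps_a, mask, affine=affine),
        "one_sample_B": one_sample_t_map(maps_b, mask, affine=affine),
        "between": two_sample_t_map(
            maps_a, maps_b, mask, voxel_p_threshold=voxel_p_threshold, affine=affine
        ),
    }
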