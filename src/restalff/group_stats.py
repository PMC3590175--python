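"""Voxel-wise group inference with Monte-Carlo cluster-extent correction.

The group comparison is a pooled-variance two-sample t-test at every mask
voxel (sign convention: group B minus group A, so negative t means
*decreased* in the patient group).  Voxel-level thresholding at an
uncorrected p is followed by a cluster-extent criterion: the minimum
surviving cluster size ``k_min`` is estimated AlphaSim-style by Monte-Carlo
simulation of smooth Gaussian null maps inside the same mask, choosing the
smallest extent whose family-wise occurrence probability under the null is
at most the corrected alpha.  A Bonferroni voxel-level mode is available
as the family-wise-error alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .preprocess import fwhm_to_sigma

__all__ = [
    "StatMap",
    "t_critical",
    "two_sample_t_map",
    "one_sample_t_map",
    "label_clusters",
    "alphasim_min_extent",
    "AlphaSimResult",
    "cluster_report",
    "write_cluster_report",
    "bonferroni_t_threshold",
]

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}

REPORT_COLUMNS = ["x_mm", "y_mm", "z_mm", "peak_t", "cluster_size", "sign"]


@dataclass
class StatMap:
    """A voxel-wise t-statistic map with its degrees of freedom."""

    t_values: np.ndarray
    df: int
    mask: np.ndarray
    voxel_p_threshold: float | None = None
    affine: np.ndarray | None = field(default=None, repr=False)

    @property
    def t_critical(self) -> float:
        if self.voxel_p_threshold is None:
            raise ValueError("no voxel p threshold set")
        return t_critical(self.voxel_p_threshold, self.df)


def t_critical(alpha_two_tailed: float, df: int) -> float:
    """Two-tailed Student-t critical value: P(|T_df| > q) = alpha."""
    if not 0 < alpha_two_tailed <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(stats.t.ppf(1.0 - alpha_two_tailed / 2.0, df))


def bonferroni_t_threshold(alpha_two_tailed: float, df: int, n_voxels: int) -> float:
    """Voxel-level family-wise threshold: Bonferroni over in-mask voxels."""
    if n_voxels < 1:
        raise ValueError("n_voxels must be >= 1")
    return t_critical(alpha_two_tailed / n_voxels, df)


def _stack(maps) -> np.ndarray:
    arr = np.stack([np.asarray(m, dtype=float) for m in maps], axis=-1)
    return arr


def two_sample_t_map(
    maps_a,
    maps_b,
    mask: np.ndarray,
    voxel_p_threshold: float | None = None,
    affine: np.ndarray | None = None,
) -> StatMap:
    """Pooled-variance two-sample t at each mask voxel, sign B - A."""
    a = _stack(maps_a)
    b = _stack(maps_b)
    mask = np.asarray(mask, dtype=bool)
    n_a, n_b = a.shape[-1], b.shape[-1]
    if n_a < 2 or n_b < 2:
        raise ValueError("need >= 2 subjects per group")
    if a.shape[:-1] != mask.shape or b.shape[:-1] != mask.shape:
        raise ValueError("map shapes do not match the mask")
    df = n_a + n_b - 2
    mean_a, mean_b = a.mean(axis=-1), b.mean(axis=-1)
    ss_a = ((a - mean_a[..., None]) ** 2).sum(axis=-1)
    ss_b = ((b - mean_b[..., None]) ** 2).sum(axis=-1)
    pooled_var = (ss_a + ss_b) / df
    se = np.sqrt(pooled_var * (1.0 / n_a + 1.0 / n_b))
    t = np.zeros(mask.shape, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_in = (mean_b - mean_a) / se
    degenerate = mask & ~np.isfinite(t_in)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} in-mask voxels with zero pooled "
            "variance; t set to 0",
            stacklevel=2,
        )
        t_in = np.where(np.isfinite(t_in), t_in, 0.0)
    t[mask] = t_in[mask]
    return StatMap(t_values=t, df=df, mask=mask,
                   voxel_p_threshold=voxel_p_threshold, affine=affine)


def one_sample_t_map(
    maps,
    mask: np.ndarray,
    popmean: float = 0.0,
    affine: np.ndarray | None = None,
) -> StatMap:
    """One-sample t vs ``popmean``; zero-variance voxels are masked out."""
    x = _stack(maps)
    mask = np.asarray(mask, dtype=bool)
    n = x.shape[-1]
    if n < 2:
        raise ValueError("need >= 2 subjects")
    mean = x.mean(axis=-1)
    sd = x.std(axis=-1, ddof=1)
    out_mask = mask.copy()
    # near-zero spread (identical maps up to rounding) counts as degenerate
    degenerate = mask & (sd <= 1e-10 * np.maximum(1.0, np.abs(mean)))
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance voxels masked out of "
            "one-sample t-map",
            stacklevel=2,
        )
        out_mask &= ~degenerate
    t = np.zeros(mask.shape, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_in = (mean - popmean) / (sd / np.sqrt(n))
    t[out_mask] = t_in[out_mask]
    return StatMap(t_values=t, df=n - 1, mask=out_mask, affine=affine)


def _structure(connectivity: int) -> np.ndarray:
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError("connectivity must be one of 6, 18, 26")
    return ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])


def label_clusters(binary_map: np.ndarray, connectivity: int = 6) -> list[np.ndarray]:
    """Connected components of a 3D binary map as (n, 3) voxel-index
    arrays, ordered by decreasing size then lexicographically smallest
    voxel index."""
    binary = np.asarray(binary_map, dtype=bool)
    if binary.ndim != 3:
        raise ValueError("expected a 3D binary map")
    labels, n_lab = ndimage.label(binary, structure=_structure(connectivity))
    clusters = [np.argwhere(labels == lab) for lab in range(1, n_lab + 1)]
    clusters.sort(key=lambda c: (-len(c), tuple(map(int, c.min(axis=0)))))
    return clusters


@dataclass
class AlphaSimResult:
    k_min: int
    null_max_sizes: np.ndarray  # max suprathreshold cluster size per iteration
    voxel_p: float
    corrected_alpha: float

    def tail_probability(self, k: int) -> float:
        """Estimated P(max null cluster size >= k)."""
        return float((self.null_max_sizes >= k).mean())


def alphasim_min_extent(
    mask: np.ndarray,
    fwhm_mm: float,
    voxel_size_mm: float,
    voxel_p: float = 0.01,
    corrected_alpha: float = 0.05,
    n_iter: int = 1000,
    connectivity: int = 6,
    rng: np.random.Generator | None = None,
) -> AlphaSimResult:
    """Monte-Carlo minimum cluster extent controlling family-wise error.

    Per iteration: fill the mask's bounding grid with unit Gaussian noise,
    smooth to the analysis FWHM, re-standardize in-mask to zero mean and
    unit variance, threshold two-tailed at ``voxel_p``, and record the
    largest suprathreshold cluster.  ``k_min`` is the smallest extent whose
    null occurrence frequency is at most ``corrected_alpha``.
    """
    if not 0 < voxel_p < 1 or not 0 < corrected_alpha <= 1:
        raise ValueError("voxel_p and corrected_alpha must lie in (0, 1]")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    if rng is None:
        rng = np.random.default_rng()
    z_thresh = float(stats.norm.ppf(1.0 - voxel_p / 2.0))
    sigma = fwhm_to_sigma(fwhm_mm, voxel_size_mm) if fwhm_mm > 0 else 0.0
    structure = _structure(connectivity)

    max_sizes = np.zeros(n_iter, dtype=int)
    for it in range(n_iter):
        noise = rng.standard_normal(mask.shape)
        if sigma > 0:
            noise = ndimage.gaussian_filter(noise, sigma=sigma, mode="nearest")
        vals = noise[mask]
        vals = (vals - vals.mean()) / vals.std()
        supra = np.zeros(mask.shape, dtype=bool)
        supra[mask] = np.abs(vals) > z_thresh
        if supra.any():
            labels, n_lab = ndimage.label(supra, structure=structure)
            if n_lab:
                sizes = np.bincount(labels.ravel())[1:]
                max_sizes[it] = int(sizes.max())

    # Smallest k with P(max >= k) <= corrected_alpha; k=1 always exists
    # when corrected_alpha = 1.
    k = 1
    while (max_sizes >= k).mean() > corrected_alpha:
        k += 1
    return AlphaSimResult(
        k_min=k, null_max_sizes=max_sizes, voxel_p=voxel_p,
        corrected_alpha=corrected_alpha,
    )


def cluster_report(
    stat_map: StatMap,
    k_min: int,
    affine: np.ndarray | None = None,
    t_threshold: float | None = None,
    connectivity: int = 6,
    exclude_voxels: np.ndarray | None = None,
) -> pd.DataFrame:
    """Suprathreshold clusters of extent >= ``k_min`` with their peaks.

    Columns: peak world coordinates (mm), peak t, cluster size, sign.
    Positive and negative tails are clustered separately; peak-|t| ties
    break to the lexicographically smallest voxel index.  Voxels listed in
    ``exclude_voxels`` (n, 3) — e.g. a seed sphere's own voxels — are
    removed before clustering.
    """
    if affine is None:
        affine = stat_map.affine
    if affine is None:
        raise ValueError("an affine is required to report world coordinates")
    if t_threshold is None:
        t_threshold = stat_map.t_critical

    t = stat_map.t_values
    usable = stat_map.mask.copy()
    if exclude_voxels is not None and len(exclude_voxels):
        usable[tuple(np.asarray(exclude_voxels).T)] = False

    rows = []
    for sign, supra in (
        (1, usable & (t > t_threshold)),
        (-1, usable & (t < -t_threshold)),
    ):
        for cluster in label_clusters(supra, connectivity):
            if len(cluster) < k_min:
                continue
            tv = t[tuple(cluster.T)]
            best = np.abs(tv).max()
            candidates = cluster[np.abs(tv) >= best - 1e-12]
            peak = candidates[np.lexsort(candidates.T[::-1])][0]
            world = (affine[:3, :3] @ peak + affine[:3, 3])
            rows.append(
                {
                    "x_mm": float(world[0]),
                    "y_mm": float(world[1]),
                    "z_mm": float(world[2]),
                    "peak_t": float(t[tuple(peak)]),
                    "cluster_size": int(len(cluster)),
                    "sign": sign,
                }
            )
    report = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    return report.sort_values(
        ["cluster_size", "peak_t"], ascending=[False, False]
    ).reset_index(drop=True)


def write_cluster_report(report: pd.DataFrame, path) -> None:
    report.to_csv(path, sep="\t", index=False)
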