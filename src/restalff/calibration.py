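"""Replicate studies: null calibration and planted-effect recovery.

These run the same computational chain as the on-disk pipeline --
simulate -> preprocess -> ALFF -> group statistics (and the FC and
clinical branches) -- but in memory, across seeded replicates, to measure
family-wise false-positive control and detection power under the
generator's study conditions.  They are what the acceptance checks and
the stochastic tests call.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .alff import alff_map, regional_mean_alff, standardize_alff
from .clinical import partial_correlation
from .coords import sphere_voxel_indices
from .fc import extract_seed_series, fc_map_subject, fc_z_map, regress_out_nuisance, resolve_sphere
from .group_stats import alphasim_min_extent, cluster_report, two_sample_t_map
from .preprocess import PreprocessParams, preprocess_series
from .simulate import GROUP_B, SimulationConfig, make_brain_mask, simulate_cohort

__all__ = [
    "ReplicateStudy",
    "null_calibration",
    "alff_recovery",
    "fc_recovery",
    "association_study",
]


@dataclass
class ReplicateStudy:
    """Outcome of a seeded replicate study."""

    n_replicates: int
    n_success: int
    k_min: int | None = None
    details: list | None = None

    @property
    def rate(self) -> float:
        return self.n_success / self.n_replicates


def _malff_maps(subjects, mask, config: SimulationConfig, pre: PreprocessParams):
    maps_a, maps_b, per_subject = [], [], {}
    for sub in subjects:
        clean = preprocess_series(sub.bold, config.tr_s, config.voxel_size_mm, pre)
        amap = standardize_alff(alff_map(clean, mask, config.tr_s, pre.band_hz))
        per_subject[sub.subject_id] = (sub, clean, amap)
        (maps_b if sub.group == GROUP_B else maps_a).append(amap.values)
    return maps_a, maps_b, per_subject


def _shared_k_min(config: SimulationConfig, pre: PreprocessParams, seed: int,
                  voxel_p: float, corrected_alpha: float, n_iter: int,
                  connectivity: int) -> int:
    mask = make_brain_mask(config)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA5]))
    return alphasim_min_extent(
        mask, pre.fwhm_mm, config.voxel_size_mm,
        voxel_p=voxel_p, corrected_alpha=corrected_alpha,
        n_iter=n_iter, connectivity=connectivity, rng=rng,
    ).k_min


def null_calibration(
    config: SimulationConfig | None = None,
    n_replicates: int = 20,
    seed: int = 0,
    pre: PreprocessParams | None = None,
    voxel_p: float = 0.01,
    corrected_alpha: float = 0.05,
    alphasim_n_iter: int = 1000,
    connectivity: int = 6,
) -> ReplicateStudy:
    """Fraction of no-effect cohorts whose corrected ALFF cluster report is
    empty (family-wise false positives under the null)."""
    base = (config or SimulationConfig()).null()
    pre = pre or PreprocessParams()
    k_min = _shared_k_min(base, pre, seed, voxel_p, corrected_alpha,
                          alphasim_n_iter, connectivity)
    n_empty = 0
    sizes = []
    for rep in range(n_replicates):
        cfg = dataclasses.replace(base, seed=seed + 1000 + rep)
        subjects, _, mask = simulate_cohort(cfg)
        maps_a, maps_b, _ = _malff_maps(subjects, mask, cfg, pre)
        stat = two_sample_t_map(maps_a, maps_b, mask, voxel_p_threshold=voxel_p,
                                affine=cfg.affine)
        report = cluster_report(stat, k_min, affine=cfg.affine,
                                connectivity=connectivity)
        sizes.append(len(report))
        n_empty += int(len(report) == 0)
    return ReplicateStudy(n_replicates=n_replicates, n_success=n_empty,
                          k_min=k_min, details=sizes)


def _roi_detected(report, center_mm, radius_mm, sign, slack_mm=0.0) -> bool:
    """A cluster counts as recovering a planted ROI when its peak lies
    within the ROI radius (plus a slack for voxel discretization) and has
    the planted sign."""
    for _, row in report.iterrows():
        d = np.linalg.norm(np.array([row.x_mm, row.y_mm, row.z_mm]) - np.asarray(center_mm))
        if d <= radius_mm + slack_mm and np.sign(row.peak_t) == sign:
            return True
    return False


def alff_recovery(
    config: SimulationConfig | None = None,
    n_replicates: int = 25,
    seed: int = 0,
    pre: PreprocessParams | None = None,
    voxel_p: float = 0.01,
    corrected_alpha: float = 0.05,
    alphasim_n_iter: int = 1000,
    connectivity: int = 6,
) -> ReplicateStudy:
    """Detection rate of the planted amplitude ROI in the corrected
    between-group ALFF report.

    The default study isolates the amplitude mechanism: no connectivity
    effect is planted, because a group difference in shared-signal weight
    also changes post-smoothing amplitude (coherent neighbours add
    constructively under the spatial filter) and would confound the ROI.
    """
    if config is None:
        config = dataclasses.replace(SimulationConfig(), connectivity_effects=())
    base = config
    if not base.effect_rois:
        raise ValueError("configuration plants no amplitude ROI")
    pre = pre or PreprocessParams()
    roi = base.effect_rois[0]
    sign = 1 if roi.amplitude_ratio > 1 else -1
    k_min = _shared_k_min(base, pre, seed, voxel_p, corrected_alpha,
                          alphasim_n_iter, connectivity)
    n_hit = 0
    for rep in range(n_replicates):
        cfg = dataclasses.replace(base, seed=seed + 2000 + rep)
        subjects, _, mask = simulate_cohort(cfg)
        maps_a, maps_b, _ = _malff_maps(subjects, mask, cfg, pre)
        stat = two_sample_t_map(maps_a, maps_b, mask, voxel_p_threshold=voxel_p,
                                affine=cfg.affine)
        report = cluster_report(stat, k_min, affine=cfg.affine,
                                connectivity=connectivity)
        n_hit += int(
            _roi_detected(report, roi.center_mm, roi.radius_mm, sign,
                          slack_mm=cfg.voxel_size_mm)
        )
    return ReplicateStudy(n_replicates=n_replicates, n_success=n_hit, k_min=k_min)


def fc_recovery(
    config: SimulationConfig | None = None,
    n_replicates: int = 25,
    seed: int = 0,
    pre: PreprocessParams | None = None,
    voxel_p: float = 0.01,
    corrected_alpha: float = 0.05,
    alphasim_n_iter: int = 1000,
    connectivity: int = 6,
) -> ReplicateStudy:
    """Detection rate of the planted seed-target connectivity difference
    in the corrected between-group FC report (seed taken from ground
    truth, target must appear with the planted sign)."""
    base = config or SimulationConfig()
    if not base.connectivity_effects:
        raise ValueError("configuration plants no connectivity effect")
    pre = pre or PreprocessParams()
    eff = base.connectivity_effects[0]
    sign = 1 if eff.weight_b > eff.weight_a else -1
    k_min = _shared_k_min(base, pre, seed, voxel_p, corrected_alpha,
                          alphasim_n_iter, connectivity)
    n_hit = 0
    for rep in range(n_replicates):
        cfg = dataclasses.replace(base, seed=seed + 3000 + rep)
        subjects, _, mask = simulate_cohort(cfg)
        # Analysis-convention seed: 6 mm diameter sphere at the planted
        # seed centre; the full planted seed region is excluded from the
        # report so self-connectivity never masquerades as recovery.
        roi = resolve_sphere(eff.seed_center_mm, 6.0, mask, cfg.affine)
        planted_seed_vox = sphere_voxel_indices(
            eff.seed_center_mm, eff.radius_mm, mask, cfg.affine
        )
        z_a, z_b = [], []
        for sub in subjects:
            clean = preprocess_series(sub.bold, cfg.tr_s, cfg.voxel_size_mm, pre)
            motion = sub.motion[pre.n_discard:]
            resid = np.zeros_like(clean)
            resid[mask] = regress_out_nuisance(clean[mask], motion)
            seed_series = regress_out_nuisance(extract_seed_series(clean, roi), motion)
            zmap = fc_z_map(fc_map_subject(seed_series, resid, mask))
            (z_b if sub.group == GROUP_B else z_a).append(zmap.values)
        stat = two_sample_t_map(z_a, z_b, mask, voxel_p_threshold=voxel_p,
                                affine=cfg.affine)
        report = cluster_report(stat, k_min, affine=cfg.affine,
                                connectivity=connectivity,
                                exclude_voxels=planted_seed_vox)
        n_hit += int(
            _roi_detected(report, eff.target_center_mm, eff.radius_mm, sign,
                          slack_mm=cfg.voxel_size_mm)
        )
    return ReplicateStudy(n_replicates=n_replicates, n_success=n_hit, k_min=k_min)


def association_study(
    config: SimulationConfig | None = None,
    n_replicates: int = 50,
    seed: int = 0,
    pre: PreprocessParams | None = None,
    alpha: float = 0.05,
    expect_negative: bool = True,
) -> ReplicateStudy:
    """Power (or, with zero coupling, type-I rate) of the regional-ALFF vs
    use-duration partial correlation in group B, controlling age,
    education and nicotine.

    Uses a reduced 16 x 16 x 12 grid with the ROI recentred so the sphere
    stays inside the smaller mask; the association mechanism does not
    depend on grid size.
    """
    if config is None:
        config = dataclasses.replace(
            SimulationConfig(),
            grid_dims=(16, 16, 12),
            effect_rois=(
                dataclasses.replace(SimulationConfig().effect_rois[0],
                                    center_mm=(6.0, 6.0, 0.0)),
            ),
            connectivity_effects=(),
        )
    pre = pre or PreprocessParams()
    roi = config.effect_rois[0]
    n_sig = 0
    r_values = []
    for rep in range(n_replicates):
        cfg = dataclasses.replace(config, seed=seed + 4000 + rep)
        subjects, _, mask = simulate_cohort(cfg)
        vox = sphere_voxel_indices(roi.center_mm, roi.radius_mm, mask, cfg.affine)
        x, y, cov = [], [], []
        for sub in subjects:
            if sub.group != GROUP_B:
                continue
            clean = preprocess_series(sub.bold, cfg.tr_s, cfg.voxel_size_mm, pre)
            amap = standardize_alff(alff_map(clean, mask, cfg.tr_s, pre.band_hz))
            x.append(regional_mean_alff(amap, vox))
            y.append(sub.covariates["duration"])
            cov.append([sub.covariates["age"], sub.covariates["education"],
                        sub.covariates["nicotine"]])
        r, p = partial_correlation(np.array(x), np.array(y), np.array(cov))
        r_values.append(r)
        hit = p < alpha and (r < 0 if expect_negative else True)
        n_sig += int(hit)
    return ReplicateStudy(n_replicates=n_replicates, n_success=n_sig,
                          details=r_values)
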