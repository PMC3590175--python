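"""Pipeline configuration and end-to-end orchestration.

Stage order mirrors the analysis narrative: simulate (or ingest) ->
preprocess + ALFF -> group ALFF statistics -> seed FC -> FC group
statistics -> clinical associations.  Every stage reads its inputs from
and writes its outputs to a conventional tree under ``output_dir``::

    alff/<sub>_malff.nii.gz         standardized ALFF per subject
    group_alff/alff_tmap.nii.gz     two-sample t-map (B - A)
    group_alff/alff_report.tsv      corrected cluster report
    group_alff/alphasim.json        k_min and Monte-Carlo settings
    fc/<sub>__<seed>_z.nii.gz       Fisher-z connectivity maps
    group_fc/fc_report.tsv          corrected FC cluster report (all seeds)
    assoc/association.tsv           ALFF vs drug-use partial correlations

Re-running with the same configuration and seed reproduces all numeric
outputs bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clinical, io
from .alff import alff_map, regional_mean_alff, standardize_alff
from .coords import sphere_voxel_indices
from .fc import (
    extract_seed_series,
    fc_map_subject,
    fc_z_map,
    group_fc_maps,
    regress_out_nuisance,
    resolve_sphere,
)
from .group_stats import (
    alphasim_min_extent,
    bonferroni_t_threshold,
    cluster_report,
    two_sample_t_map,
    write_cluster_report,
)
from .preprocess import PreprocessParams, preprocess_series, screen_motion
from .simulate import ConnectivityEffect, EffectRoi, GroundTruth, SimulationConfig, generate_cohort

logger = logging.getLogger("restalff")

__all__ = ["PipelineConfig", "run_pipeline", "PipelineResult"]


def _as_tuple(x):
    return tuple(x) if isinstance(x, (list, tuple)) else x


def _sim_config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    d["grid_dims"] = tuple(d["grid_dims"])
    d["n_per_group"] = tuple(d["n_per_group"])
    d["band_hz"] = tuple(d["band_hz"])
    d["effect_rois"] = tuple(
        EffectRoi(center_mm=tuple(r["center_mm"]), radius_mm=r["radius_mm"],
                  amplitude_ratio=r.get("amplitude_ratio", 1.0))
        for r in d.get("effect_rois", [])
    )
    d["connectivity_effects"] = tuple(
        ConnectivityEffect(
            seed_center_mm=tuple(c["seed_center_mm"]),
            target_center_mm=tuple(c["target_center_mm"]),
            radius_mm=c.get("radius_mm", 6.0),
            weight_a=c.get("weight_a", 0.0),
            weight_b=c.get("weight_b", 0.0),
        )
        for c in d.get("connectivity_effects", [])
    )
    return SimulationConfig(**d)


@dataclass
class PipelineConfig:
    """Everything a full run needs; YAML round-trip is lossless."""

    input_dir: str = "cohort"
    output_dir: str = "derived"
    simulation: SimulationConfig | None = field(default_factory=SimulationConfig)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    tr_s: float | None = None  # overrides header / simulation TR
    voxel_p: float = 0.01
    corrected_alpha: float = 0.05
    alphasim_n_iter: int = 1000
    connectivity: int = 6
    correction: str = "alphasim"  # or "bonferroni"
    seed_mode: str = "ground_truth"  # "config" | "ground_truth" | "peaks"
    seeds: list = field(default_factory=list)  # dicts: label, x_mm, y_mm, z_mm, diameter_mm
    seed_diameter_mm: float = 6.0
    assoc_roi: dict | None = None  # {"center_mm": [...], "radius_mm": r}; None -> ground truth
    covariate_names: tuple[str, ...] = ("age", "education", "nicotine")
    use_variables: tuple[str, ...] = ("duration", "dose")
    rng_seed: int = 0

    def __post_init__(self):
        if self.correction not in ("alphasim", "bonferroni"):
            raise ValueError("correction must be 'alphasim' or 'bonferroni'")
        if self.seed_mode not in ("config", "ground_truth", "peaks"):
            raise ValueError("seed_mode must be 'config', 'ground_truth' or 'peaks'")
        self.covariate_names = _as_tuple(self.covariate_names)
        self.use_variables = _as_tuple(self.use_variables)

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(_listify(self.to_dict()), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("simulation") is not None:
            d["simulation"] = _sim_config_from_dict(d["simulation"])
        if d.get("preprocess") is not None:
            p = dict(d["preprocess"])
            p["band_hz"] = tuple(p["band_hz"])
            d["preprocess"] = PreprocessParams(**p)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def with_seed(self, seed: int) -> "PipelineConfig":
        """Copy with every random stream re-seeded from one integer."""
        sim = (
            dataclasses.replace(self.simulation, seed=seed)
            if self.simulation is not None
            else None
        )
        return dataclasses.replace(self, simulation=sim, rng_seed=seed)


def _listify(obj):
    """YAML-friendly: tuples -> lists, recursively."""
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_listify(v) for v in obj]
    return obj


@dataclass
class PipelineResult:
    alff_report: pd.DataFrame
    fc_reports: dict[str, pd.DataFrame]
    association: pd.DataFrame
    k_min: int | None
    excluded_subjects: list[str]
    output_dir: str


# ---------------------------------------------------------------------
# cohort access


class _Cohort:
    """Lazy view of an on-disk cohort directory."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.dir = Path(config.input_dir)
        self.manifest = io.read_manifest(self.dir / "manifest.tsv")
        self.mask, self.affine = io.read_mask(self.dir / "brain_mask.nii.gz")
        self.voxel_size_mm = float(np.abs(np.diag(self.affine)[:3]).mean())
        truth_path = self.dir / "ground_truth.yaml"
        self.ground_truth = GroundTruth.from_yaml(truth_path) if truth_path.exists() else None
        if config.tr_s is not None:
            self.tr_s = config.tr_s
        elif config.simulation is not None:
            self.tr_s = config.simulation.tr_s
        else:
            first = self.manifest.iloc[0]
            self.tr_s = io.read_bold(self.dir / first["bold_path"]).tr_s

    def bold(self, row) -> np.ndarray:
        return io.read_bold(self.dir / row["bold_path"], tr_s=self.tr_s).data

    def motion(self, row) -> np.ndarray:
        return io.read_motion(self.dir / row["motion_path"])


def _ensure_cohort(config: PipelineConfig) -> None:
    cohort_dir = Path(config.input_dir)
    if (cohort_dir / "manifest.tsv").exists():
        return
    if config.simulation is None:
        raise FileNotFoundError(
            f"no cohort at {cohort_dir} and no simulation configured"
        )
    logger.info("simulating cohort into %s", cohort_dir)
    generate_cohort(config.simulation, cohort_dir)


# ---------------------------------------------------------------------
# stages


def stage_simulate(config: PipelineConfig) -> pd.DataFrame:
    _ensure_cohort(config)
    return io.read_manifest(Path(config.input_dir) / "manifest.tsv")


def _included_rows(cohort: _Cohort) -> tuple[list, list[str]]:
    """Motion screen: subject-level exclusion."""
    included, excluded = [], []
    for _, row in cohort.manifest.iterrows():
        result = screen_motion(cohort.motion(row), cohort.config.preprocess)
        if result.passed:
            included.append(row)
        else:
            excluded.append(str(row["subject_id"]))
            logger.warning(
                "excluding %s: motion limits exceeded at %d frames",
                row["subject_id"], len(result.offending_frames),
            )
    return included, excluded


def _preprocessed(cohort: _Cohort, row) -> np.ndarray:
    return preprocess_series(
        cohort.bold(row), cohort.tr_s, cohort.voxel_size_mm, cohort.config.preprocess
    )


def stage_alff(config: PipelineConfig) -> tuple[dict[str, np.ndarray], list[str]]:
    """Per-subject standardized ALFF maps, written under ``alff/``."""
    cohort = _Cohort(config)
    out = Path(config.output_dir) / "alff"
    out.mkdir(parents=True, exist_ok=True)
    included, excluded = _included_rows(cohort)
    maps: dict[str, np.ndarray] = {}
    for row in included:
        clean = _preprocessed(cohort, row)
        amap = standardize_alff(
            alff_map(clean, cohort.mask, cohort.tr_s, config.preprocess.band_hz,
                     affine=cohort.affine)
        )
        maps[row["subject_id"]] = amap.values
        io.write_stat_map(out / f"{row['subject_id']}_malff.nii.gz", amap.values, cohort.affine)
    io.write_provenance(out / "provenance.json", "alff", config.to_yaml(),
                        sorted(f"{s}_malff.nii.gz" for s in maps))
    return maps, excluded


def _load_malff(config: PipelineConfig, cohort: _Cohort) -> dict[str, np.ndarray]:
    out = Path(config.output_dir) / "alff"
    maps = {}
    for _, row in cohort.manifest.iterrows():
        p = out / f"{row['subject_id']}_malff.nii.gz"
        if p.exists():
            import nibabel as nib

            maps[row["subject_id"]] = np.asarray(nib.load(p).dataobj, dtype=float)
    if not maps:
        raise FileNotFoundError(f"no ALFF maps under {out}; run the alff stage first")
    return maps


def _k_min_and_threshold(config: PipelineConfig, cohort: _Cohort, df: int) -> tuple[int, float]:
    """Corrected inference settings for the chosen mode.

    alphasim: voxel threshold at ``voxel_p`` + Monte-Carlo minimum extent.
    bonferroni: voxel-level family-wise threshold, extent 1.
    """
    from .group_stats import t_critical

    if config.correction == "bonferroni":
        thr = bonferroni_t_threshold(config.corrected_alpha, df, int(cohort.mask.sum()))
        return 1, thr
    cache = Path(config.output_dir) / "group_alff" / "alphasim.json"
    key = {
        "n_iter": config.alphasim_n_iter,
        "voxel_p": config.voxel_p,
        "corrected_alpha": config.corrected_alpha,
        "connectivity": config.connectivity,
        "fwhm_mm": config.preprocess.fwhm_mm,
        "rng_seed": config.rng_seed,
        "n_mask": int(cohort.mask.sum()),
    }
    if cache.exists():
        stored = json.loads(cache.read_text())
        if stored.get("key") == key:
            return int(stored["k_min"]), t_critical(config.voxel_p, df)
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 0xA5]))
    result = alphasim_min_extent(
        cohort.mask,
        config.preprocess.fwhm_mm,
        cohort.voxel_size_mm,
        voxel_p=config.voxel_p,
        corrected_alpha=config.corrected_alpha,
        n_iter=config.alphasim_n_iter,
        connectivity=config.connectivity,
        rng=rng,
    )
    cache.parent.mkdir(parents=True, exist_ok=True)
    cache.write_text(json.dumps({"key": key, "k_min": result.k_min}))
    return result.k_min, t_critical(config.voxel_p, df)


def stage_group_alff(config: PipelineConfig) -> tuple[pd.DataFrame, int]:
    """Between-group mALFF t-map and corrected cluster report."""
    cohort = _Cohort(config)
    maps = _load_malff(config, cohort)
    groups = cohort.manifest.set_index("subject_id")["group"]
    maps_a = [m for s, m in maps.items() if groups[s] == "A"]
    maps_b = [m for s, m in maps.items() if groups[s] == "B"]
    stat = two_sample_t_map(maps_a, maps_b, cohort.mask,
                            voxel_p_threshold=config.voxel_p, affine=cohort.affine)
    k_min, thr = _k_min_and_threshold(config, cohort, stat.df)
    report = cluster_report(stat, k_min, affine=cohort.affine, t_threshold=thr,
                            connectivity=config.connectivity)
    out = Path(config.output_dir) / "group_alff"
    out.mkdir(parents=True, exist_ok=True)
    io.write_stat_map(out / "alff_tmap.nii.gz", stat.t_values, cohort.affine)
    write_cluster_report(report, out / "alff_report.tsv")
    io.write_provenance(out / "provenance.json", "group_alff", config.to_yaml(),
                        ["alff_tmap.nii.gz", "alff_report.tsv"])
    return report, k_min


def _seed_definitions(config: PipelineConfig, cohort: _Cohort) -> list[dict]:
    if config.seed_mode == "config":
        if not config.seeds:
            raise ValueError("seed_mode 'config' but no seeds listed")
        return [dict(s) for s in config.seeds]
    if config.seed_mode == "ground_truth":
        if cohort.ground_truth is None:
            raise ValueError("seed_mode 'ground_truth' but cohort has no ground truth")
        return [
            {
                "label": f"seed{i}",
                "x_mm": c["seed_center_mm"][0],
                "y_mm": c["seed_center_mm"][1],
                "z_mm": c["seed_center_mm"][2],
                "diameter_mm": config.seed_diameter_mm,
            }
            for i, c in enumerate(cohort.ground_truth.connectivity_effects)
        ]
    # peaks: centres from the group-ALFF cluster report
    report_path = Path(config.output_dir) / "group_alff" / "alff_report.tsv"
    if not report_path.exists():
        raise FileNotFoundError("seed_mode 'peaks' needs the group-alff report first")
    report = pd.read_csv(report_path, sep="\t")
    return [
        {
            "label": f"peak{i}",
            "x_mm": row["x_mm"],
            "y_mm": row["y_mm"],
            "z_mm": row["z_mm"],
            "diameter_mm": config.seed_diameter_mm,
        }
        for i, row in report.iterrows()
    ]


def stage_fc(config: PipelineConfig) -> dict[str, dict[str, np.ndarray]]:
    """Per-subject, per-seed Fisher-z connectivity maps under ``fc/``."""
    cohort = _Cohort(config)
    seed_defs = _seed_definitions(config, cohort)
    out = Path(config.output_dir) / "fc"
    out.mkdir(parents=True, exist_ok=True)
    included, _ = _included_rows(cohort)
    n_discard = config.preprocess.n_discard
    z_maps: dict[str, dict[str, np.ndarray]] = {d["label"]: {} for d in seed_defs}
    rois = {
        d["label"]: resolve_sphere(
            (d["x_mm"], d["y_mm"], d["z_mm"]), d["diameter_mm"],
            cohort.mask, cohort.affine, label=d["label"],
        )
        for d in seed_defs
    }
    for row in included:
        clean = _preprocessed(cohort, row)
        motion = cohort.motion(row)[n_discard:]
        flat = regress_out_nuisance(clean[cohort.mask], motion)
        resid = np.zeros_like(clean)
        resid[cohort.mask] = flat
        for label, roi in rois.items():
            seed_series = regress_out_nuisance(extract_seed_series(clean, roi), motion)
            fcm = fc_map_subject(seed_series, resid, cohort.mask, seed_label=label,
                                 subject_id=row["subject_id"], affine=cohort.affine)
            zmap = fc_z_map(fcm)
            z_maps[label][row["subject_id"]] = zmap.values
            io.write_stat_map(out / f"{row['subject_id']}__{label}_z.nii.gz",
                              zmap.values, cohort.affine)
    seed_table = pd.DataFrame(seed_defs)
    seed_table.to_csv(out / "seeds.tsv", sep="\t", index=False)
    io.write_provenance(out / "provenance.json", "fc", config.to_yaml(), ["seeds.tsv"])
    return z_maps


def stage_group_fc(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Between-group FC statistics per seed; combined corrected report."""
    cohort = _Cohort(config)
    out_fc = Path(config.output_dir) / "fc"
    seeds = pd.read_csv(out_fc / "seeds.tsv", sep="\t")
    groups = cohort.manifest.set_index("subject_id")["group"]
    reports: dict[str, pd.DataFrame] = {}
    combined = []
    out = Path(config.output_dir) / "group_fc"
    out.mkdir(parents=True, exist_ok=True)
    for _, sd in seeds.iterrows():
        label = sd["label"]
        import nibabel as nib

        z_maps, z_groups = [], []
        for sid, grp in groups.items():
            p = out_fc / f"{sid}__{label}_z.nii.gz"
            if p.exists():
                z_maps.append(np.asarray(nib.load(p).dataobj, dtype=float))
                z_groups.append(grp)
        stats_maps = group_fc_maps(z_maps, z_groups, cohort.mask,
                                   voxel_p_threshold=config.voxel_p, affine=cohort.affine)
        between = stats_maps["between"]
        k_min, thr = _k_min_and_threshold(config, cohort, between.df)
        roi = resolve_sphere((sd["x_mm"], sd["y_mm"], sd["z_mm"]), sd["diameter_mm"],
                             cohort.mask, cohort.affine, label=label)
        report = cluster_report(between, k_min, affine=cohort.affine, t_threshold=thr,
                                connectivity=config.connectivity,
                                exclude_voxels=roi.voxels)
        report.insert(0, "seed", label)
        reports[label] = report
        combined.append(report)
        io.write_stat_map(out / f"{label}_between_tmap.nii.gz",
                          between.t_values, cohort.affine)
    full = (
        pd.concat(combined, ignore_index=True)
        if combined
        else pd.DataFrame(columns=["seed", "x_mm", "y_mm", "z_mm", "peak_t", "cluster_size", "sign"])
    )
    write_cluster_report(full, out / "fc_report.tsv")
    io.write_provenance(out / "provenance.json", "group_fc", config.to_yaml(), ["fc_report.tsv"])
    return reports


def stage_assoc(config: PipelineConfig) -> pd.DataFrame:
    """Regional mALFF vs drug-use partial correlations in group B."""
    cohort = _Cohort(config)
    maps = _load_malff(config, cohort)
    if config.assoc_roi is not None:
        center = tuple(config.assoc_roi["center_mm"])
        radius = float(config.assoc_roi["radius_mm"])
    elif cohort.ground_truth is not None and cohort.ground_truth.effect_rois:
        roi0 = cohort.ground_truth.effect_rois[0]
        center, radius = tuple(roi0["center_mm"]), float(roi0["radius_mm"])
    else:
        raise ValueError("no association ROI configured and no ground truth available")
    vox = sphere_voxel_indices(center, radius, cohort.mask, cohort.affine)
    from .alff import AlffMap

    regional = {
        sid: regional_mean_alff(
            AlffMap(values=m, mask=cohort.mask, band_hz=config.preprocess.band_hz,
                    standardized=True),
            vox,
        )
        for sid, m in maps.items()
    }
    table = clinical.alff_use_association(
        regional, cohort.manifest,
        use_variables=config.use_variables,
        covariate_names=config.covariate_names,
    )
    out = Path(config.output_dir) / "assoc"
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "association.tsv", sep="\t", index=False)
    # scatter-plot source data: (use variable, regional mALFF) pairs
    sub = cohort.manifest[cohort.manifest["group"] == "B"]
    scatter = pd.DataFrame(
        {
            "subject_id": sub["subject_id"],
            "regional_malff": [regional.get(s, np.nan) for s in sub["subject_id"]],
            **{v: sub[v].to_numpy() for v in config.use_variables if v in sub},
        }
    )
    scatter.to_csv(out / "scatter_data.tsv", sep="\t", index=False)
    io.write_provenance(out / "provenance.json", "assoc", config.to_yaml(),
                        ["association.tsv", "scatter_data.tsv"])
    return table


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage in order; deterministic given (config, seed)."""
    stage = "simulate"
    try:
        stage_simulate(config)
        stage = "alff"
        _, excluded = stage_alff(config)
        stage = "group_alff"
        alff_report, k_min = stage_group_alff(config)
        stage = "fc"
        stage_fc(config)
        stage = "group_fc"
        fc_reports = stage_group_fc(config)
        stage = "assoc"
        association = stage_assoc(config)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage '{stage}': {exc}") from exc
    return PipelineResult(
        alff_report=alff_report,
        fc_reports=fc_reports,
        association=association,
        k_min=k_min,
        excluded_subjects=excluded,
        output_dir=str(config.output_dir),
    )
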