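"""Synthetic two-group resting-state BOLD cohorts with planted effects.

The generator emulates the statistical structure a resting-state ALFF /
seed-connectivity analysis assumes: every in-mask voxel carries a
band-limited (default 0.01-0.08 Hz) stochastic signal plus AR(1) noise and
a slow linear drift, all on a common grid (the data are "already aligned",
so no realignment or normalization step exists downstream).  Effects are
planted in two ways:

* **Amplitude ROIs** -- spherical regions whose band-limited signal is
  scaled by ``amplitude_ratio`` in group B (the "patient" group), producing
  a known ALFF group difference.
* **Connectivity effects** -- a seed sphere and a target sphere whose
  voxels share a common latent band-limited signal with a group-specific
  mixing weight ``w`` (voxel = sqrt(1-w^2)*private + w*shared), producing a
  known seed-based correlation difference between groups.

Group B additionally receives drug-use covariates (duration in months,
daily dose in g/day) drawn so that longer/heavier use goes with *lower*
planted ROI amplitude, giving a recoverable negative partial correlation
between regional standardized ALFF and use history.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning, so a cohort is bit-reproducible
from its configuration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.signal import lfilter

from .coords import make_affine, sphere_voxel_indices
from .preprocess import band_bin_mask

__all__ = [
    "EffectRoi",
    "ConnectivityEffect",
    "SimulationConfig",
    "GroundTruth",
    "SubjectData",
    "make_brain_mask",
    "generate_subject",
    "simulate_cohort",
    "generate_cohort",
]

GROUP_A = "A"  # control-like group
GROUP_B = "B"  # patient-like group (carries amplitude ratios and drug use)


@dataclass(frozen=True)
class EffectRoi:
    """A spherical region with a planted group-B/group-A amplitude ratio."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    amplitude_ratio: float = 1.0

    def __post_init__(self):
        if self.amplitude_ratio < 0:
            raise ValueError("amplitude_ratio must be >= 0")


@dataclass(frozen=True)
class ConnectivityEffect:
    """A seed-target sphere pair sharing a latent signal with per-group
    mixing weights in [0, 1]."""

    seed_center_mm: tuple[float, float, float]
    target_center_mm: tuple[float, float, float]
    radius_mm: float = 6.0
    weight_a: float = 0.0
    weight_b: float = 0.0

    def __post_init__(self):
        for w in (self.weight_a, self.weight_b):
            if not 0.0 <= w <= 1.0:
                raise ValueError("connectivity weights must lie in [0, 1]")


# Cohort demographics emulate a two-group adult male sample matched on age,
# education and smoking, with heroin-use history for group B (mean 81.5 +/-
# 33.9 months, 0.71 +/- 0.35 g/day, truncated at zero).
_COVARIATE_DISTS = {
    "age": (34.1, 6.8),
    "education": (10.4, 2.6),
    "nicotine": (19.2, 4.5),
    "duration": (81.5, 33.9),
    "dose": (0.71, 0.35),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the synthetic cohort.

    Defaults follow the emulated acquisition: TR = 2 s, 155 acquired
    volumes (5 min 10 s), 15 controls vs 17 patients, 3 mm isotropic
    voxels on a 24 x 24 x 18 grid, signal band 0.01-0.08 Hz.
    """

    grid_dims: tuple[int, int, int] = (24, 24, 18)
    voxel_size_mm: float = 3.0
    tr_s: float = 2.0
    n_volumes_acquired: int = 155
    n_per_group: tuple[int, int] = (15, 17)  # (group A, group B)
    band_hz: tuple[float, float] = (0.01, 0.08)
    signal_sd: float = 1.0
    noise_sd: float = 0.5
    ar1_coef: float = 0.3
    drift_slope_sd: float = 0.005  # signal units per frame
    effect_rois: tuple[EffectRoi, ...] = (
        EffectRoi(center_mm=(9.0, 12.0, 3.0), radius_mm=6.0, amplitude_ratio=1.5),
    )
    connectivity_effects: tuple[ConnectivityEffect, ...] = (
        ConnectivityEffect(
            seed_center_mm=(9.0, 12.0, 3.0),
            target_center_mm=(-18.0, -9.0, 9.0),
            radius_mm=6.0,
            weight_a=0.8,
            weight_b=0.2,
        ),
    )
    # Between-subject lognormal spread of each subject's ROI amplitude
    # multiplier; also the handle the drug-use coupling acts through.
    subject_amp_sd: float = 0.15
    duration_coupling: float = 0.8  # |corr| of duration with the amplitude latent
    dose_coupling: float = 0.8
    motion_sd_mm: float = 0.01  # random-walk step SD
    motion_sd_deg: float = 0.01
    inject_motion_violator: bool = False
    seed: int = 0

    def __post_init__(self):
        if any(d < 8 for d in self.grid_dims):
            raise ValueError("all grid dimensions must be >= 8")
        if self.n_volumes_acquired * self.tr_s < 1.0 / self.band_hz[0]:
            raise ValueError(
                "scan too short: need at least one full cycle of the "
                "slowest band frequency"
            )
        if not 0.0 <= self.ar1_coef < 1.0:
            raise ValueError("ar1_coef must lie in [0, 1)")

    @property
    def affine(self) -> np.ndarray:
        return make_affine(self.grid_dims, self.voxel_size_mm)

    def null(self) -> "SimulationConfig":
        """A copy with every planted effect removed (exchangeable groups)."""
        return dataclasses.replace(
            self,
            effect_rois=tuple(
                dataclasses.replace(r, amplitude_ratio=1.0) for r in self.effect_rois
            ),
            connectivity_effects=tuple(
                dataclasses.replace(c, weight_a=c.weight_a, weight_b=c.weight_a)
                for c in self.connectivity_effects
            ),
            duration_coupling=0.0,
            dose_coupling=0.0,
        )


@dataclass
class GroundTruth:
    """Planted-effect record emitted alongside a cohort, for recovery tests."""

    effect_rois: list[dict]
    connectivity_effects: list[dict]
    duration_coupling: float
    dose_coupling: float
    seed: int

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class SubjectData:
    subject_id: str
    group: str
    bold: np.ndarray  # (X, Y, Z, T)
    motion: np.ndarray  # (T, 6)
    covariates: dict


def make_brain_mask(config: SimulationConfig) -> np.ndarray:
    """Centred ellipsoidal brain mask, strictly inside the grid bounds."""
    dims = np.asarray(config.grid_dims, dtype=float)
    center = (dims - 1.0) / 2.0
    semi = dims / 2.0 - 1.5
    grid = np.indices(config.grid_dims).astype(float)
    r2 = sum(((grid[a] - center[a]) / semi[a]) ** 2 for a in range(3))
    return r2 <= 1.0


def _resolve_roi(center_mm, radius_mm, mask, affine, require_inside=True) -> np.ndarray:
    vox = sphere_voxel_indices(center_mm, radius_mm, mask, affine)
    if require_inside:
        full = sphere_voxel_indices(
            center_mm, radius_mm, np.ones(mask.shape, dtype=bool), affine
        )
        if len(vox) != len(full):
            raise ValueError(
                f"planted ROI at {tuple(center_mm)} (r={radius_mm} mm) is not "
                "fully inside the brain mask"
            )
    if len(vox) == 0:
        raise ValueError(f"ROI at {tuple(center_mm)} resolves to no mask voxels")
    return vox


def _band_noise(rng: np.random.Generator, shape_t: tuple, tr_s: float, band) -> np.ndarray:
    """Unit-variance band-limited Gaussian signal: white noise ideally
    filtered to the band in the frequency domain, rescaled so the expected
    variance is 1."""
    t_len = shape_t[-1]
    keep = band_bin_mask(t_len, tr_s, band).copy()
    keep[0] = False
    if t_len % 2 == 0:
        keep[-1] = False
    white = rng.standard_normal(shape_t)
    spec = np.fft.rfft(white, axis=-1)
    spec[..., ~keep] = 0.0
    filtered = np.fft.irfft(spec, n=t_len, axis=-1)
    n_kept = int(keep.sum())
    return filtered * np.sqrt(t_len / (2.0 * n_kept))


def _ar1_noise(rng: np.random.Generator, shape_t: tuple, sd: float, phi: float) -> np.ndarray:
    """Stationary AR(1) noise with marginal SD ``sd`` (burn-in discarded)."""
    if sd == 0:
        return np.zeros(shape_t)
    burn = 50
    t_len = shape_t[-1]
    innov = rng.standard_normal(shape_t[:-1] + (t_len + burn,))
    innov *= sd * np.sqrt(1.0 - phi**2)
    series = lfilter([1.0], [1.0, -phi], innov, axis=-1)
    return series[..., burn:]


def generate_subject(
    config: SimulationConfig,
    group: str,
    subject_rng: np.random.Generator,
    mask: np.ndarray | None = None,
    roi_amp_modifiers: dict[int, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One subject's 4D BOLD series and T x 6 motion trace.

    ``roi_amp_modifiers`` maps effect-ROI index -> multiplicative subject
    modifier of that ROI's amplitude factor (used by the cohort generator
    to couple drug-use covariates to ROI amplitude); default 1.
    """
    if group not in (GROUP_A, GROUP_B):
        raise ValueError(f"unknown group label {group!r}; expected 'A' or 'B'")
    if mask is None:
        mask = make_brain_mask(config)
    affine = config.affine
    t_len = config.n_volumes_acquired
    n_vox = int(mask.sum())

    signal = config.signal_sd * _band_noise(subject_rng, (n_vox, t_len), config.tr_s, config.band_hz)

    # Flat index of each mask voxel inside the (n_vox, T) signal array.
    flat_of_voxel = np.full(mask.shape, -1, dtype=int)
    flat_of_voxel[mask] = np.arange(n_vox)

    # Shared latent signals create seed-target connectivity.
    for eff in config.connectivity_effects:
        w = eff.weight_a if group == GROUP_A else eff.weight_b
        shared = config.signal_sd * _band_noise(
            subject_rng, (t_len,), config.tr_s, config.band_hz
        )
        if w == 0:
            continue
        for center in (eff.seed_center_mm, eff.target_center_mm):
            vox = _resolve_roi(center, eff.radius_mm, mask, affine)
            rows = flat_of_voxel[tuple(vox.T)]
            signal[rows] = np.sqrt(1.0 - w**2) * signal[rows] + w * shared

    # Amplitude ratios scale the band-limited signal in group B.
    for i, roi in enumerate(config.effect_rois):
        factor = 1.0
        if group == GROUP_B:
            factor = roi.amplitude_ratio
        if roi_amp_modifiers:
            factor *= roi_amp_modifiers.get(i, 1.0)
        if factor != 1.0:
            vox = _resolve_roi(roi.center_mm, roi.radius_mm, mask, affine)
            signal[flat_of_voxel[tuple(vox.T)]] *= factor

    noise = _ar1_noise(subject_rng, (n_vox, t_len), config.noise_sd, config.ar1_coef)
    slopes = subject_rng.normal(0.0, config.drift_slope_sd, size=(n_vox, 1))
    drift = slopes * (np.arange(t_len) - (t_len - 1) / 2.0)

    bold = np.zeros(config.grid_dims + (t_len,), dtype=float)
    bold[mask] = signal + noise + drift

    steps = np.column_stack(
        [
            subject_rng.normal(0.0, config.motion_sd_mm, size=(t_len, 3)),
            subject_rng.normal(0.0, config.motion_sd_deg, size=(t_len, 3)),
        ]
    )
    motion = np.cumsum(steps, axis=0)
    return bold, motion


def _truncated_normal(rng, mean, sd, size):
    """Normal draws redrawn until non-negative (light truncation)."""
    out = rng.normal(mean, sd, size=size)
    for _ in range(100):
        neg = out < 0
        if not neg.any():
            break
        out[neg] = rng.normal(mean, sd, size=int(neg.sum()))
    return np.clip(out, 0.0, None)


def simulate_cohort(config: SimulationConfig) -> tuple[list[SubjectData], GroundTruth, np.ndarray]:
    """Generate the full in-memory cohort: subjects, ground truth, mask."""
    n_a, n_b = config.n_per_group
    if n_a < 2 or n_b < 2:
        raise ValueError("need at least 2 subjects per group for group statistics")
    mask = make_brain_mask(config)
    affine = config.affine
    for roi in config.effect_rois:
        _resolve_roi(roi.center_mm, roi.radius_mm, mask, affine)
    for eff in config.connectivity_effects:
        _resolve_roi(eff.seed_center_mm, eff.radius_mm, mask, affine)
        _resolve_roi(eff.target_center_mm, eff.radius_mm, mask, affine)

    n_total = n_a + n_b
    seq = np.random.SeedSequence(config.seed)
    child_seqs = seq.spawn(n_total + 1)
    cov_rng = np.random.default_rng(child_seqs[-1])

    groups = [GROUP_A] * n_a + [GROUP_B] * n_b
    age = _truncated_normal(cov_rng, *_COVARIATE_DISTS["age"], n_total)
    edu = _truncated_normal(cov_rng, *_COVARIATE_DISTS["education"], n_total)
    nic = _truncated_normal(cov_rng, *_COVARIATE_DISTS["nicotine"], n_total)

    # Latent per-subject amplitude factor u drives both the ROI amplitude
    # modifier exp(tau*u) and (negatively) the drug-use covariates.
    u = cov_rng.standard_normal(n_total)
    rho_dur, rho_dose = config.duration_coupling, config.dose_coupling
    eps_dur = cov_rng.standard_normal(n_total)
    eps_dose = cov_rng.standard_normal(n_total)
    mu_d, sd_d = _COVARIATE_DISTS["duration"]
    mu_g, sd_g = _COVARIATE_DISTS["dose"]
    duration = mu_d + sd_d * (-rho_dur * u + np.sqrt(1 - rho_dur**2) * eps_dur)
    dose = mu_g + sd_g * (-rho_dose * u + np.sqrt(1 - rho_dose**2) * eps_dose)
    duration = np.clip(duration, 0.0, None)
    dose = np.clip(dose, 0.0, None)

    violator_idx = cov_rng.integers(n_total) if config.inject_motion_violator else -1

    subjects: list[SubjectData] = []
    for i, group in enumerate(groups):
        rng = np.random.default_rng(child_seqs[i])
        modifiers = {
            j: float(np.exp(config.subject_amp_sd * u[i]))
            for j in range(len(config.effect_rois))
        }
        bold, motion = generate_subject(config, group, rng, mask=mask, roi_amp_modifiers=modifiers)
        if i == violator_idx:
            motion = motion.copy()
            motion[config.n_volumes_acquired // 2 :, 0] += 1.5
        cov = {
            "age": float(age[i]),
            "education": float(edu[i]),
            "nicotine": float(nic[i]),
            "duration": float(duration[i]) if group == GROUP_B else np.nan,
            "dose": float(dose[i]) if group == GROUP_B else np.nan,
        }
        subjects.append(
            SubjectData(
                subject_id=f"sub-{i + 1:03d}",
                group=group,
                bold=bold,
                motion=motion,
                covariates=cov,
            )
        )

    truth = GroundTruth(
        effect_rois=[dataclasses.asdict(r) for r in config.effect_rois],
        connectivity_effects=[dataclasses.asdict(c) for c in config.connectivity_effects],
        duration_coupling=config.duration_coupling,
        dose_coupling=config.dose_coupling,
        seed=config.seed,
    )
    return subjects, truth, mask


def generate_cohort(config: SimulationConfig, out_dir) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a cohort and write it to disk.

    Layout: one ``<id>_bold.nii.gz`` and one ``rp_<id>.txt`` (SPM-style
    6-column motion trace) per subject, a ``manifest.tsv`` and a
    ``ground_truth.yaml``.  Also writes ``brain_mask.nii.gz``.
    """
    from .io import write_bold, write_mask, write_motion  # local import: io imports us

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    subjects, truth, mask = simulate_cohort(config)
    affine = config.affine

    rows = []
    for sub in subjects:
        bold_path = out_dir / f"{sub.subject_id}_bold.nii.gz"
        motion_path = out_dir / f"rp_{sub.subject_id}.txt"
        write_bold(bold_path, sub.bold, affine, config.tr_s)
        write_motion(motion_path, sub.motion)
        rows.append(
            {
                "subject_id": sub.subject_id,
                "group": sub.group,
                **sub.covariates,
                "bold_path": bold_path.name,
                "motion_path": motion_path.name,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    truth.to_yaml(out_dir / "ground_truth.yaml")
    write_mask(out_dir / "brain_mask.nii.gz", mask, affine)
    return manifest, truth
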