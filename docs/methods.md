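# Methods

This note documents the models, conventions and design choices behind
`restalff`, and what the synthetic validation does and does not show.

## Analysis chain

Stages run in the order: discard initial volumes → subject-level motion
screen → spatial smoothing → linear detrending → band-pass filtering →
ALFF → group statistics → seed FC → clinical associations. The data are
assumed already aligned to a common grid (realignment and spatial
normalization are out of scope; motion traces are consumed as inputs, not
estimated).

### Preprocessing

* **Volume discard** — the first `n_discard` (default 5) frames are
  dropped to remove magnetization non-equilibrium; 155 acquired volumes at
  TR 2 s leave 150 for analysis.
* **Motion screen** — a subject is excluded (not frame-censored) when any
  translation exceeds 1 mm or any rotation exceeds 1° in absolute value at
  any frame. The comparison is strict (`>`), so a trace touching the limit
  exactly passes.
* **Smoothing** — isotropic Gaussian, FWHM 8 mm
  (σ = FWHM / (2√(2 ln 2)) voxels after scaling by voxel size). Boundary
  mode is replicate-nearest to avoid rim attenuation inside small masks;
  configurable.
* **Detrending** — least-squares removal of intercept + slope per voxel.
* **Band-pass** — ideal (brick-wall) frequency-domain filter: DFT bins
  with frequency in the closed interval [0.01, 0.08] Hz are retained,
  everything else including DC is zeroed. An ideal filter was chosen over
  an IIR family because it makes the ALFF band edges exact and the filter
  idempotent; band-edge bins are included on both sides. A consequence,
  asserted in tests, is that ALFF commutes with the filter: computing ALFF
  before or after band-passing gives identical values, since ALFF reads
  only in-band bins.

### ALFF

The single-sided amplitude convention is a_k = (2/T)·|X_k| for
0 < k < T/2, so a unit-amplitude sinusoid sitting exactly on a bin has
amplitude 1; DC and the Nyquist bin never contribute. ALFF is the
arithmetic mean of a_k over in-band bins (no interpolation between bins).
The convention is validated by a Parseval identity
(Σ a_k²·T/2 + Nyquist term = Σ(x−x̄)²). Any fixed convention cancels under
global-mean standardization (mALFF: each in-mask voxel divided by the
in-mask mean), which is what enters all cross-subject statistics.

### Group statistics

Pooled-variance (Student) two-sample t per voxel, df = n_A + n_B − 2,
sign B − A. Zero-pooled-variance voxels get t = 0 with a warning. Cluster
correction is AlphaSim-style: per Monte-Carlo iteration, unit Gaussian
noise on the mask's grid is smoothed to the analysis FWHM,
re-standardized within the mask, thresholded two-tailed at the voxel p,
and the largest connected component recorded; k_min is the smallest
extent whose null frequency is ≤ the corrected alpha. Clusters of size
≥ k_min survive. Defaults: voxel p 0.01, corrected alpha 0.05, 1000
iterations, face (6-) connectivity (18 and 26 available — AlphaSim
dialects differ on this, so it is explicit). The null-field smoothness is
taken from the applied smoothing kernel, not estimated from residuals;
since the amplitude maps are if anything *less* smooth than the smoothed
series (amplitude correlation decays roughly as the squared series
correlation), this choice errs conservative. The family-wise-error
alternative is Bonferroni over in-mask voxels (random-field theory is out
of scope). Peak-|t| ties inside a cluster break to the lexicographically
smallest voxel index; reports carry world (mm) coordinates only.

The printed reference threshold 2.7633 corresponds to two-tailed
alpha = 0.01 at df = 28, whereas 15 + 17 − 2 = 30 gives 2.7500; the
package always derives df from its actual inputs and exposes
`t_critical(alpha, df)` so both values are checkable.

### Seed FC

"Diameter 6 mm" is read literally (radius 3 mm): on a 3 mm grid centred
on a voxel this resolves to the centre plus its six face neighbours
(distance exactly 3 mm, inclusive). The seed mean series is computed
first and then residualized against [intercept, 6 motion parameters] —
equivalent, for a linear operation, to averaging residualized voxels
(asserted in tests). Only motion is regressed; no global-signal or tissue
regressors. Fisher z uses atanh with |r| clipped at 1 − 1e−7 (a seed's
own voxels reach r = 1). Seed-sphere voxels are excluded from
between-group cluster reports to keep trivial self-connectivity out of
the tables. Seeds come from an explicit config list, from the simulator's
ground truth, or from the peaks of the group-ALFF report
(`peak_difference_voxel`: max |t| within a region, lexicographic
tie-break).

### Clinical associations

Partial correlation by residualization (numerically identical to the
precision-matrix/recursive formula, asserted in tests), p two-tailed from
t = r√((n−2−k)/(1−r²)) on df = n−2−k. With n = 17 group-B subjects and 3
covariates, df = 12. Demographic group tests use the pooled-variance t —
also available from per-group summary statistics (mean, SD, n), which
reproduces matching-table p-values of ≈0.87 (age) and ≈0.31 (cigarettes
per day) from summaries rounded to one decimal; a Welch flag exists.
Drug-use variables are reported without multiplicity correction by
default, with an optional Bonferroni flag.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
not scanner physics. Defaults define the study conditions: 24×24×18 grid
at 3 mm isotropic, ellipsoidal brain mask (~3400 voxels), TR 2 s, 155
volumes, groups of 15 (A) and 17 (B), band 0.01–0.08 Hz.

Each in-mask voxel carries, per subject:

* a **band-limited signal** (white Gaussian noise ideally filtered to the
  band, rescaled to unit expected variance) — matching the analysis
  filter exactly, so spectral placement is not an artifact of leakage;
* **AR(1) noise**, marginal SD 0.5, lag-1 coefficient 0.3 (a mild
  within-band-flat noise floor, roughly 2:1 in-band signal-to-noise);
* a **linear drift** with per-voxel slope ~ N(0, 0.005/frame), small
  enough that ≥ 90% of no-noise variance stays in band.

**Planted amplitude effect**: inside a 6 mm-radius sphere the band signal
of group-B subjects is multiplied by `amplitude_ratio` (default 1.5 — the
emulated study reports no ALFF effect sizes, so this is a chosen,
moderately strong test point). Each subject additionally carries a
lognormal ROI modifier exp(0.15·u), u ~ N(0,1), in both groups: it
provides realistic between-subject amplitude spread and is the handle the
drug-use coupling acts through.

**Planted connectivity effect**: voxels of a seed sphere and a target
sphere share a latent band-limited signal with group-specific weight w
(voxel = √(1−w²)·private + w·shared; defaults 0.8 in A vs 0.2 in B),
giving a seed-target correlation difference of known sign. A side effect,
deliberate and documented: coherent neighbours add constructively under
spatial smoothing, so a *difference* in w also produces an ALFF
difference at the seed and target. The amplitude-recovery study therefore
plants no connectivity effect, and vice-versa the amplitude ratio leaves
correlations untouched (scaling invariance), so the FC study needs no
such isolation.

**Covariates**: age ~ N(34.1, 6.8), education ~ N(10.4, 2.6) years,
nicotine ~ N(19.2, 4.5) cigarettes/day for everyone; group B adds heroin
use duration ~ N(81.5, 33.9) months and dose ~ N(0.71, 0.35) g/day,
truncated at zero, constructed from the same latent u with correlation
−0.8 (duration) and −0.8 (dose), so longer/heavier use accompanies lower
planted ROI amplitude.

**Motion**: random walks with 0.01 mm / 0.01° steps — all subjects pass
the 1 mm/1° screen by default; a flag injects one violator for testing
the exclusion rule.

All randomness flows from one integer seed through `SeedSequence`
spawning; cohort regeneration is bit-identical.

### What the simulation does not emulate

Scanner artifacts (spikes, ghosting, distortion), physiological noise,
spatial heterogeneity of tissue, realistic anatomy, and any real spatial
normalization error. Passing recovery tests therefore demonstrates the
*statistical machinery* — calibration of the cluster correction, power of
the planted contrasts at these SNRs — not performance on real scans.

## Validation studies and problem sizes

* **Null calibration**: 20 replicate no-effect cohorts (full default
  size); the corrected ALFF report is empty in ≥95% of replicates with
  k_min computed once (1000 iterations) per condition. Observed k_min is
  24 voxels at the default settings.
* **Amplitude recovery**: 25 replicates, detection = a corrected cluster
  of the planted sign whose peak lies within ROI radius + one voxel of
  the planted centre (the one-voxel slack absorbs grid discretization of
  the smoothed peak).
* **Connectivity recovery**: 25 replicates; seed = 6 mm-diameter sphere at
  the planted seed centre; the full planted seed region is excluded from
  the report so self-connectivity never counts as recovery; detection =
  corrected cluster at the target with the planted sign.
* **Association power**: 50 replicates on a reduced 16×16×12 grid with
  the ROI recentred to stay inside the smaller mask (the association
  mechanism is grid-size independent); success = r_partial < 0 and
  p < 0.05. A zero-coupling variant checks the type-I rate stays at the
  nominal 5% (within binomial error).

## Known limitations

* The ideal band-pass assumes stationarity and exact periodic extension;
  very short series (< 16 frames) are rejected rather than padded.
* AlphaSim assumes the applied FWHM describes the null smoothness; on
  real data residual-based smoothness estimation (not implemented) is
  preferable.
* Global-mean standardization couples voxels: a strong regional deficit
  shifts the rest of the brain slightly the other way, which can surface
  as small opposite-signed clusters (visible in the worked example).
* Cluster reports carry coordinates only; no anatomical labelling. The
  MNI→Talairach mapping (Brett's piecewise-affine transform, the
  conventional choice) is provided as a coordinate utility.
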