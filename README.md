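# restalff

Resting-state fMRI analysis of spontaneous low-frequency BOLD activity:
voxel-wise **ALFF** (amplitude of low-frequency fluctuation) with
global-mean standardization, two-sample group comparison with Monte-Carlo
(**AlphaSim-style**) cluster-extent correction, **seed-based functional
connectivity** with head-motion regression and Fisher z-transform, and
**partial correlation** of regional ALFF with clinical covariates — plus a
synthetic two-group BOLD cohort generator with known planted effects so the
entire chain can be validated end to end.

The package is aimed at researchers who want a small, fully tested,
scriptable re-implementation of this classic analysis (the kind usually run
through SPM + REST) operating on NIfTI-1 volumes already aligned to a
common grid.

## The statistics

**ALFF.** For a voxel time series $x_t$ ($t = 0,\dots,T-1$, sampling
interval TR), let $X_k$ be its DFT. The single-sided amplitude at bin $k$
is $a_k = \tfrac{2}{T}\lvert X_k\rvert$, and

$$\mathrm{ALFF} = \frac{1}{\lvert B\rvert}\sum_{k \in B} a_k,\qquad
B = \{k : f_\mathrm{low} \le k/(T\cdot\mathrm{TR}) \le f_\mathrm{high}\},$$

with the band 0.01–0.08 Hz by default. Standardized ALFF (mALFF) divides
each voxel by the whole-brain mean, making maps comparable across
subjects. At the reference window ($T=150$, TR = 2 s) the band covers the
22 DFT bins 3…24.

**Group inference.** Pooled-variance two-sample t at every voxel
($\mathrm{df}=n_A+n_B-2$, sign convention B − A), thresholded at an
uncorrected voxel p (default 0.01, i.e. $|T|>t_{\mathrm{crit}}$); clusters
smaller than a Monte-Carlo minimum extent $k_{\min}$ are discarded.
$k_{\min}$ is the smallest size whose occurrence probability among
suprathreshold clusters of smoothed Gaussian null maps (same mask, same
smoothing FWHM) is at most the corrected alpha (default 0.05). A
Bonferroni voxel-level mode is available as the family-wise-error
alternative.

**Seed FC.** A 6 mm-diameter sphere at a peak-difference voxel; its mean
series and all voxel series are residualized on the six rigid-body motion
parameters; Pearson r maps are Fisher z-transformed
($z=\operatorname{atanh} r$) and passed to within-group one-sample and
between-group two-sample t-tests.

**Clinical association.** Partial correlation by residualization:
regional mALFF and a drug-use variable are each regressed on
[intercept, age, education, nicotine]; the Pearson correlation of the
residuals is tested on $\mathrm{df}=n-2-k$.

## Worked example

Simulate the default two-group cohort (15 vs 17 subjects, 24×24×18 grid at
3 mm, TR 2 s, 155 volumes) with its planted effects — a 1.5× band-amplitude
sphere, a seed–target pair whose shared-signal weight drops from 0.8
(group A) to 0.2 (group B), and a negative coupling between group B's ROI
amplitude and drug-use duration — then run every stage:

```python
from restalff import PipelineConfig, SimulationConfig, run_pipeline

config = PipelineConfig(input_dir="cohort", output_dir="derived",
                        simulation=SimulationConfig(seed=0), rng_seed=0)
result = run_pipeline(config)
print("minimum corrected cluster extent k_min =", result.k_min)
print(result.alff_report.to_string(index=False))
print(result.fc_reports["seed0"].to_string(index=False))
print(result.association.to_string(index=False))
```

Output:

```
minimum corrected cluster extent k_min = 24
 x_mm  y_mm  z_mm     peak_t  cluster_size  sign
-16.5  -7.5  10.5 -24.578739            93    -1
 10.5  10.5   4.5  -8.781333            62    -1
-10.5   4.5 -13.5   5.861186            28     1
 seed  x_mm  y_mm  z_mm     peak_t  cluster_size  sign
seed0 -19.5 -10.5   7.5 -30.296436           169    -1
seed0  10.5  13.5   7.5 -16.608065           128    -1
variable  n  r_partial        p  significant
duration 17  -0.712005 0.004281           True
    dose 17  -0.752410 0.001904           True
```

Reading the numbers: the between-group ALFF map flags the planted
seed (9, 12, 3) and target (−18, −9, 9) regions as *decreased* in group B —
when the shared-signal weight falls, neighbouring voxels lose coherence and
their spatially smoothed amplitude drops — and the global-mean
standardization redistributes that deficit as a smaller positive cluster
elsewhere. The FC comparison recovers the connectivity loss at the target
sphere (peak t ≈ −30 at (−19.5, −10.5, 7.5)). Regional standardized ALFF in
the planted sphere correlates negatively with drug-use duration
(r = −0.71, p = 0.004) and dose after controlling age, education and
nicotine, mirroring the planted coupling.

The same run is available from the shell:

```sh
restalff all --config pipeline.yaml --seed 0
```

with subcommands `simulate`, `alff`, `group-alff`, `fc`, `group-fc`,
`assoc` composing to identical outputs.

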