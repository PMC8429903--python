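# Methods

## Ratiometric readout

Each probe converts from a short-wavelength emitter (Ch1, 400–450 nm) to a
long-wavelength emitter (Ch2, 600–650 nm) as its target enzyme processes it,
so the dimensionless per-voxel ratio *R* = *I*₂/*I*₁ increases monotonically
with enzyme activity and cancels probe concentration, staining efficiency,
and illumination. A sample's summary statistic is the **arithmetic mean of
per-voxel ratios** over all foreground voxels across the imaged depth — the
ratio image is computed first and then averaged, not the ratio of channel
means; the two differ under spatial heterogeneity, and averaging the ratio
image matches how ratiometric sections are produced and then pooled over the
whole sample depth. Every masked voxel is weighted equally across sections;
ratios are never clipped for statistics (clipping applies only to the display
range when rendering).

## Calibrations

`tpmratio.calibration` ships two per-probe, per-class tables of mean ± SD
(dimensionless Ch2/Ch1): whole-depth imaging means and lysate endpoint
(t = 120 min) means, for normal/ulcer/adenoma/cancer gastric tissue. The ±
values are treated as **between-sample** SDs — group spread across subjects —
not within-sample spatial spread, which is a separate generator knob (below).
Reference cohort sizes are normal 21, ulcer 18, adenoma 17, cancer 20
(76 subjects).

One deliberate mapping: the SE1 lysate statistics are quoted in the source
material as "lower in cancer than in normal (1.859 ± 0.053 vs. 1.313 ±
0.051)", where the printed order contradicts the cancer-first convention used
elsewhere. This package honours the stated *direction* — carboxylesterase
activity is reduced in cancer — and assigns 1.313 to cancer and 1.859 to
normal. Both assays therefore agree in sign for every probe, which is the
property the lysate arm exists to check.

## Synthetic tissue phantoms

The generator's defaults define the study conditions; they are not tuned per
experiment.

* **Per-sample mean**: drawn from Normal(μ_class, σ_class) truncated at > 0.
* **Gland geometry**: gastric glands are modelled as tubules (bright annular
  walls, radius 15 μm, wall 6 μm, spacing 40 μm) on a square lattice,
  extruded in z with 0.5 μm per-section wobble. Disorder displaces each
  tubule by up to disorder/2 of the spacing and perturbs radii by ±40% ×
  disorder. Class defaults: normal 0.1, ulcer/adenoma 0.3, cancer 0.6 —
  regular glands in normal mucosa, irregular and disordered in cancer.
* **Within-sample texture**: a Gaussian-smoothed random field (σ = 1 section
  × 2 px), exactly mean-centred and scaled over gland voxels, added with SD
  0.05 (ratio units). The spatial mean over the gland thus equals the drawn
  sample mean exactly; the texture SD is a free choice, as within-sample
  heterogeneity of enzyme activity is not quantified in the calibration
  source.
* **Background**: non-gland voxels carry 1% of gland brightness (weak
  unconverted-probe/background signal).

## Forward imaging model

Noise-free expected counts split a voxel's brightness between the bands:

    B = brightness × photon_budget × exp(−z / L)
    E[Ch2] = B·r/(1+r),   E[Ch1] = B/(1+r)

so Ch1 + Ch2 = B and Ch2/Ch1 = r exactly. Defaults: photon_budget = 500
counts at the brightest surface voxel (chosen so per-voxel ratio CV stays
below ~10% at the surface), attenuation length L = 200 μm (a realistic
scattering length for two-photon imaging in tissue), read noise SD = 2
counts, 64×64 px at 2 μm/px, 30 sections spanning 80–200 μm. Observed counts
are Poisson(E) + N(0, read_noise), clipped at zero. Out of scope by design:
optical PSF/scattering simulation, spectral bleed-through, motion artifacts,
and inter-section registration (simulated stacks are registered by
construction).

The imaged depth window is configurable: both 80–200 μm and 90–210 μm appear
in the source material as the usable range; the generator and analysis
default to 80–200 μm but neither is privileged — `AcquisitionParams
.with_depth_range` switches windows.

Known estimator property: the plain per-voxel ratio ch2/ch1 is convex in
ch1, so Poisson noise inflates the measured mean by roughly (1+r)/E[Ch1]
(~1% at default settings, growing with depth). This bias is inherent to the
readout as practised and is left uncorrected; it is well inside the
between-sample SDs the pipeline is asked to recover.

## Masking

The foreground procedure is this package's construction (the calibration
source does not state one): Otsu thresholding on the summed-channel
intensity, applied **per optical section** by default so that depth
attenuation does not push deep tissue below a global threshold (a global
variant and a percentile method are provided). Voxels with ch1 = 0 or
ch2 = 0 are always excluded — the ratio is undefined or degenerate there —
as are voxels saturated at the 16-bit maximum in either channel, where the
ratio is biased. An empty mask is a hard analysis error with a diagnostic.

## Depth profiles

Per-section mean/min/max/SD of masked ratios within the depth window,
binned by exact z position with no interpolation. Min/max serve as the error
bars of the depth plot (matching how sectional ratio plots are conventionally
annotated); the SD is stored alongside. The aggregation identity — the
voxel-count-weighted mean of per-section means equals the whole-sample mean
to ≤ 1e-9 relative error — is asserted on every pipeline run.

## Group statistics

"t-test or rank-sum as appropriate" is resolved as a Shapiro–Wilk gate at
α = 0.05 per group: both groups normal → Welch's unequal-variance t-test
(group SDs in the calibrations differ up to ~3-fold, so a pooled-variance
test would be wrong); otherwise the Wilcoxon rank-sum (Mann–Whitney U) test,
two-sided, with the exact null for tie-free samples of ≤ 20 per group. Gate
and α are configurable, and the gate can be overridden per call. No
multiple-testing correction is applied by default across the probe ×
class-pair grid (a Bonferroni option exists, off by default).

The threshold classifier maximizes Youden's J over midpoints between
consecutive sorted sample means; direction comes from the probe's calibrated
directionality (SG1: cancer above; SE1: cancer below). Ties in J are broken
toward the widest margin; ties at the threshold are called non-cancer
(conservative). Cut-off selection on real data is explicitly deferred by the
source material, so this rule is a construction of this package, evaluated
only on simulated cohorts.

## Lysate kinetics

Trajectories follow a first-order approach to plateau, R(t) = R∞ − (R∞ −
R0)e^(−kt), sampled at 13 points (0–120 min, every 10 min) with additive
Gaussian noise (SD 0.02). The model form is a modelling choice: the source
shows trajectories but fits no model; first-order conversion is the natural
kinetics for an enzyme acting on a probe well below saturation. Per-sample
curves are calibrated so the **measured** endpoint matches the endpoint
table: the latent endpoint is drawn with SD sqrt(σ² − noise²) and the noise
restores the printed total SD. Defaults k = 0.04 /min and per-probe R0
(SG1 0.45, SE1 0.50, SHC 0.20) are fixed baselines of the unconverted
probes. The endpoint statistic is the t = 120 min value (one value per
sample, matching how endpoint box plots are drawn), not a window average.
Fits use bounded nonlinear least squares (k ≥ 0), initialized from the first
point, last point, and a two-point log-linear rate estimate; flat series
short-circuit to the exact degenerate solution; non-convergence is reported
in the fit record, never raised. Wavelength-resolved spectra are out of
scope — only the two band-integrated channels are modelled.

## Rendering

Pseudocolor sections encode the ratio (clipped to a display range) through a
colormap and modulate brightness by the summed-channel intensity normalized
to the stack's foreground maximum; background renders black. The default
display range spans mean ± 2 SD of both the normal and cancer calibration
anchors, taking the min/max across the two so the range stays ordered for
probes whose ratio falls in cancer as well as those where it rises.

## Problem sizes and determinism

Default simulations use 64×64×30 voxel stacks (about 123k voxels; ~65 ms per
sample end-to-end), which gives thousands of foreground voxels per sample —
ample for the per-sample mean, whose uncertainty is dominated by
between-sample variation, not voxel noise. The test suite's
parameter-recovery checks average three independent reference-size cohorts
per probe × class and compare at 2 SE of the calibrated SD at the per-cohort
n: the replicate averaging reduces estimator variance so the check probes
bias rather than single-cohort sampling luck, while the tolerance stays at
the single-cohort scale. All randomness flows through integer seeds via
`numpy.random.SeedSequence`; sample-level streams for phantom construction,
rendering, and lysate noise are tagged sub-streams of the same seed, so
cohorts are bit-reproducible from one master seed.

## What passing tests do and do not show

The phantoms reproduce the *statistical* structure the analysis assumes —
per-class between-sample ratio distributions, gland-shaped brightness,
depth attenuation, shot noise — not real tissue. Passing recovery tests
shows the pipeline is an unbiased, correctly wired estimator of the
quantities it claims to measure under that model; it cannot validate the
biology (enzyme levels, probe penetration, pH effects) or imaging physics
(scattering, autofluorescence) that the generator idealizes away. Real-data
limitations flagged by the source — weak gland contrast in acidic stomach
tissue, depth access limited to ~200 μm — are inherited, not solved, here.
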