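# tpmratio

Ratiometric two-photon microscopy (TPM) analysis of enzyme-selective
fluorescent probes for gastric-tissue diagnosis — with a calibrated
synthetic-tissue generator, since the underlying clinical image data are not
publicly deposited.

## The problem

Ratiometric TPM probes shift their emission from a short band (Ch1,
400–450 nm) to a long band (Ch2, 600–650 nm) when converted by a target
enzyme, so the per-voxel intensity ratio

&nbsp;&nbsp;&nbsp;&nbsp;*R* = *I*<sub>Ch2</sub> / *I*<sub>Ch1</sub>

reports enzyme activity independently of probe concentration and
illumination. Three probes are modelled: **SG1** (β-galactosidase, ratio
rises in gastric cancer), **SE1** (carboxylesterase, ratio falls), and
**SHC** (hNQO1, no appreciable contrast in stomach). A tissue sample imaged
as a two-channel z-stack over the 80–200 μm depth window is summarized by the
arithmetic mean of per-voxel ratios over all foreground voxels across the
imaged depth; cohorts of such per-sample means are compared between tissue
classes (normal / ulcer / adenoma / cancer) with Welch's t-test or the
Wilcoxon rank-sum test, two-sided, chosen by a Shapiro–Wilk normality gate.
A plate-reader lysate assay (Ch2/Ch1 every 10 min for 120 min, first-order
conversion kinetics *R*(*t*) = *R*<sub>∞</sub> − (*R*<sub>∞</sub> − *R*<sub>0</sub>)e<sup>−*kt*</sup>)
cross-validates the imaging contrast.

The package is for researchers developing or evaluating ratiometric
enzyme-activity imaging: it provides the full analysis pipeline (masking,
ratio mapping, whole-depth summaries, depth profiles, pseudocolor rendering,
group statistics, threshold classifiers, kinetics fits) plus a
forward-simulation layer that generates gland-structured tissue phantoms and
noisy two-channel acquisitions calibrated to published per-class group
statistics, so every analysis step can be validated against ground truth.

## Worked example

```python
from tpmratio import analyze_stack, simulate_sample

stack, phantom = simulate_sample("SG1", "cancer", seed=1)
summary, profile, ratio_volume = analyze_stack(stack)
print(phantom.sample_ratio_mean, summary.mean_ratio)
```

Running `examples/01_simulate_and_measure_one_sample.py` prints:

```
probe SG1, class cancer
true per-sample mean ratio (ground truth): 1.2323
measured whole-depth mean Ch2/Ch1 ratio:   1.2442
foreground voxels: 39016 over 30 sections
```

The phantom's per-sample mean ratio (a draw from the SG1 cancer calibration,
Normal(1.127, 0.109)) is recovered by the full pipeline to about 1%; the
small positive residual is Poisson-ratio bias at finite photon counts.
`examples/02_cohort_discrimination.py` runs cohorts through the pipeline and
prints, per probe, the group means ± SD, the test used, p-value, and fold
change — e.g. SG1 normal 0.616 ± 0.146 vs cancer 1.102 ± 0.112, p ≈ 2×10⁻⁷,
fold 1.79, while SHC is non-significant. The other examples cover depth
profiling (with the section-to-sample aggregation identity) and lysate
kinetics.

A thin CLI wires the stages end-to-end on disk:

```sh
tpmratio --outdir run --seed 1 simulate   # TIFF stacks + JSON sidecars + manifest
tpmratio --outdir run analyze             # summaries.csv + depth_profiles.csv
tpmratio --outdir run compare             # comparisons.csv + box plots
tpmratio --outdir run lysate              # kinetics + endpoint comparisons
tpmratio --outdir run report              # single markdown report
```

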