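"""Simulate one stained tissue sample and measure its Ch2/Ch1 ratio.

Builds a gastric-cancer phantom for the beta-galactosidase probe SG1, renders
it through the two-photon forward model (Poisson shot noise + read noise,
exponential depth attenuation), then runs the analysis pipeline: Otsu
foreground masking, per-voxel Ch2/Ch1 ratio mapping, and the whole-depth
sample mean.
"""

from tpmratio import analyze_stack, simulate_sample

stack, phantom = simulate_sample("SG1", "cancer", seed=1)
summary, profile, ratio_volume = analyze_stack(stack)

print(f"probe {stack.probe_id}, class {stack.tissue_class}")
print(f"true per-sample mean ratio (ground truth): {phantom.sample_ratio_mean:.4f}")
print(f"measured whole-depth mean Ch2/Ch1 ratio:   {summary.mean_ratio:.4f}")
print(f"foreground voxels: {summary.n_foreground_voxels} over {summary.n_sections} sections")

# The measured mean recovers the ground-truth draw to ~1%; the residual gap
# is Poisson-ratio bias at finite photon counts.  Values near 1.13 are what
# the SG1 calibration assigns to cancer tissue (normal sits near 0.66).
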