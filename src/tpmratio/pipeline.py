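"""End-to-end wiring: simulate, analyze, compare — in memory or on disk.

These functions compose the module-level operations into the standard run:
phantom → rendered stack → foreground mask → ratio volume → whole-depth
sample mean + depth profile (with the aggregation identity asserted on every
sample) → cohort comparison tables.  The CLI is a thin shell over them.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as tio
from .calibration import PROBES, TABLE1_COUNTS, get_calibration
from .depth import DepthProfile, depth_profile, profile_consistency
from .ratiometry import RatioVolume, SampleSummary, foreground_mask, ratio_map, sample_mean_ratio
from .stats import comparison_table
from .synthetic import (
    AcquisitionParams,
    CohortDesign,
    cohort_seeds,
    simulate_cohort,
    simulate_sample,
)

log = logging.getLogger("tpmratio")


def analyze_stack(stack: tio.TwoChannelStack, mask_method: str = "otsu",
                  mask_percentile: float = 50.0,
                  depth_window: tuple[float, float] | None = (80.0, 200.0)
                  ) -> tuple[SampleSummary, DepthProfile, RatioVolume]:
    """Mask, ratio-map, and summarize one stack; asserts profile consistency."""
    mask = foreground_mask(stack, method=mask_method, percentile=mask_percentile)
    rv = ratio_map(stack, mask)
    summary = sample_mean_ratio(rv, depth_window=depth_window)
    profile = depth_profile(rv, depth_window=depth_window)
    profile_consistency(profile, summary)  # aggregation identity, every run
    return summary, profile, rv


def summarize_stacks(stacks: Sequence[tio.TwoChannelStack],
                     mask_method: str = "otsu", mask_percentile: float = 50.0,
                     depth_window: tuple[float, float] | None = (80.0, 200.0)
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample summaries and depth profiles for a batch of stacks."""
    summaries, profiles = [], []
    for stack in stacks:
        summary, profile, _ = analyze_stack(stack, mask_method, mask_percentile,
                                            depth_window)
        summaries.append({
            "sample_id": summary.sample_id, "probe_id": summary.probe_id,
            "tissue_class": summary.tissue_class,
            "mean_ratio": summary.mean_ratio,
            "n_foreground_voxels": summary.n_foreground_voxels,
            "n_sections": summary.n_sections,
        })
        profiles.append(profile.to_dataframe())
    return pd.DataFrame(summaries), pd.concat(profiles, ignore_index=True)


def simulate_class_means(probe_id: str, tissue_class: str, n: int,
                         master_seed: int = 0,
                         seeds: Sequence[int] | None = None,
                         acquisition: AcquisitionParams | None = None,
                         texture_sd: float = 0.05,
                         mask_method: str = "otsu",
                         depth_window: tuple[float, float] | None = (80.0, 200.0)
                         ) -> np.ndarray:
    """Measured per-sample mean ratios for one simulated probe x class cohort.

    Runs the full pipeline (phantom, noisy rendering, masking, ratio mapping,
    whole-depth mean) per sample and returns the ``n`` measured means.
    """
    if acquisition is None:
        acquisition = AcquisitionParams()
    if seeds is None:
        seeds = cohort_seeds(master_seed, n)
    means = np.empty(n)
    for i, seed in enumerate(seeds):
        stack, _ = simulate_sample(probe_id, tissue_class, seed,
                                   acquisition=acquisition, texture_sd=texture_sd,
                                   sample_id=f"{probe_id}-{tissue_class}-{i + 1:03d}")
        summary, _, _ = analyze_stack(stack, mask_method=mask_method,
                                      depth_window=depth_window)
        means[i] = summary.mean_ratio
    return means


# ---------------------------------------------------------------------------
# on-disk pipeline stages (used by the CLI)


def simulate_to_dir(design: CohortDesign, out_dir: str | Path) -> Path:
    """Simulate a cohort and write TIFF stacks, sidecars, and the manifest."""
    out_dir = Path(out_dir)
    stacks_dir = out_dir / "stacks"
    stacks_dir.mkdir(parents=True, exist_ok=True)
    stacks, manifest = simulate_cohort(design)
    paths = []
    for stack in stacks:
        tiff_path = stacks_dir / f"{stack.sample_id}.tif"
        tio.write_stack(stack, tiff_path)
        paths.append(str(tiff_path.relative_to(out_dir)))
    manifest = manifest.assign(tiff_path=paths)
    manifest_path = out_dir / "manifest.csv"
    tio.write_manifest(manifest, manifest_path)
    log.info("simulated %d stacks -> %s", len(stacks), out_dir)
    return manifest_path


def analyze_manifest(manifest_path: str | Path, out_dir: str | Path,
                     mask_method: str = "otsu",
                     depth_window: tuple[float, float] | None = (80.0, 200.0)
                     ) -> tuple[Path, Path]:
    """Analyze every stack listed in a manifest; write summary + profile CSVs."""
    manifest_path = Path(manifest_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = tio.read_manifest(manifest_path)
    stacks = [tio.read_stack(manifest_path.parent / p) for p in manifest["tiff_path"]]
    summaries, profiles = summarize_stacks(stacks, mask_method=mask_method,
                                           depth_window=depth_window)
    summary_path = out_dir / "summaries.csv"
    profile_path = out_dir / "depth_profiles.csv"
    tio.write_summary(summaries, summary_path)
    tio.write_summary(profiles, profile_path)
    log.info("analyzed %d stacks -> %s", len(stacks), summary_path)
    return summary_path, profile_path


def compare_from_summaries(summary_path: str | Path, out_dir: str | Path,
                           alpha: float = 0.05, bonferroni: bool = False) -> Path:
    """Pairwise class comparisons per probe from a summary CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summaries = pd.read_csv(summary_path)
    probes = [p for p in PROBES if (summaries["probe_id"] == p).any()]
    table = comparison_table(summaries, probes, alpha=alpha, bonferroni=bonferroni)
    path = out_dir / "comparisons.csv"
    tio.write_summary(table, path)
    log.info("wrote %d comparisons -> %s", len(table), path)
    return path
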