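"""Figure export: per-probe box plots and depth profiles with min/max bars."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .calibration import TISSUE_CLASSES
from .depth import DepthProfile


def boxplot_by_class(summaries: pd.DataFrame, probe_id: str,
                     out_path: str | Path, value_col: str = "mean_ratio",
                     ylabel: str = "mean Ch2/Ch1 ratio") -> Path:
    """Box plot of per-sample ratios by tissue class for one probe."""
    sel = summaries[summaries["probe_id"] == probe_id]
    classes = [c for c in TISSUE_CLASSES if (sel["tissue_class"] == c).any()]
    data = [sel.loc[sel["tissue_class"] == c, value_col].to_numpy() for c in classes]
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.boxplot(data, tick_labels=classes)
    ax.set_ylabel(ylabel)
    ax.set_title(probe_id)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path


def plot_depth_profile(profile: DepthProfile, out_path: str | Path) -> Path:
    """Mean ratio vs depth, min/max as error bars; empty sections omitted."""
    ok = profile.n_voxels > 0
    z = profile.z_um[ok]
    mean = profile.mean_ratio[ok]
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.errorbar(z, mean,
                yerr=[mean - profile.min_ratio[ok], profile.max_ratio[ok] - mean],
                fmt="o-", markersize=3, capsize=2, linewidth=1)
    ax.set_xlabel("depth (μm)")
    ax.set_ylabel("Ch2/Ch1 ratio")
    title = " ".join(x for x in (profile.probe_id, profile.sample_id) if x)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path
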