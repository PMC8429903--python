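"""Per-section ratio statistics versus depth (optical-section profiling).

Each optical section inside the configured depth window is summarized by the
mean, minimum, and maximum of its masked per-voxel ratios (min/max become the
error bars of a depth plot; the SD is stored as well).  An aggregation
identity ties the profile back to the whole-sample mean: the voxel-count-
weighted mean of per-section means equals the sample mean ratio exactly, and
is asserted on every pipeline run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AnalysisError, ValidationError
from .ratiometry import RatioVolume, SampleSummary, _window_slice


@dataclass
class DepthProfile:
    """Per-section ratio statistics at each imaged depth.

    Sections whose mask is empty are reported with ``n_voxels = 0`` and NaN
    statistics (excluded from plots but kept for bookkeeping).
    """

    z_um: np.ndarray
    n_voxels: np.ndarray
    mean_ratio: np.ndarray
    min_ratio: np.ndarray
    max_ratio: np.ndarray
    sd_ratio: np.ndarray
    probe_id: str | None = None
    sample_id: str | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.z_um) <= 0):
            raise ValidationError("profile depths must be strictly increasing")
        ok = self.n_voxels > 0
        if not np.all((self.min_ratio[ok] <= self.mean_ratio[ok] + 1e-12)
                      & (self.mean_ratio[ok] <= self.max_ratio[ok] + 1e-12)):
            raise ValidationError("per-section min <= mean <= max violated")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sample_id": self.sample_id,
            "probe_id": self.probe_id,
            "z_um": self.z_um,
            "n_voxels": self.n_voxels,
            "mean_ratio": self.mean_ratio,
            "min_ratio": self.min_ratio,
            "max_ratio": self.max_ratio,
            "sd_ratio": self.sd_ratio,
        })


@dataclass
class ConsistencyReport:
    """Result of the profile/summary aggregation-identity check."""

    weighted_mean: float
    sample_mean: float
    relative_error: float
    ok: bool


def depth_profile(ratio_volume: RatioVolume,
                  depth_window: tuple[float, float] | None = (80.0, 200.0)
                  ) -> DepthProfile:
    """Per-section mean/min/max/SD of masked ratios within the depth window.

    Sections are binned by their exact z position; there is no interpolation
    across depths.
    """
    z = ratio_volume.z_positions_um
    keep = _window_slice(z, depth_window)
    if not keep.any():
        raise AnalysisError(
            f"depth window {depth_window} outside stack z-range "
            f"[{z[0]:.0f}, {z[-1]:.0f}] um"
        )
    idx = np.nonzero(keep)[0]
    n = len(idx)
    out = {k: np.full(n, np.nan) for k in ("mean", "min", "max", "sd")}
    n_vox = np.zeros(n, dtype=int)
    for j, iz in enumerate(idx):
        vals = ratio_volume.ratios[iz][ratio_volume.mask[iz]]
        n_vox[j] = vals.size
        if vals.size:
            out["mean"][j] = vals.mean()
            out["min"][j] = vals.min()
            out["max"][j] = vals.max()
            out["sd"][j] = vals.std(ddof=0)
    return DepthProfile(
        z_um=z[idx].copy(), n_voxels=n_vox,
        mean_ratio=out["mean"], min_ratio=out["min"],
        max_ratio=out["max"], sd_ratio=out["sd"],
        probe_id=ratio_volume.probe_id, sample_id=ratio_volume.sample_id,
    )


def profile_consistency(profile: DepthProfile, sample_summary: SampleSummary,
                        tol: float = 1e-9) -> ConsistencyReport:
    """Check the aggregation identity between a profile and a sample summary.

    The voxel-count-weighted mean of per-section means must equal the
    whole-sample mean ratio to within ``tol`` relative error (both computed
    over the same depth window).  A mismatch raises :class:`AnalysisError`.
    """
    if (profile.sample_id is not None and sample_summary.sample_id is not None
            and profile.sample_id != sample_summary.sample_id):
        raise ValidationError(
            f"profile is for {profile.sample_id!r}, summary for "
            f"{sample_summary.sample_id!r}"
        )
    ok = profile.n_voxels > 0
    total = int(profile.n_voxels[ok].sum())
    if total == 0:
        raise AnalysisError("profile has no foreground voxels")
    weighted = float(np.sum(profile.mean_ratio[ok] * profile.n_voxels[ok]) / total)
    rel = abs(weighted - sample_summary.mean_ratio) / abs(sample_summary.mean_ratio)
    if rel > tol:
        raise AnalysisError(
            f"aggregation identity violated: section-weighted mean {weighted!r} "
            f"vs sample mean {sample_summary.mean_ratio!r} (rel err {rel:.3e})"
        )
    return ConsistencyReport(weighted_mean=weighted,
                             sample_mean=sample_summary.mean_ratio,
                             relative_error=rel, ok=True)
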