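"""Per-voxel Ch2/Ch1 ratiometry: masking, ratio volumes, sample means, rendering.

The core quantitative readout: inside a foreground mask, each voxel's ratio is
``ch2/ch1`` (dimensionless; concentration- and illumination-independent), and
a sample is summarized by the arithmetic mean of per-voxel ratios over all
masked voxels across the imaged depth.  Pseudocolor rendering encodes ratio
as hue and summed intensity as brightness, matching how ratiometric
two-photon images are conventionally displayed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
from matplotlib import colormaps
from matplotlib import image as mpl_image
from skimage.filters import threshold_otsu

from .calibration import IMAGING_CALIBRATIONS, ProbeCalibration
from .errors import AnalysisError, ValidationError
from .io import MAX_COUNT, TwoChannelStack


@dataclass
class RatioVolume:
    """Per-voxel Ch2/Ch1 values with a foreground mask.

    ``ratios`` is NaN outside the mask; inside, values are finite and > 0.
    """

    ratios: np.ndarray
    mask: np.ndarray
    z_positions_um: np.ndarray
    probe_id: str | None = None
    sample_id: str | None = None
    tissue_class: str | None = None
    display_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.mask.shape != self.ratios.shape:
            raise ValidationError("mask shape must equal ratio shape")
        if len(self.z_positions_um) != self.ratios.shape[0]:
            raise ValidationError("z_positions_um length must equal section count")
        vals = self.ratios[self.mask]
        if vals.size and not np.all(np.isfinite(vals) & (vals > 0)):
            raise ValidationError("masked ratios must be finite and > 0")


@dataclass
class SampleSummary:
    """Whole-depth summary of one sample."""

    sample_id: str | None
    probe_id: str | None
    tissue_class: str | None
    mean_ratio: float
    n_foreground_voxels: int
    n_sections: int

    def __post_init__(self) -> None:
        if not self.mean_ratio > 0:
            raise ValidationError("mean_ratio must be > 0")
        if self.n_foreground_voxels <= 0:
            raise ValidationError("n_foreground_voxels must be > 0")


def foreground_mask(stack: TwoChannelStack, method: str = "otsu",
                    percentile: float = 50.0, per_section: bool = True,
                    exclude_saturated: bool = True) -> np.ndarray:
    """Foreground (tissue) mask on the summed-channel intensity.

    Methods
    -------
    ``"otsu"``
        Otsu threshold on ``ch1+ch2``.  By default the threshold is computed
        per optical section, which keeps deep (attenuated) tissue in the mask;
        ``per_section=False`` uses one global threshold.
    ``"percentile"``
        Keep voxels at or above the ``percentile``-th percentile of the
        summed intensity (global); ``percentile=0`` keeps every voxel.

    Voxels with ``ch1 == 0`` or ``ch2 == 0`` are always excluded (the ratio
    is undefined or degenerate there), as are voxels saturated at the 16-bit
    maximum in either channel (the ratio is biased at saturation).
    """
    summed = stack.summed
    valid = (stack.ch1 > 0) & (stack.ch2 > 0)
    if exclude_saturated:
        valid &= (stack.ch1 < MAX_COUNT) & (stack.ch2 < MAX_COUNT)

    if method == "otsu":
        mask = np.zeros_like(valid)
        if per_section:
            for iz in range(summed.shape[0]):
                sec = summed[iz]
                if np.ptp(sec) == 0:
                    continue  # constant section: no separable foreground
                mask[iz] = sec > threshold_otsu(sec)
        else:
            if np.ptp(summed) > 0:
                mask = summed > threshold_otsu(summed)
        mask &= valid
    elif method == "percentile":
        if not (0.0 <= percentile <= 100.0):
            raise ValidationError("percentile must be in [0, 100]")
        mask = (summed >= np.percentile(summed, percentile)) & valid
    else:
        raise ValidationError(f"unknown masking method {method!r}")

    if not mask.any():
        n_zero = int((stack.ch1 == 0).sum())
        raise AnalysisError(
            f"empty foreground mask (method={method}); "
            f"{n_zero}/{stack.ch1.size} voxels have ch1=0"
        )
    return mask


def ratio_map(stack: TwoChannelStack, mask: np.ndarray) -> RatioVolume:
    """Voxel-wise Ch2/Ch1 inside the mask; NaN outside.

    Scale invariant: multiplying both channels by any c > 0 leaves the map
    unchanged.
    """
    if mask.shape != stack.ch1.shape:
        raise ValidationError("mask shape must match stack shape")
    if not mask.any():
        raise AnalysisError("mask is empty")
    assert np.all(stack.ch1[mask] > 0), "mask contract violated: ch1=0 inside mask"
    ratios = np.full(stack.ch1.shape, np.nan)
    ratios[mask] = stack.ch2[mask] / stack.ch1[mask]
    return RatioVolume(
        ratios=ratios, mask=mask.copy(),
        z_positions_um=stack.z_positions_um.copy(),
        probe_id=stack.probe_id, sample_id=stack.sample_id,
        tissue_class=stack.tissue_class,
    )


def _window_slice(z: np.ndarray, depth_window: tuple[float, float] | None) -> np.ndarray:
    if depth_window is None:
        return np.ones(len(z), dtype=bool)
    lo, hi = depth_window
    if not lo < hi:
        raise ValidationError(f"invalid depth window [{lo}, {hi}]")
    return (z >= lo) & (z <= hi)


def sample_mean_ratio(ratio_volume: RatioVolume,
                      depth_window: tuple[float, float] | None = None) -> SampleSummary:
    """Arithmetic mean of per-voxel ratios over all masked voxels in the window.

    Every masked voxel is weighted equally across sections (whole-depth
    mean); ratios are not clipped.
    """
    keep = _window_slice(ratio_volume.z_positions_um, depth_window)
    if not keep.any():
        raise AnalysisError(
            f"no sections inside depth window {depth_window} "
            f"(stack spans {ratio_volume.z_positions_um[0]:.0f}-"
            f"{ratio_volume.z_positions_um[-1]:.0f} um)"
        )
    mask = ratio_volume.mask[keep]
    vals = ratio_volume.ratios[keep][mask]
    if vals.size == 0:
        raise AnalysisError("no foreground voxels inside the depth window")
    return SampleSummary(
        sample_id=ratio_volume.sample_id,
        probe_id=ratio_volume.probe_id,
        tissue_class=ratio_volume.tissue_class,
        mean_ratio=float(vals.mean()),
        n_foreground_voxels=int(vals.size),
        n_sections=int(keep.sum()),
    )


def default_display_range(probe_id: str,
                          calibration: ProbeCalibration | None = None
                          ) -> tuple[float, float]:
    """Display range spanning the normal and cancer calibration anchors.

    Covers mean ± 2 SD of both anchor classes regardless of which one is
    higher, so it works for probes whose ratio falls in cancer (SE1) as well
    as those where it rises (SG1).
    """
    cal = calibration if calibration is not None else IMAGING_CALIBRATIONS[probe_id]
    anchors = [("normal", cal.mean("normal"), cal.sd("normal")),
               ("cancer", cal.mean("cancer"), cal.sd("cancer"))]
    lo = min(m - 2 * s for _, m, s in anchors)
    hi = max(m + 2 * s for _, m, s in anchors)
    return (max(lo, 1e-6), hi)


def pseudocolor(ratio_volume: RatioVolume, intensity_volume: np.ndarray | None = None,
                colormap: str = "turbo",
                display_range: tuple[float, float] | None = None,
                modulate_brightness: bool = True) -> np.ndarray:
    """Render sections as RGB: hue encodes ratio, brightness encodes intensity.

    Returns a ``(n_sections, ny, nx, 3)`` float array in [0, 1]; unmasked
    (background) voxels are black.  ``intensity_volume`` is the summed-channel
    intensity, normalized per stack to its foreground maximum; omit it (or
    pass ``modulate_brightness=False``) for flat brightness.
    """
    if display_range is None:
        if ratio_volume.display_range is not None:
            display_range = ratio_volume.display_range
        elif ratio_volume.probe_id in IMAGING_CALIBRATIONS:
            display_range = default_display_range(ratio_volume.probe_id)
        else:
            vals = ratio_volume.ratios[ratio_volume.mask]
            display_range = (float(vals.min()), float(vals.max()) + 1e-9)
    lo, hi = display_range
    if not lo < hi:
        raise ValidationError(f"invalid display range [{lo}, {hi}]")

    cmap = colormaps[colormap]
    norm = np.clip((ratio_volume.ratios - lo) / (hi - lo), 0.0, 1.0)
    norm = np.where(ratio_volume.mask, norm, 0.0)
    rgb = cmap(norm)[..., :3]

    if modulate_brightness and intensity_volume is not None:
        fg = intensity_volume[ratio_volume.mask]
        peak = float(fg.max()) if fg.size else 1.0
        if peak <= 0:
            peak = 1.0
        brightness = np.clip(intensity_volume / peak, 0.0, 1.0)
        rgb = rgb * brightness[..., None]
    rgb[~ratio_volume.mask] = 0.0
    return rgb


def save_pseudocolor_sections(ratio_volume: RatioVolume, out_dir: str | Path,
                              intensity_volume: np.ndarray | None = None,
                              colormap: str = "turbo",
                              display_range: tuple[float, float] | None = None
                              ) -> list[Path]:
    """Write one PNG per section, named ``{sample}_{z}um.png``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rgb = pseudocolor(ratio_volume, intensity_volume, colormap, display_range)
    sample = ratio_volume.sample_id or "sample"
    paths = []
    for iz, z in enumerate(ratio_volume.z_positions_um):
        path = out_dir / f"{sample}_{z:.0f}um.png"
        mpl_image.imsave(path, rgb[iz], vmin=0.0, vmax=1.0)
        paths.append(path)
    return paths
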