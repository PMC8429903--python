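"""Readers and writers for two-channel stacks, manifests, and result tables.

On-disk conventions
-------------------
* Stacks: multi-page 16-bit unsigned TIFF, page order **z-major,
  channel-minor** (section 0 Ch1, section 0 Ch2, section 1 Ch1, ...), with a
  JSON sidecar carrying acquisition metadata.  The page order is validated on
  read: a silent channel swap would invert the diagnostic direction of every
  probe, so inconsistencies fail loudly.
* Tables: CSV with a header row, UTF-8, ``.`` decimal.
* Depths: ``z_positions_um`` are absolute depths below the tissue surface in
  micrometres, surface = 0, increasing downward.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError, ValidationError

MAX_COUNT = 65535  # 16-bit acquisition depth


@dataclass(frozen=True)
class ChannelBand:
    """An emission detection band (nm)."""

    name: str
    low_nm: float
    high_nm: float

    def __post_init__(self) -> None:
        if not self.low_nm < self.high_nm:
            raise ValidationError(f"band {self.name}: low {self.low_nm} >= high {self.high_nm}")


#: Default detection bands: Ch1 400-450 nm (short), Ch2 600-650 nm (long).
DEFAULT_BANDS: tuple[ChannelBand, ChannelBand] = (
    ChannelBand("Ch1", 400.0, 450.0),
    ChannelBand("Ch2", 600.0, 650.0),
)


def _validate_bands(bands: Sequence[ChannelBand]) -> None:
    if len(bands) != 2 or bands[0].name != "Ch1" or bands[1].name != "Ch2":
        raise ValidationError("bands must be (Ch1, Ch2)")
    if not bands[1].low_nm > bands[0].high_nm:
        raise ValidationError("Ch2 band must lie entirely above the Ch1 band")


@dataclass
class TwoChannelStack:
    """Registered two-channel intensity volumes with acquisition metadata.

    ``ch1`` and ``ch2`` are ``(n_sections, ny, nx)`` arrays of non-negative
    photon counts; section ``i`` was acquired at depth ``z_positions_um[i]``.
    ``tissue_class`` is optional so stacks can be carried blinded.
    """

    ch1: np.ndarray
    ch2: np.ndarray
    z_positions_um: np.ndarray
    pixel_size_um: float
    bands: tuple[ChannelBand, ChannelBand] = DEFAULT_BANDS
    probe_id: str | None = None
    sample_id: str | None = None
    tissue_class: str | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.ch1 = np.asarray(self.ch1, dtype=np.float64)
        self.ch2 = np.asarray(self.ch2, dtype=np.float64)
        self.z_positions_um = np.asarray(self.z_positions_um, dtype=np.float64)
        if self.ch1.ndim != 3:
            raise ValidationError("channel volumes must be 3-D (z, y, x)")
        if self.ch1.shape != self.ch2.shape:
            raise ValidationError(
                f"channel shapes differ: {self.ch1.shape} vs {self.ch2.shape}"
            )
        if len(self.z_positions_um) != self.ch1.shape[0]:
            raise ValidationError(
                f"{self.ch1.shape[0]} sections but {len(self.z_positions_um)} z positions"
            )
        if np.any(np.diff(self.z_positions_um) <= 0):
            raise ValidationError("z_positions_um must be strictly increasing")
        if self.ch1.min(initial=0) < 0 or self.ch2.min(initial=0) < 0:
            raise ValidationError("intensities must be non-negative")
        if not self.pixel_size_um > 0:
            raise ValidationError("pixel_size_um must be > 0")
        _validate_bands(self.bands)

    @property
    def n_sections(self) -> int:
        return self.ch1.shape[0]

    @property
    def summed(self) -> np.ndarray:
        """Summed-channel intensity, used for masking and display brightness."""
        return self.ch1 + self.ch2


# ---------------------------------------------------------------------------
# stack I/O

_SIDECAR_REQUIRED = (
    "probe_id",
    "tissue_class",
    "sample_id",
    "pixel_size_um",
    "z_positions_um",
    "channel_bands_nm",
    "seed",
)


def write_stack(stack: TwoChannelStack, tiff_path: str | Path,
                sidecar_path: str | Path | None = None) -> Path:
    """Write a stack as 16-bit multi-page TIFF plus a JSON sidecar.

    Counts are rounded and clipped to [0, 65535].  Page order is z-major,
    channel-minor.  Returns the sidecar path.
    """
    tiff_path = Path(tiff_path)
    sidecar_path = Path(sidecar_path) if sidecar_path else tiff_path.with_suffix(".json")
    nz, ny, nx = stack.ch1.shape
    pages = np.empty((2 * nz, ny, nx), dtype=np.uint16)
    pages[0::2] = np.clip(np.rint(stack.ch1), 0, MAX_COUNT).astype(np.uint16)
    pages[1::2] = np.clip(np.rint(stack.ch2), 0, MAX_COUNT).astype(np.uint16)
    tifffile.imwrite(tiff_path, pages, photometric="minisblack")
    sidecar = {
        "probe_id": stack.probe_id,
        "tissue_class": stack.tissue_class,
        "sample_id": stack.sample_id,
        "pixel_size_um": stack.pixel_size_um,
        "z_positions_um": [float(z) for z in stack.z_positions_um],
        "channel_bands_nm": {b.name: [b.low_nm, b.high_nm] for b in stack.bands},
        "seed": stack.seed,
        "page_order": "z-major,channel-minor",
    }
    sidecar_path.write_text(json.dumps(sidecar, indent=1, sort_keys=True) + "\n")
    return sidecar_path


def read_stack(tiff_path: str | Path, sidecar_path: str | Path | None = None) -> TwoChannelStack:
    """Read a stack written by :func:`write_stack`; round-trips bit-exactly.

    Missing sidecar fields are a hard error — metadata is never silently
    defaulted.
    """
    tiff_path = Path(tiff_path)
    sidecar_path = Path(sidecar_path) if sidecar_path else tiff_path.with_suffix(".json")
    if not tiff_path.exists():
        raise FormatError(f"stack file not found: {tiff_path}")
    if not sidecar_path.exists():
        raise FormatError(f"sidecar not found: {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    missing = [k for k in _SIDECAR_REQUIRED if k not in meta]
    if missing:
        raise FormatError(f"sidecar {sidecar_path} missing fields: {missing}")
    order = meta.get("page_order", "z-major,channel-minor")
    if order != "z-major,channel-minor":
        raise FormatError(f"unsupported page order {order!r}")
    pages = tifffile.imread(tiff_path)
    if pages.ndim == 2:
        pages = pages[None]
    z = np.asarray(meta["z_positions_um"], dtype=np.float64)
    if pages.shape[0] != 2 * len(z):
        raise FormatError(
            f"{tiff_path}: expected {2 * len(z)} pages for {len(z)} sections, "
            f"found {pages.shape[0]}"
        )
    if np.any(np.diff(z) <= 0):
        raise ValidationError(f"{sidecar_path}: z positions not strictly increasing")
    bands_meta = meta["channel_bands_nm"]
    try:
        bands = (
            ChannelBand("Ch1", *map(float, bands_meta["Ch1"])),
            ChannelBand("Ch2", *map(float, bands_meta["Ch2"])),
        )
    except KeyError as exc:
        raise FormatError(f"sidecar {sidecar_path}: channel_bands_nm missing {exc}") from None
    return TwoChannelStack(
        ch1=pages[0::2],
        ch2=pages[1::2],
        z_positions_um=z,
        pixel_size_um=float(meta["pixel_size_um"]),
        bands=bands,
        probe_id=meta["probe_id"],
        sample_id=meta["sample_id"],
        tissue_class=meta["tissue_class"],
        seed=meta["seed"],
    )


# ---------------------------------------------------------------------------
# tabular I/O

MANIFEST_COLUMNS = (
    "sample_id", "tissue_class", "probe_id", "seed", "true_mean_ratio", "tiff_path",
)


def write_manifest(manifest: pd.DataFrame, csv_path: str | Path) -> None:
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise FormatError(f"manifest missing required columns: {missing}")
    manifest.to_csv(csv_path, index=False)


def read_manifest(csv_path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort manifest CSV; unknown columns are kept."""
    csv_path = Path(csv_path)
    if not csv_path.exists():
        raise FormatError(f"manifest not found: {csv_path}")
    df = pd.read_csv(csv_path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"manifest {csv_path} missing required columns: {missing}")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"manifest {csv_path}: duplicate sample_id values {sorted(set(dup))}")
    return df


def write_summary(table: pd.DataFrame, csv_path: str | Path) -> None:
    """Write any result table as CSV (header row, UTF-8, '.' decimal)."""
    table.to_csv(csv_path, index=False)


def write_lysate_series(time_min: Sequence[float], ratio: Sequence[float],
                        csv_path: str | Path,
                        ch1: Sequence[float] | None = None,
                        ch2: Sequence[float] | None = None) -> None:
    data = {"time_min": list(time_min), "ratio": list(ratio)}
    if ch1 is not None:
        data["ch1"] = list(ch1)
    if ch2 is not None:
        data["ch2"] = list(ch2)
    pd.DataFrame(data).to_csv(csv_path, index=False)


def read_lysate_series(csv_path: str | Path) -> pd.DataFrame:
    csv_path = Path(csv_path)
    if not csv_path.exists():
        raise FormatError(f"lysate series not found: {csv_path}")
    df = pd.read_csv(csv_path)
    missing = [c for c in ("time_min", "ratio") if c not in df.columns]
    if missing:
        raise FormatError(f"lysate series {csv_path} missing columns: {missing}")
    return df
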