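"""Synthetic two-channel tissue phantoms, acquired stacks, cohorts, lysates.

The raw clinical images behind the calibrations are not deposited, so this
module generates surrogates with the statistical structure the downstream
analysis assumes, with ground truth attached:

* **Phantom** — a gastric-gland-like 3-D scene: a lattice of tubular glands
  (regular in normal tissue, displaced and deformed in cancer), a per-sample
  mean Ch2/Ch1 ratio drawn from the probe calibration, and a smooth
  within-sample spatial texture on top of it.
* **Forward imaging model** — a ratiometric probe splits a voxel's emission
  brightness ``B`` between the two detection bands as ``E[Ch2] = B·r/(1+r)``
  and ``E[Ch1] = B/(1+r)`` where ``r`` is the voxel's true ratio; brightness
  decays exponentially with depth; detection adds Poisson shot noise and
  Gaussian read noise.
* **Cohorts** — one stack per sample per probe at the reference design sizes
  (normal 21, ulcer 18, adenoma 17, cancer 20), reproducible from one master
  seed.
* **Lysate time courses** — first-order approach to plateau,
  ``R(t) = R_inf − (R_inf − R0)·exp(−k·t)``, sampled every 10 min over
  120 min with additive Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .calibration import (
    IMAGING_CALIBRATIONS,
    LYSATE_CALIBRATIONS,
    PROBES,
    TABLE1_COUNTS,
    TISSUE_CLASSES,
    ProbeCalibration,
    get_calibration,
)
from .errors import ConfigurationError, ValidationError
from .io import DEFAULT_BANDS, TwoChannelStack
from .lysate import LysateTimeSeries

# Distinct sub-stream tags so phantom construction and rendering driven by the
# same sample seed use independent random streams.
_PHANTOM_STREAM = 101
_RENDER_STREAM = 211
_LYSATE_STREAM = 307

#: Relative brightness of non-gland (background) voxels.
BACKGROUND_BRIGHTNESS = 0.01


@dataclass(frozen=True)
class GlandGeometry:
    """Tubular gland lattice parameters (micrometres).

    ``disorder_fraction`` = 0 gives a periodic lattice; increasing it
    displaces tubule centres (by up to ``disorder_fraction/2`` of the
    spacing) and perturbs radii, emulating the irregular, disordered gland
    pattern of cancerous mucosa.
    """

    tubule_radius_um: float = 15.0
    spacing_um: float = 40.0
    wall_thickness_um: float = 6.0
    disorder_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.disorder_fraction <= 1.0):
            raise ValidationError("disorder_fraction must be in [0, 1]")
        for name in ("tubule_radius_um", "spacing_um", "wall_thickness_um"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")


#: Class-default gland disorder; cancer >= 0.5 (irregular, disordered glands).
CLASS_DISORDER: Mapping[str, float] = {
    "normal": 0.1,
    "ulcer": 0.3,
    "adenoma": 0.3,
    "cancer": 0.6,
}


def default_geometry(tissue_class: str) -> GlandGeometry:
    if tissue_class not in TISSUE_CLASSES:
        raise ConfigurationError(f"unknown tissue class {tissue_class!r}")
    return GlandGeometry(disorder_fraction=CLASS_DISORDER[tissue_class])


@dataclass(frozen=True)
class AcquisitionParams:
    """Imaging parameters for the forward model.

    ``z_positions_um`` defaults to 30 optical sections spanning the 80–200 μm
    depth window; ``attenuation_length_um`` is the exponential signal-loss
    length with depth; ``photon_budget`` is the expected count at the
    brightest voxel at the surface.
    """

    image_size: int = 64
    pixel_size_um: float = 2.0
    z_positions_um: tuple[float, ...] = tuple(np.linspace(80.0, 200.0, 30))
    depth_window_um: tuple[float, float] = (80.0, 200.0)
    attenuation_length_um: float = 200.0
    photon_budget: float = 500.0
    read_noise_sd: float = 2.0
    probe_concentration_um: float = 10.0

    def __post_init__(self) -> None:
        z = np.asarray(self.z_positions_um, dtype=float)
        if len(z) == 0 or np.any(np.diff(z) <= 0):
            raise ValidationError("z_positions_um must be non-empty, strictly increasing")
        if z[0] < 0 or z[-1] > 500:
            raise ValidationError("z positions must lie within 0-500 um")
        if not self.photon_budget > 0:
            raise ValidationError("photon_budget must be > 0")
        if not self.attenuation_length_um > 0:
            raise ValidationError("attenuation_length_um must be > 0")
        if self.read_noise_sd < 0:
            raise ValidationError("read_noise_sd must be >= 0")
        if self.image_size < 1 or not self.pixel_size_um > 0:
            raise ValidationError("image_size and pixel_size_um must be positive")

    @property
    def z_array(self) -> np.ndarray:
        return np.asarray(self.z_positions_um, dtype=np.float64)

    def with_depth_range(self, lo_um: float, hi_um: float,
                         n_sections: int | None = None) -> "AcquisitionParams":
        """Return a copy imaging ``n_sections`` between ``lo_um`` and ``hi_um``."""
        n = n_sections if n_sections is not None else len(self.z_positions_um)
        return replace(self, z_positions_um=tuple(np.linspace(lo_um, hi_um, n)),
                       depth_window_um=(lo_um, hi_um))


@dataclass
class Phantom:
    """Ground-truth scene: per-voxel ratio and relative emission brightness."""

    true_ratio_field: np.ndarray    # (nz, ny, nx) dimensionless, > 0
    brightness_field: np.ndarray    # (nz, ny, nx) relative, in (0, 1]
    gland_mask: np.ndarray          # (nz, ny, nx) bool, True inside gland walls
    gland_geometry: GlandGeometry
    tissue_class: str
    probe_id: str
    sample_ratio_mean: float        # realized per-sample mean ratio

    def __post_init__(self) -> None:
        if not np.all(self.true_ratio_field > 0):
            raise ValidationError("true_ratio_field must be strictly positive")


@dataclass(frozen=True)
class CohortDesign:
    """A full simulated study: per-class sample counts x probe panel."""

    counts: Mapping[str, int] = field(default_factory=lambda: dict(TABLE1_COUNTS))
    probes: tuple[str, ...] = PROBES
    acquisition: AcquisitionParams = AcquisitionParams()
    master_seed: int = 0
    texture_sd: float = 0.05

    def __post_init__(self) -> None:
        for cls, n in self.counts.items():
            if cls not in TISSUE_CLASSES:
                raise ConfigurationError(f"unknown tissue class {cls!r}")
            if n < 1:
                raise ValidationError(f"count for {cls!r} must be >= 1")
        for p in self.probes:
            if p not in PROBES:
                raise ConfigurationError(f"unknown probe {p!r}")


@dataclass(frozen=True)
class LysateAssayParams:
    """First-order lysate conversion model parameters.

    ``ratio_t`` follows ``R(t) = R_inf − (R_inf − R0)·exp(−k·t)`` with
    additive Gaussian noise of SD ``noise_sd`` per time point.
    """

    probe_id: str = "SG1"
    tissue_class: str | None = None
    r0: float = 0.5
    r_inf: float = 1.8
    k_per_min: float = 0.04
    noise_sd: float = 0.02
    time_points_min: tuple[float, ...] = tuple(range(0, 121, 10))
    probe_concentration_um: float = 1.0
    protein_amount_ug: float = 200.0

    def __post_init__(self) -> None:
        t = np.asarray(self.time_points_min, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValidationError("time points must be strictly increasing")
        if self.k_per_min < 0:
            raise ValidationError("k_per_min must be >= 0")
        if not (self.r0 > 0 and self.r_inf > 0):
            raise ValidationError("r0 and r_inf must be > 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


# ---------------------------------------------------------------------------
# phantom construction


def draw_sample_mean(mu: float, sd: float, rng: np.random.Generator) -> float:
    """Draw a per-sample mean ratio from Normal(mu, sd) truncated at > 0."""
    if sd < 0:
        raise ValidationError("sd must be >= 0")
    if sd == 0:
        return float(mu)
    for _ in range(1000):
        x = rng.normal(mu, sd)
        if x > 0:
            return float(x)
    raise ValidationError(f"could not draw a positive ratio from N({mu}, {sd})")


def _gland_wall_mask(geometry: GlandGeometry, acquisition: AcquisitionParams,
                     n_sections: int, rng: np.random.Generator) -> np.ndarray:
    """Boolean (nz, ny, nx) mask of gland-wall voxels.

    Tubules sit on a square lattice in the xy plane and are extruded in z
    with a small per-section wobble; disorder adds a fixed random
    displacement and radius perturbation per tubule.
    """
    n = acquisition.image_size
    extent = n * acquisition.pixel_size_um
    g = geometry
    # lattice centres, padded one spacing beyond the field so edge tubules appear
    coords = np.arange(g.spacing_um / 2 - g.spacing_um, extent + g.spacing_um, g.spacing_um)
    cy, cx = np.meshgrid(coords, coords, indexing="ij")
    centres = np.column_stack([cy.ravel(), cx.ravel()])
    n_tub = len(centres)
    displacement = rng.uniform(-0.5, 0.5, size=(n_tub, 2)) * g.disorder_fraction * g.spacing_um
    radii = g.tubule_radius_um * (1.0 + g.disorder_fraction * rng.uniform(-0.4, 0.4, size=n_tub))
    centres = centres + displacement
    wobble = rng.normal(0.0, 0.5, size=(n_sections, n_tub, 2))  # um, per-section jitter

    px = (np.arange(n) + 0.5) * acquisition.pixel_size_um
    yy, xx = np.meshgrid(px, px, indexing="ij")
    mask = np.zeros((n_sections, n, n), dtype=bool)
    half_wall = g.wall_thickness_um / 2.0
    for iz in range(n_sections):
        sec = np.zeros((n, n), dtype=bool)
        for it in range(n_tub):
            c = centres[it] + wobble[iz, it]
            dist = np.hypot(yy - c[0], xx - c[1])
            sec |= np.abs(dist - radii[it]) <= half_wall
        mask[iz] = sec
    return mask


def build_phantom(tissue_class: str, probe_calibration: ProbeCalibration,
                  gland_geometry: GlandGeometry | None = None,
                  acquisition: AcquisitionParams | None = None,
                  seed: int | None = None,
                  texture_sd: float = 0.05) -> Phantom:
    """Build a ground-truth tissue phantom for one sample.

    The per-sample mean ratio is drawn from the calibration's
    Normal(mu_class, sd_class) truncated at > 0; the voxel-wise true ratio is
    that mean plus a smooth zero-mean texture of SD ``texture_sd``
    (dimensionless ratio units), exactly mean-centred over gland voxels so
    the spatial mean over the gland equals the drawn sample mean.
    """
    if tissue_class not in TISSUE_CLASSES:
        raise ConfigurationError(f"unknown tissue class {tissue_class!r}")
    mu = probe_calibration.mean(tissue_class)
    sd = probe_calibration.sd(tissue_class)
    if gland_geometry is None:
        gland_geometry = default_geometry(tissue_class)
    if acquisition is None:
        acquisition = AcquisitionParams()
    rng = np.random.default_rng([_PHANTOM_STREAM, seed] if seed is not None else None)

    sample_mean = draw_sample_mean(mu, sd, rng)
    nz = len(acquisition.z_positions_um)
    gland = _gland_wall_mask(gland_geometry, acquisition, nz, rng)

    noise = rng.standard_normal(gland.shape)
    texture = gaussian_filter(noise, sigma=(1.0, 2.0, 2.0))
    n_gland = int(gland.sum())
    if n_gland > 1 and texture_sd > 0:
        t_g = texture[gland]
        texture = (texture - t_g.mean()) / t_g.std()
        ratio_field = sample_mean + texture_sd * texture
    else:
        ratio_field = np.full(gland.shape, sample_mean)
    # keep ratios strictly positive even in extreme texture draws
    ratio_field = np.maximum(ratio_field, 0.05 * sample_mean)

    brightness = np.where(gland, 1.0, BACKGROUND_BRIGHTNESS)
    return Phantom(
        true_ratio_field=ratio_field,
        brightness_field=brightness,
        gland_mask=gland,
        gland_geometry=gland_geometry,
        tissue_class=tissue_class,
        probe_id=probe_calibration.probe_id,
        sample_ratio_mean=sample_mean,
    )


# ---------------------------------------------------------------------------
# forward imaging model


def expected_channels(phantom: Phantom, acquisition: AcquisitionParams
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free expected counts (ch1, ch2) under the forward model.

    ``B = brightness × photon_budget × exp(−z / attenuation_length)`` is split
    between the bands as ``Ch2 = B·r/(1+r)``, ``Ch1 = B/(1+r)``; hence
    ``Ch1 + Ch2 = B`` at every voxel and ``Ch2/Ch1 = r`` exactly.
    """
    if phantom.true_ratio_field.shape[0] != len(acquisition.z_positions_um):
        raise ValidationError("phantom and acquisition z grids are incompatible")
    atten = np.exp(-acquisition.z_array / acquisition.attenuation_length_um)
    b = phantom.brightness_field * acquisition.photon_budget * atten[:, None, None]
    r = phantom.true_ratio_field
    ch2 = b * r / (1.0 + r)
    ch1 = b / (1.0 + r)
    return ch1, ch2


def render_stack(phantom: Phantom, acquisition: AcquisitionParams | None = None,
                 seed: int | None = None, noise: bool = True,
                 sample_id: str | None = None) -> TwoChannelStack:
    """Render a phantom into an acquired two-channel stack.

    With ``noise=True`` observed counts are ``Poisson(E) + N(0, read_noise)``
    clipped at zero; with ``noise=False`` the noise-free expectations are
    returned (useful for oracle checks).
    """
    if acquisition is None:
        acquisition = AcquisitionParams()
    ch1, ch2 = expected_channels(phantom, acquisition)
    if noise:
        rng = np.random.default_rng([_RENDER_STREAM, seed] if seed is not None else None)
        ch1 = rng.poisson(ch1).astype(np.float64)
        ch2 = rng.poisson(ch2).astype(np.float64)
        if acquisition.read_noise_sd > 0:
            ch1 = ch1 + rng.normal(0.0, acquisition.read_noise_sd, ch1.shape)
            ch2 = ch2 + rng.normal(0.0, acquisition.read_noise_sd, ch2.shape)
        ch1 = np.clip(ch1, 0.0, None)
        ch2 = np.clip(ch2, 0.0, None)
    return TwoChannelStack(
        ch1=ch1, ch2=ch2,
        z_positions_um=acquisition.z_array.copy(),
        pixel_size_um=acquisition.pixel_size_um,
        bands=DEFAULT_BANDS,
        probe_id=phantom.probe_id,
        sample_id=sample_id,
        tissue_class=phantom.tissue_class,
        seed=seed,
    )


def simulate_sample(probe_id: str, tissue_class: str, seed: int,
                    acquisition: AcquisitionParams | None = None,
                    calibration: ProbeCalibration | None = None,
                    texture_sd: float = 0.05, noise: bool = True,
                    sample_id: str | None = None) -> tuple[TwoChannelStack, Phantom]:
    """Phantom + rendered stack for one sample, from one integer seed."""
    cal = calibration if calibration is not None else get_calibration(probe_id)
    phantom = build_phantom(tissue_class, cal, acquisition=acquisition,
                            seed=seed, texture_sd=texture_sd)
    stack = render_stack(phantom, acquisition, seed=seed, noise=noise,
                         sample_id=sample_id)
    return stack, phantom


def cohort_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic per-sample seeds (< 2**31) derived from a master seed."""
    state = np.random.SeedSequence(master_seed).generate_state(n, dtype=np.uint32)
    return [int(s & 0x7FFFFFFF) for s in state]


def simulate_cohort(design: CohortDesign,
                    calibrations: Mapping[str, ProbeCalibration] | None = None
                    ) -> tuple[list[TwoChannelStack], pd.DataFrame]:
    """Simulate a full cohort: one stack per sample per probe plus a manifest.

    The manifest records ``sample_id, tissue_class, probe_id, seed,
    true_mean_ratio, tiff_path`` (path empty until written) and the run is
    bit-reproducible from ``design.master_seed``.
    """
    cals = calibrations or IMAGING_CALIBRATIONS
    n_subjects = sum(design.counts.values())
    stacks: list[TwoChannelStack] = []
    rows: list[dict] = []
    for probe in design.probes:
        # independent per-probe seed stream, stable under panel changes
        probe_master = int(
            np.random.SeedSequence([design.master_seed, PROBES.index(probe)])
            .generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF
        )
        seeds = cohort_seeds(probe_master, n_subjects)
        i = 0
        for cls in TISSUE_CLASSES:
            for j in range(design.counts.get(cls, 0)):
                sample_id = f"{probe}-{cls}-{j + 1:03d}"
                seed = seeds[i]
                i += 1
                stack, phantom = simulate_sample(
                    probe, cls, seed, acquisition=design.acquisition,
                    calibration=cals[probe], texture_sd=design.texture_sd,
                    sample_id=sample_id)
                stacks.append(stack)
                rows.append({
                    "sample_id": sample_id,
                    "tissue_class": cls,
                    "probe_id": probe,
                    "seed": seed,
                    "true_mean_ratio": phantom.sample_ratio_mean,
                    "tiff_path": "",
                })
    return stacks, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# lysate time courses


def first_order_ratio(t: np.ndarray | float, r0: float, r_inf: float,
                      k: float) -> np.ndarray | float:
    """Closed-form first-order conversion: R(t) = R_inf − (R_inf − R0)e^(−kt)."""
    return r_inf - (r_inf - r0) * np.exp(-k * np.asarray(t, dtype=float))


def simulate_lysate_series(params: LysateAssayParams, seed: int | None = None,
                           sample_id: str | None = None) -> LysateTimeSeries:
    """Simulate one plate-reader Ch2/Ch1 trajectory."""
    t = np.asarray(params.time_points_min, dtype=float)
    clean = first_order_ratio(t, params.r0, params.r_inf, params.k_per_min)
    rng = np.random.default_rng([_LYSATE_STREAM, seed] if seed is not None else None)
    ratio = clean + (rng.normal(0.0, params.noise_sd, t.shape)
                     if params.noise_sd > 0 else 0.0)
    ratio = np.maximum(ratio, 1e-6)
    return LysateTimeSeries(
        sample_id=sample_id,
        probe_id=params.probe_id,
        tissue_class=params.tissue_class,
        time_min=t,
        ratio=np.asarray(ratio, dtype=float),
        probe_concentration_um=params.probe_concentration_um,
        protein_amount_ug=params.protein_amount_ug,
    )


#: Baseline (t=0) ratio of the unconverted probe, per probe.
LYSATE_R0: Mapping[str, float] = {"SG1": 0.45, "SE1": 0.50, "SHC": 0.20}
LYSATE_K_PER_MIN = 0.04
LYSATE_NOISE_SD = 0.02


def lysate_params_for(probe_id: str, tissue_class: str, endpoint: float,
                      k_per_min: float = LYSATE_K_PER_MIN,
                      r0: float | None = None,
                      noise_sd: float = LYSATE_NOISE_SD) -> LysateAssayParams:
    """Parameters whose noise-free trajectory hits ``endpoint`` at t = 120 min.

    Solves ``R(120) = endpoint`` for the plateau ``R_inf`` given ``r0`` and
    ``k``.
    """
    if r0 is None:
        r0 = LYSATE_R0.get(probe_id, 0.5)
    t_end = 120.0
    a = float(np.exp(-k_per_min * t_end))
    r_inf = (endpoint - r0 * a) / (1.0 - a)
    if r_inf <= 0:
        raise ValidationError(f"endpoint {endpoint} incompatible with r0={r0}, k={k_per_min}")
    return LysateAssayParams(probe_id=probe_id, tissue_class=tissue_class,
                             r0=r0, r_inf=r_inf, k_per_min=k_per_min,
                             noise_sd=noise_sd)


def simulate_lysate_cohort(probe_id: str, tissue_class: str, n: int,
                           master_seed: int = 0,
                           seeds: Sequence[int] | None = None,
                           calibration: ProbeCalibration | None = None,
                           k_per_min: float = LYSATE_K_PER_MIN,
                           noise_sd: float = LYSATE_NOISE_SD
                           ) -> list[LysateTimeSeries]:
    """Simulate ``n`` lysate trajectories calibrated to the endpoint table.

    Per-sample latent endpoints are drawn from Normal(mu, sd_latent) truncated
    at > 0, with ``sd_latent = sqrt(sd² − noise_sd²)`` so that measured
    endpoints (latent + read noise) have the calibrated between-sample SD.
    """
    cal = calibration if calibration is not None else get_calibration(probe_id, "lysate")
    mu = cal.mean(tissue_class)
    sd = cal.sd(tissue_class)
    sd_latent = float(np.sqrt(max(sd ** 2 - noise_sd ** 2, 0.0)))
    if seeds is None:
        seeds = cohort_seeds(master_seed, n)
    elif len(seeds) != n:
        raise ValidationError(f"expected {n} seeds, got {len(seeds)}")
    out = []
    for j, seed in enumerate(seeds):
        rng = np.random.default_rng([_LYSATE_STREAM, seed, 1])
        endpoint = draw_sample_mean(mu, sd_latent, rng)
        params = lysate_params_for(probe_id, tissue_class, endpoint,
                                   k_per_min=k_per_min, noise_sd=noise_sd)
        out.append(simulate_lysate_series(
            params, seed=seed, sample_id=f"{probe_id}-{tissue_class}-L{j + 1:03d}"))
    return out
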