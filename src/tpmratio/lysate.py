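"""Lysate-assay analysis: endpoint ratios and first-order kinetics fits.

The cross-validation arm of the pipeline: tissue is homogenized, the probe is
added at 1 μM to 200 μg of extracted protein, and the Ch2/Ch1 emission ratio
is read every 10 min for 120 min on a plate reader.  Enzyme activity is
summarized by the endpoint ratio at t = 120 min; trajectories can also be fit
with a first-order approach-to-plateau model
``R(t) = R_inf − (R_inf − R0)·exp(−k·t)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import ValidationError

_FLAT_TOL = 1e-12


@dataclass
class LysateTimeSeries:
    """One plate-reader Ch2/Ch1 trajectory (dimensionless ratios vs minutes)."""

    time_min: np.ndarray
    ratio: np.ndarray
    sample_id: str | None = None
    probe_id: str | None = None
    tissue_class: str | None = None
    probe_concentration_um: float = 1.0
    protein_amount_ug: float = 200.0

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=np.float64)
        self.ratio = np.asarray(self.ratio, dtype=np.float64)
        if self.time_min.shape != self.ratio.shape or self.time_min.ndim != 1:
            raise ValidationError("time_min and ratio must be equal-length 1-D arrays")
        if np.any(np.diff(self.time_min) <= 0):
            raise ValidationError("time points must be strictly increasing")
        if np.any(self.ratio <= 0):
            raise ValidationError("ratios must be strictly positive")


@dataclass
class KineticsFit:
    """First-order fit result.  ``converged=False`` carries diagnostics, never raises."""

    r0: float
    r_inf: float
    k_per_min: float
    rss: float
    converged: bool
    message: str = ""


def endpoint_ratio(series: LysateTimeSeries, t_end_min: float = 120.0) -> float:
    """Ratio at the assay endpoint (t = 120 min by default)."""
    idx = np.nonzero(np.isclose(series.time_min, t_end_min))[0]
    if len(idx) == 0:
        raise ValidationError(
            f"series {series.sample_id!r} has no time point at t={t_end_min} min"
        )
    return float(series.ratio[idx[0]])


def _model(t: np.ndarray, r0: float, r_inf: float, k: float) -> np.ndarray:
    return r_inf - (r_inf - r0) * np.exp(-k * t)


def fit_first_order(series: LysateTimeSeries) -> KineticsFit:
    """Nonlinear least-squares fit of the first-order conversion model.

    Initialization: R0 from the first point, R_inf from the last, k from a
    log-linearized two-point estimate at the series midpoint; k is bounded
    below at 0.  A flat series short-circuits to the exact degenerate
    solution (k = 0, R0 = R_inf = the constant).
    """
    t = series.time_min
    y = series.ratio
    if len(t) < 4:
        raise ValidationError("kinetics fit requires at least 4 time points")
    if np.ptp(y) < _FLAT_TOL:
        c = float(y[0])
        return KineticsFit(r0=c, r_inf=c, k_per_min=0.0, rss=0.0,
                           converged=True, message="flat series")

    r0_init = float(y[0])
    rinf_init = float(y[-1])
    mid = len(t) // 2
    k_init = 0.01
    denom = rinf_init - r0_init
    if abs(denom) > _FLAT_TOL:
        frac = (rinf_init - y[mid]) / denom
        if 0.0 < frac < 1.0 and t[mid] > 0:
            k_init = float(-np.log(frac) / t[mid])
    k_init = max(k_init, 1e-6)

    try:
        popt, _ = curve_fit(
            _model, t, y, p0=[r0_init, rinf_init, k_init],
            bounds=([0.0, 0.0, 0.0], [np.inf, np.inf, np.inf]),
            xtol=1e-13, ftol=1e-13, gtol=1e-13, maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        resid = y - _model(t, r0_init, rinf_init, k_init)
        return KineticsFit(r0=r0_init, r_inf=rinf_init, k_per_min=k_init,
                           rss=float(resid @ resid), converged=False,
                           message=str(exc))
    resid = y - _model(t, *popt)
    return KineticsFit(r0=float(popt[0]), r_inf=float(popt[1]),
                       k_per_min=float(popt[2]), rss=float(resid @ resid),
                       converged=True)


def compare_lysate_groups(series: list[LysateTimeSeries], class_a: str,
                          class_b: str, alpha: float = 0.05,
                          probe_id: str | None = None):
    """Group comparison of endpoint ratios; delegates to cohort statistics.

    Returns a :class:`~tpmratio.stats.GroupComparison` of the t = 120 min
    endpoints of the two tissue classes.
    """
    from .stats import compare_values  # local import avoids a cycle

    a = [endpoint_ratio(s) for s in series if s.tissue_class == class_a]
    b = [endpoint_ratio(s) for s in series if s.tissue_class == class_b]
    if probe_id is None:
        probes = {s.probe_id for s in series if s.probe_id is not None}
        probe_id = probes.pop() if len(probes) == 1 else None
    return compare_values(a, b, probe_id=probe_id, group_a=class_a,
                          group_b=class_b, alpha=alpha)
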