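"""Probe calibrations: per tissue-class mean Ch2/Ch1 ratios and SDs.

Three two-photon ratiometric probes are modelled, each reporting the activity
of one enzyme through the ratio of its long- to short-wavelength emission
(Ch2/Ch1):

* ``SG1`` — beta-galactosidase; ratio rises in gastric cancer.
* ``SE1`` — carboxylesterase; ratio falls in gastric cancer.
* ``SHC`` — hNQO1; no appreciable cancer/normal contrast in stomach.

Two calibration tables are shipped: whole-depth imaging means (per-sample mean
Ch2/Ch1 over the imaged tissue volume) and lysate-assay endpoint means (the
Ch2/Ch1 ratio read on a plate reader 120 min after probe addition to tissue
lysate).  Means are dimensionless ratios; SDs are between-sample standard
deviations across subjects of a class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .errors import ConfigurationError, ValidationError

PROBES: tuple[str, ...] = ("SG1", "SE1", "SHC")
TISSUE_CLASSES: tuple[str, ...] = ("normal", "ulcer", "adenoma", "cancer")

TARGET_ENZYMES: Mapping[str, str] = {
    "SG1": "beta-galactosidase",
    "SE1": "carboxylesterase",
    "SHC": "hNQO1",
}

#: Subjects per tissue class in the reference cohort design.
TABLE1_COUNTS: Mapping[str, int] = {
    "normal": 21,
    "ulcer": 18,
    "adenoma": 17,
    "cancer": 20,
}


@dataclass(frozen=True)
class ProbeCalibration:
    """Per-probe, per-tissue-class ratio statistics.

    Parameters
    ----------
    probe_id
        One of ``SG1``, ``SE1``, ``SHC``.
    target_enzyme
        Enzyme whose activity the probe reports.
    class_means
        Mean Ch2/Ch1 ratio per tissue class (dimensionless).
    class_sds
        Between-sample SD of the ratio per tissue class.
    """

    probe_id: str
    target_enzyme: str
    class_means: Mapping[str, float]
    class_sds: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.probe_id not in PROBES:
            raise ConfigurationError(f"unknown probe {self.probe_id!r}")
        for cls in self.class_means:
            if cls not in TISSUE_CLASSES:
                raise ConfigurationError(f"unknown tissue class {cls!r}")
        if set(self.class_means) != set(self.class_sds):
            raise ValidationError("class_means and class_sds cover different classes")
        for cls, mu in self.class_means.items():
            if not mu > 0:
                raise ValidationError(f"mean for {cls!r} must be > 0, got {mu}")
        for cls, sd in self.class_sds.items():
            if sd < 0:
                raise ValidationError(f"SD for {cls!r} must be >= 0, got {sd}")

    def mean(self, tissue_class: str) -> float:
        try:
            return float(self.class_means[tissue_class])
        except KeyError:
            raise ConfigurationError(
                f"probe {self.probe_id} has no calibration for class {tissue_class!r}"
            ) from None

    def sd(self, tissue_class: str) -> float:
        try:
            return float(self.class_sds[tissue_class])
        except KeyError:
            raise ConfigurationError(
                f"probe {self.probe_id} has no calibration for class {tissue_class!r}"
            ) from None

    @property
    def direction(self) -> str:
        """``"up"`` if the cancer mean exceeds the normal mean, else ``"down"``."""
        return "up" if self.mean("cancer") > self.mean("normal") else "down"


def _cal(probe: str, stats: Mapping[str, tuple[float, float]]) -> ProbeCalibration:
    return ProbeCalibration(
        probe_id=probe,
        target_enzyme=TARGET_ENZYMES[probe],
        class_means={c: m for c, (m, _) in stats.items()},
        class_sds={c: s for c, (_, s) in stats.items()},
    )


#: Whole-depth imaging calibration (mean Ch2/Ch1 per sample, by class).
IMAGING_CALIBRATIONS: Mapping[str, ProbeCalibration] = {
    "SG1": _cal("SG1", {
        "normal": (0.656, 0.142),
        "ulcer": (0.992, 0.119),
        "adenoma": (0.927, 0.049),
        "cancer": (1.127, 0.109),
    }),
    "SE1": _cal("SE1", {
        "normal": (0.876, 0.049),
        "ulcer": (0.884, 0.048),
        "adenoma": (0.879, 0.059),
        "cancer": (0.579, 0.089),
    }),
    "SHC": _cal("SHC", {
        "normal": (1.393, 0.141),
        "ulcer": (1.317, 0.120),
        "adenoma": (1.343, 0.073),
        "cancer": (1.354, 0.174),
    }),
}

#: Lysate-assay endpoint (t = 120 min) calibration.
#:
#: Note the SE1 entry: the source statistics state esterase activity *lower*
#: in cancer than in normal while printing the larger number first; this table
#: honours the stated direction (cancer 1.313, normal 1.859).  See the methods
#: note for discussion.
LYSATE_CALIBRATIONS: Mapping[str, ProbeCalibration] = {
    "SG1": _cal("SG1", {
        "normal": (1.324, 0.035),
        "ulcer": (1.579, 0.055),
        "adenoma": (1.639, 0.047),
        "cancer": (1.794, 0.048),
    }),
    "SE1": _cal("SE1", {
        "normal": (1.859, 0.053),
        "ulcer": (1.775, 0.063),
        "adenoma": (1.677, 0.051),
        "cancer": (1.313, 0.051),
    }),
    "SHC": _cal("SHC", {
        "normal": (0.657, 0.038),
        "ulcer": (0.664, 0.029),
        "adenoma": (0.671, 0.028),
        "cancer": (0.687, 0.048),
    }),
}


def get_calibration(probe_id: str, assay: str = "imaging") -> ProbeCalibration:
    """Return the default calibration for ``probe_id``.

    ``assay`` selects between the whole-depth ``"imaging"`` table and the
    plate-reader ``"lysate"`` endpoint table.
    """
    tables = {"imaging": IMAGING_CALIBRATIONS, "lysate": LYSATE_CALIBRATIONS}
    try:
        table = tables[assay]
    except KeyError:
        raise ConfigurationError(f"unknown assay {assay!r}") from None
    try:
        return table[probe_id]
    except KeyError:
        raise ConfigurationError(f"unknown probe {probe_id!r}") from None
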