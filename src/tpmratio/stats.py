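"""Group-level comparison and discrimination statistics.

Per-sample mean ratios are compared between tissue classes with either
Welch's two-sample t-test (when both groups pass Shapiro–Wilk normality at
alpha = 0.05) or the Wilcoxon rank-sum (Mann–Whitney U) test, two-sided, with
the exact null distribution for small tie-free samples.  Fold changes are
simple ratios of group means.  A one-dimensional threshold classifier
(maximum Youden's J over candidate midpoints) turns a probe's calibrated
directionality into a cancer/non-cancer decision rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .calibration import IMAGING_CALIBRATIONS
from .errors import AnalysisError, ValidationError
from .ratiometry import SampleSummary

_EXACT_MAX_N = 20


@dataclass
class GroupComparison:
    """A two-group comparison of per-sample ratios."""

    probe_id: str | None
    group_a: str
    group_b: str
    n_a: int
    mean_a: float
    sd_a: float
    n_b: int
    mean_b: float
    sd_b: float
    test_used: str           # "t-test" or "wilcoxon"
    statistic: float
    p_value: float
    fold_change: float       # mean_b / mean_a
    alpha: float
    significant: bool

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p-value {self.p_value} outside [0, 1]")
        if not self.fold_change > 0:
            raise ValidationError("fold_change must be > 0")
        if self.significant != (self.p_value < self.alpha):
            raise ValidationError("significant flag inconsistent with p-value and alpha")


@dataclass(frozen=True)
class ClassifierRule:
    """Threshold rule: a sample is called cancer on one side of the threshold."""

    probe_id: str
    threshold: float
    direction: str  # "above" -> cancer above threshold; "below" -> cancer below

    def __post_init__(self) -> None:
        if self.direction not in ("above", "below"):
            raise ValidationError(f"direction must be 'above' or 'below', got {self.direction!r}")

    def predict(self, value: float) -> bool:
        """True = cancer.  Ties at the threshold are called non-cancer."""
        return value > self.threshold if self.direction == "above" else value < self.threshold


@dataclass
class ClassifierEvaluation:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float | None
    specificity: float | None
    accuracy: float | None


def _to_frame(summaries) -> pd.DataFrame:
    if isinstance(summaries, pd.DataFrame):
        return summaries
    rows = []
    for s in summaries:
        if isinstance(s, SampleSummary):
            rows.append({"sample_id": s.sample_id, "probe_id": s.probe_id,
                         "tissue_class": s.tissue_class, "mean_ratio": s.mean_ratio})
        else:
            rows.append(dict(s))
    return pd.DataFrame(rows)


def compare_values(values_a: Sequence[float], values_b: Sequence[float],
                   probe_id: str | None = None, group_a: str = "a",
                   group_b: str = "b", alpha: float = 0.05,
                   normality_alpha: float = 0.05,
                   force_test: str | None = None) -> GroupComparison:
    """Compare two groups of per-sample values.

    Test selection ("as appropriate"): Shapiro–Wilk on each group at
    ``normality_alpha``; both normal -> Welch's t-test, otherwise Wilcoxon
    rank-sum.  ``force_test`` (``"t-test"`` / ``"wilcoxon"``) overrides the
    gate.  The exact rank-sum null is used for tie-free samples with both
    n <= 20.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise AnalysisError(f"need >= 2 samples per group, got {len(a)} and {len(b)}")

    if force_test is None:
        def _normal(x: np.ndarray) -> bool:
            if len(x) < 3 or np.ptp(x) == 0:
                return False
            return sps.shapiro(x).pvalue >= normality_alpha
        test = "t-test" if (_normal(a) and _normal(b)) else "wilcoxon"
    elif force_test in ("t-test", "wilcoxon"):
        test = force_test
    else:
        raise ValidationError(f"unknown test {force_test!r}")

    if test == "t-test":
        res = sps.ttest_ind(a, b, equal_var=False)
        statistic, p = float(res.statistic), float(res.pvalue)
    else:
        pooled = np.concatenate([a, b])
        no_ties = len(np.unique(pooled)) == len(pooled)
        method = "exact" if (no_ties and max(len(a), len(b)) <= _EXACT_MAX_N) else "asymptotic"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        statistic, p = float(res.statistic), float(res.pvalue)

    mean_a, mean_b = float(a.mean()), float(b.mean())
    if not (mean_a > 0 and mean_b > 0):
        raise ValidationError("group means must be > 0 for fold-change reporting")
    return GroupComparison(
        probe_id=probe_id, group_a=group_a, group_b=group_b,
        n_a=len(a), mean_a=mean_a, sd_a=float(a.std(ddof=1)),
        n_b=len(b), mean_b=mean_b, sd_b=float(b.std(ddof=1)),
        test_used=test, statistic=statistic, p_value=min(p, 1.0),
        fold_change=mean_b / mean_a, alpha=alpha,
        significant=bool(min(p, 1.0) < alpha),
    )


def compare_groups(summaries, probe_id: str, class_a: str, class_b: str,
                   alpha: float = 0.05, normality_alpha: float = 0.05,
                   force_test: str | None = None) -> GroupComparison:
    """Compare two tissue classes' per-sample mean ratios for one probe."""
    df = _to_frame(summaries)
    sel = df[df["probe_id"] == probe_id] if "probe_id" in df.columns else df
    a = sel.loc[sel["tissue_class"] == class_a, "mean_ratio"].to_numpy()
    b = sel.loc[sel["tissue_class"] == class_b, "mean_ratio"].to_numpy()
    return compare_values(a, b, probe_id=probe_id, group_a=class_a,
                          group_b=class_b, alpha=alpha,
                          normality_alpha=normality_alpha, force_test=force_test)


def fold_change(mean_a: float, mean_b: float, ndigits: int | None = None) -> float:
    """``mean_b / mean_a`` (e.g. cancer over normal), optionally rounded."""
    if not (mean_a > 0 and mean_b > 0):
        raise ValidationError("fold change requires strictly positive means")
    fc = mean_b / mean_a
    return round(fc, ndigits) if ndigits is not None else fc


def fit_threshold(summaries, probe_id: str, positive_class: str = "cancer",
                  direction: str | None = None) -> ClassifierRule:
    """Threshold maximizing Youden's J over midpoints of sorted sample means.

    ``direction`` defaults to the probe's calibrated directionality (SG1:
    cancer above; SE1: cancer below).  Ties in J are broken toward the
    candidate with the widest margin to the nearest sample.
    """
    df = _to_frame(summaries)
    sel = df[df["probe_id"] == probe_id] if "probe_id" in df.columns else df
    pos = sel.loc[sel["tissue_class"] == positive_class, "mean_ratio"].to_numpy()
    neg = sel.loc[sel["tissue_class"] != positive_class, "mean_ratio"].to_numpy()
    if len(pos) == 0 or len(neg) == 0:
        raise AnalysisError(
            f"need samples of both {positive_class!r} and other classes for probe {probe_id}"
        )
    if direction is None:
        if probe_id in IMAGING_CALIBRATIONS:
            direction = "above" if IMAGING_CALIBRATIONS[probe_id].direction == "up" else "below"
        else:
            direction = "above" if pos.mean() >= neg.mean() else "below"

    values = np.sort(np.unique(np.concatenate([pos, neg])))
    if len(values) == 1:
        candidates = np.array([values[0]])
    else:
        candidates = (values[:-1] + values[1:]) / 2.0

    def youden(thr: float) -> float:
        if direction == "above":
            sens = np.mean(pos > thr)
            spec = np.mean(neg <= thr)
        else:
            sens = np.mean(pos < thr)
            spec = np.mean(neg >= thr)
        return float(sens + spec - 1.0)

    js = np.array([youden(c) for c in candidates])
    best = np.flatnonzero(js == js.max())
    if len(best) > 1:
        all_vals = np.concatenate([pos, neg])
        margins = [np.min(np.abs(all_vals - candidates[i])) for i in best]
        best = [best[int(np.argmax(margins))]]
    return ClassifierRule(probe_id=probe_id, threshold=float(candidates[best[0]]),
                          direction=direction)


def evaluate_classifier(rule: ClassifierRule, summaries,
                        positive_class: str = "cancer") -> ClassifierEvaluation:
    """Confusion counts and sensitivity/specificity of a threshold rule.

    Every sample must carry a tissue-class label; undefined rates (empty
    denominators) are reported as ``None``.
    """
    df = _to_frame(summaries)
    sel = df[df["probe_id"] == rule.probe_id] if "probe_id" in df.columns else df
    tp = fp = tn = fn = 0
    for _, row in sel.iterrows():
        label = row.get("tissue_class")
        if label is None or (isinstance(label, float) and np.isnan(label)):
            raise ValidationError(f"sample {row.get('sample_id')!r} has no tissue class label")
        pred = rule.predict(float(row["mean_ratio"]))
        truth = label == positive_class
        if truth and pred:
            tp += 1
        elif truth:
            fn += 1
        elif pred:
            fp += 1
        else:
            tn += 1
    total = tp + fp + tn + fn
    return ClassifierEvaluation(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=tp / (tp + fn) if (tp + fn) else None,
        specificity=tn / (tn + fp) if (tn + fp) else None,
        accuracy=(tp + tn) / total if total else None,
    )


def comparison_table(summaries, probes: Iterable[str], alpha: float = 0.05,
                     bonferroni: bool = False) -> pd.DataFrame:
    """All pairwise class comparisons per probe as one tidy table.

    Unadjusted p-values by default; ``bonferroni=True`` additionally reports
    p-values multiplied by the number of comparisons (capped at 1).
    """
    from itertools import combinations

    df = _to_frame(summaries)
    rows = []
    for probe in probes:
        classes = [c for c in ("normal", "ulcer", "adenoma", "cancer")
                   if (df["probe_id"] == probe).any()
                   and ((df["probe_id"] == probe) & (df["tissue_class"] == c)).sum() >= 2]
        for a, b in combinations(classes, 2):
            c = compare_groups(df, probe, a, b, alpha=alpha)
            rows.append({
                "probe_id": probe, "group_a": a, "group_b": b,
                "n_a": c.n_a, "mean_a": c.mean_a, "sd_a": c.sd_a,
                "n_b": c.n_b, "mean_b": c.mean_b, "sd_b": c.sd_b,
                "test": c.test_used, "statistic": c.statistic,
                "p_value": c.p_value, "fold_change": c.fold_change,
                "significant": c.significant,
            })
    table = pd.DataFrame(rows)
    if bonferroni and len(table):
        table["p_bonferroni"] = np.minimum(table["p_value"] * len(table), 1.0)
        table["significant"] = table["p_bonferroni"] < alpha
    return table
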