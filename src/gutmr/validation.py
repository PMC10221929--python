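"""Biomarker-evaluation statistics for the clinical validation cohort.

ROC/AUC, Youden-index cutoff selection, confusion-matrix metrics, Pearson
correlation and group-comparison dispatch.  The classification rule used
throughout is strict: a subject is called positive when its score exceeds
the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


class DegenerateCurveError(ValueError):
    """ROC requested on single-class input."""


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC over all observed thresholds.

    ``thresholds`` are ordered from high to low (the curve runs from (0,0)
    to (1,1)); the final threshold is −inf so the curve always reaches
    (1,1).  ``auc`` is the trapezoidal area, which coincides with the
    all-pairs concordance statistic.
    """

    thresholds: tuple[float, ...]
    sensitivity: tuple[float, ...]
    specificity: tuple[float, ...]
    auc: float

    def __post_init__(self) -> None:
        sens = np.asarray(self.sensitivity)
        fpr = 1.0 - np.asarray(self.specificity)
        if np.any(np.diff(sens) < 0) or np.any(np.diff(fpr) < 0):
            raise ValueError("ROC curve must be monotone")
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("auc must lie in [0,1]")


@dataclass(frozen=True)
class ConfusionSummary:
    """2x2 classification counts and the derived metrics."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total if self.total else float("nan")


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> RocCurve:
    """Empirical ROC curve and AUC for binary labels (1 = case).

    The curve enumerates every observed score as a threshold with the strict
    ``score > threshold`` positivity rule, plus −inf so that (1,1) is always
    reached.  The trapezoidal AUC equals the all-pairs statistic
    (#{case > control} + ½#{ties}) / (n₁·n₀).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise DegenerateCurveError("both classes must be present for a ROC curve")

    thresholds = np.concatenate([np.unique(scores)[::-1], [-np.inf]])
    pred = scores[None, :] > thresholds[:, None]
    tp = (pred & (labels == 1)).sum(axis=1)
    fp = (pred & (labels == 0)).sum(axis=1)
    sens = tp / n1
    spec = 1.0 - fp / n0
    auc = float(np.trapezoid(sens, 1.0 - spec))
    return RocCurve(
        thresholds=tuple(float(t) for t in thresholds),
        sensitivity=tuple(float(s) for s in sens),
        specificity=tuple(float(s) for s in spec),
        auc=auc,
    )


def youden_cutoff(curve: RocCurve) -> tuple[float, bool]:
    """Threshold maximizing Youden's J = sensitivity + specificity − 1.

    Only finite observed thresholds are candidates.  Ties on J break toward
    the higher threshold (the more specific classifier).  When the best J is
    0 (an uninformative curve) the lowest finite threshold is returned with
    the degeneracy flag set.

    Returns ``(cutoff, degenerate)``.
    """
    ts = np.asarray(curve.thresholds)
    j_stat = np.asarray(curve.sensitivity) + np.asarray(curve.specificity) - 1.0
    finite = np.isfinite(ts)
    ts, j_stat = ts[finite], j_stat[finite]
    if ts.size == 0:
        raise ValueError("curve has no finite thresholds")
    j_max = float(j_stat.max())
    if j_max <= 0.0:
        return float(ts.min()), True
    # thresholds are stored high→low; argmax takes the first = highest tied
    return float(ts[int(np.argmax(j_stat))]), False


def confusion_at(
    scores: Sequence[float], labels: Sequence[int], cutoff: float
) -> ConfusionSummary:
    """Confusion counts with the strict ``score > cutoff`` positivity rule."""
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = scores > cutoff
    return ConfusionSummary(
        tp=int((pred & (labels == 1)).sum()),
        fp=int((pred & (labels == 0)).sum()),
        tn=int((~pred & (labels == 0)).sum()),
        fn=int((~pred & (labels == 1)).sum()),
    )


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment correlation with the two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("series must have equal length")
    if x.size < 3:
        raise ValueError("pearson_r needs n >= 3")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValueError("correlation undefined for a zero-variance series")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class GroupTestResult:
    """Which comparison ran, its statistic and p-value, and the screen."""

    test: str
    statistic: float
    pvalue: float
    family: str
    screen: dict | None = None
    degenerate: bool = False


def _normality_screen(groups: list[np.ndarray], alpha: float = 0.05) -> tuple[bool, dict]:
    """Shapiro normality per group plus a Levene homogeneity check."""
    screen: dict = {"shapiro_p": [], "levene_p": None}
    normal = True
    for g in groups:
        if g.size < 3 or np.ptp(g) == 0.0:
            screen["shapiro_p"].append(None)
            normal = False
            continue
        p = float(stats.shapiro(g).pvalue)
        screen["shapiro_p"].append(p)
        normal = normal and p >= alpha
    if all(g.size >= 2 and np.ptp(g) > 0 for g in groups):
        lev = float(stats.levene(*groups).pvalue)
        screen["levene_p"] = lev
        normal = normal and lev >= alpha
    else:
        normal = False
    return normal, screen


def group_compare(
    values: Sequence[float],
    groups: Sequence,
    family: str = "auto",
) -> GroupTestResult:
    """Two-group or k-group location comparison.

    ``family`` is ``"parametric"`` (t-test / one-way ANOVA),
    ``"nonparametric"`` (Wilcoxon rank-sum / Kruskal-Wallis) or ``"auto"``,
    which runs a Shapiro + Levene screen at 0.05 and picks the parametric
    family only when every group passes.  The result records which test ran
    and, for ``auto``, the screen p-values.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(groups)
    uniq = list(dict.fromkeys(labels.tolist()))
    if len(uniq) < 2:
        raise ValueError("group_compare needs >= 2 groups")
    samples = [values[labels == g] for g in uniq]

    screen = None
    if family == "auto":
        normal, screen = _normality_screen(samples)
        chosen = "parametric" if normal else "nonparametric"
    elif family in ("parametric", "nonparametric"):
        chosen = family
    else:
        raise ValueError(f"unknown family {family!r}")

    if chosen == "parametric" and any(s.size < 2 for s in samples):
        raise ValueError("parametric tests need >= 2 observations per group")

    pooled = np.concatenate(samples)
    if np.ptp(pooled) == 0.0:
        # identical constant data: no location difference detectable
        return GroupTestResult(
            test="degenerate", statistic=0.0, pvalue=1.0,
            family=chosen, screen=screen, degenerate=True,
        )

    if len(uniq) == 2:
        if chosen == "parametric":
            res = stats.ttest_ind(samples[0], samples[1])
            name = "t-test"
        else:
            res = stats.mannwhitneyu(samples[0], samples[1],
                                     alternative="two-sided")
            name = "wilcoxon-rank-sum"
    else:
        if chosen == "parametric":
            res = stats.f_oneway(*samples)
            name = "one-way-anova"
        else:
            res = stats.kruskal(*samples)
            name = "kruskal-wallis"
    return GroupTestResult(
        test=name, statistic=float(res.statistic), pvalue=float(res.pvalue),
        family=chosen, screen=screen,
    )


def chi_square_table(table: np.ndarray) -> GroupTestResult:
    """Chi-square test on a contingency table of counts."""
    res = stats.chi2_contingency(np.asarray(table))
    return GroupTestResult(
        test="chi-square", statistic=float(res.statistic),
        pvalue=float(res.pvalue), family="count",
    )
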