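"""Diagnostic test metrics for LOOCV score distributions.

Turns the two per-group "% classified mass peaks" score distributions into
the usual screening-test summary: an SD-balanced cut-off, confusion counts,
sensitivity / specificity / efficiency, a group-separation p-value, Cohen's
d with a noncentral-t power estimate, and an ROC curve.

The cut-off convention: the threshold sits between the two group score means
at the same number k of standard deviations from each —
``cutoff = m2 + k·s2 = m1 − k·s1`` with ``k = (m1 − m2)/(s1 + s2)`` — so a
large k means widely separated, tight distributions.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn import metrics as skmetrics

from .errors import ValidationError
from .loocv import LOOCVResult

logger = logging.getLogger("seroprofile")


# ---------------------------------------------------------------------------
# cut-off rule
# ---------------------------------------------------------------------------

@dataclass
class CutoffRule:
    """SD-balanced score threshold between two group means (m1 > m2)."""

    m1: float
    s1: float
    m2: float
    s2: float
    k: float          # SD multiplier; inf flags zero-spread separation
    cutoff: float     # % score threshold
    swapped: bool = False   # True if the input groups arrived with m1 < m2
    degenerate: bool = False


def cutoff_from_moments(m1: float, s1: float, m2: float, s2: float,
                        swapped: bool = False) -> CutoffRule:
    """SD-balanced cut-off from the two score means and SDs.

    k = (m1 − m2)/(s1 + s2); cutoff = m2 + k·s2 (= m1 − k·s1).  If both SDs
    are zero the groups are perfectly separated: the cutoff falls back to
    the midpoint and k is flagged infinite.
    """
    if s1 + s2 == 0:
        return CutoffRule(m1=m1, s1=s1, m2=m2, s2=s2, k=math.inf,
                          cutoff=(m1 + m2) / 2.0, swapped=swapped, degenerate=True)
    k = (m1 - m2) / (s1 + s2)
    return CutoffRule(m1=m1, s1=s1, m2=m2, s2=s2, k=k,
                      cutoff=m2 + k * s2, swapped=swapped)


def derive_cutoff(scores_g1, scores_g2) -> CutoffRule:
    """Cut-off equidistant from both group means in units of each group's
    sample SD (n−1 divisor); see :func:`cutoff_from_moments`."""
    x1 = np.asarray(scores_g1, dtype=float)
    x2 = np.asarray(scores_g2, dtype=float)
    if x1.size < 2 or x2.size < 2:
        raise ValidationError("need at least 2 defined scores per group")
    m1, s1 = float(x1.mean()), float(x1.std(ddof=1))
    m2, s2 = float(x2.mean()), float(x2.std(ddof=1))
    swapped = m1 < m2
    if swapped:
        logger.warning("group-1 score mean below group-2; swapping for the cut-off")
        m1, s1, m2, s2 = m2, s2, m1, s1
    return cutoff_from_moments(m1, s1, m2, s2, swapped=swapped)


# ---------------------------------------------------------------------------
# confusion counts and rates
# ---------------------------------------------------------------------------

@dataclass
class TestMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    efficiency: float
    tpr: float
    fpr: float
    cutoff_rule: CutoffRule | None = None
    separation_p: float | None = None
    cohens_d: float | None = None
    cohens_d_display: float | None = None
    power: float | None = None
    roc_fpr: np.ndarray | None = None
    roc_tpr: np.ndarray | None = None
    auc: float | None = None
    n_excluded: int = 0

    def to_dict(self) -> dict:
        d = {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "efficiency": self.efficiency, "tpr": self.tpr, "fpr": self.fpr,
            "separation_p": self.separation_p,
            "cohens_d": self.cohens_d,
            "cohens_d_display": self.cohens_d_display,
            "power": self.power, "auc": self.auc,
            "n_excluded": self.n_excluded,
        }
        if self.cutoff_rule is not None:
            c = self.cutoff_rule
            d["cutoff"] = {
                "m1": c.m1, "s1": c.s1, "m2": c.m2, "s2": c.s2,
                "k": None if math.isinf(c.k) else c.k,
                "k_infinite": math.isinf(c.k),
                "cutoff": c.cutoff, "degenerate": c.degenerate,
            }
        return d


def rates_from_counts(tp: int, fp: int, tn: int, fn: int) -> TestMetrics:
    """Sensitivity TP/(TP+FN), specificity TN/(TN+FP), efficiency
    (TP+TN)/total, directly from confusion counts."""
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    eff = (tp + tn) / (tp + fp + tn + fn) if tp + fp + tn + fn else float("nan")
    fpr = fp / (fp + tn) if fp + tn else float("nan")
    return TestMetrics(tp=tp, fp=fp, tn=tn, fn=fn, sensitivity=sens,
                       specificity=spec, efficiency=eff, tpr=sens, fpr=fpr)


def confusion_metrics(scores, labels, cutoff: float, positive_label: str) -> TestMetrics:
    """Counts and rates at a fixed cut-off.

    A score strictly above the cut-off predicts the positive (group-1)
    label; at or below predicts the other.  Undefined (NaN) scores are
    excluded and counted in ``n_excluded``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    defined = ~np.isnan(scores)
    n_excluded = int(np.count_nonzero(~defined))
    if n_excluded:
        logger.warning("%d undefined score(s) excluded from confusion counts",
                       n_excluded)
    scores, labels = scores[defined], labels[defined]
    pos = labels == positive_label
    pred_pos = scores > cutoff
    tp = int(np.count_nonzero(pos & pred_pos))
    fn = int(np.count_nonzero(pos & ~pred_pos))
    fp = int(np.count_nonzero(~pos & pred_pos))
    tn = int(np.count_nonzero(~pos & ~pred_pos))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    eff = (tp + tn) / (tp + fp + tn + fn) if tp + fp + tn + fn else float("nan")
    fpr = fp / (fp + tn) if fp + tn else float("nan")
    return TestMetrics(tp=tp, fp=fp, tn=tn, fn=fn,
                       sensitivity=sens, specificity=spec, efficiency=eff,
                       tpr=sens, fpr=fpr, n_excluded=n_excluded)


# ---------------------------------------------------------------------------
# separation, effect size, power
# ---------------------------------------------------------------------------

def separation_pvalue(scores_g1, scores_g2, alternative: str = "two-sided") -> float:
    """Welch t-test p-value between the two score distributions."""
    x1 = np.asarray(scores_g1, dtype=float)
    x2 = np.asarray(scores_g2, dtype=float)
    if x1.size < 2 or x2.size < 2:
        raise ValidationError("need at least 2 defined scores per group")
    if x1.var(ddof=1) == 0 and x2.var(ddof=1) == 0:
        return 1.0 if x1.mean() == x2.mean() else 0.0
    res = stats.ttest_ind(x1, x2, equal_var=False, alternative=alternative)
    return float(res.pvalue)


def cohens_d(m1: float, s1: float, m2: float, s2: float) -> float:
    """Cohen's d = (m1 − m2) / sqrt((s1² + s2²)/2), regardless of group sizes."""
    if s1 < 0 or s2 < 0:
        raise ValidationError("standard deviations must be non-negative")
    pooled = math.sqrt((s1 ** 2 + s2 ** 2) / 2.0)
    if pooled == 0:
        if m1 == m2:
            return 0.0
        return math.copysign(math.inf, m1 - m2)
    return (m1 - m2) / pooled


def truncate2(x: float) -> float:
    """Truncate (toward zero) to 2 decimals — the display convention for d."""
    if math.isinf(x) or math.isnan(x):
        return x
    return math.trunc(x * 100) / 100.0


def power_estimate(d: float, n1: int, n2: int, alpha: float = 0.05) -> float:
    """Two-sample t-test power at effect size d via the noncentral t.

    ncp = d·sqrt(n1·n2/(n1+n2)), df = n1+n2−2, two-sided alpha.
    d = 0 recovers the type-I rate alpha.
    """
    if n1 < 2 or n2 < 2:
        raise ValidationError("need n ≥ 2 per group for a power estimate")
    if d < 0:
        d = -d
    if math.isinf(d):
        return 1.0
    df = n1 + n2 - 2
    ncp = d * math.sqrt(n1 * n2 / (n1 + n2))
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    upper = stats.nct.sf(tcrit, df, ncp)
    lower = stats.nct.cdf(-tcrit, df, ncp)
    # scipy's noncentral-t far tail can underflow to NaN at large ncp;
    # that term is then vanishingly small
    if math.isnan(lower):
        lower = 0.0
    if math.isnan(upper):
        upper = float(stats.norm.sf(tcrit - ncp))
    return float(upper + lower)


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

def roc_curve(scores, labels, positive_label: str):
    """ROC points and trapezoidal AUC over all observed score thresholds.

    Tied scores are grouped into single threshold steps, so the AUC equals
    the Mann–Whitney statistic (#concordant + ½·#ties)/(n1·n2).
    Returns (fpr, tpr, auc).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    defined = ~np.isnan(scores)
    scores, labels = scores[defined], labels[defined]
    y = labels == positive_label
    if y.all() or not y.any():
        raise ValidationError("ROC needs both classes present")
    fpr, tpr, _ = skmetrics.roc_curve(y.astype(int), scores,
                                      drop_intermediate=False)
    return fpr, tpr, float(skmetrics.auc(fpr, tpr))


# ---------------------------------------------------------------------------
# one-call evaluation of a LOOCV result
# ---------------------------------------------------------------------------

def evaluate(result: LOOCVResult, alpha: float = 0.05) -> TestMetrics:
    """Full Table-2-style metrics from an LOOCV result.

    The cut-off is derived from the two score distributions, confusion
    counts are taken at it (positive = group 1), and separation p, Cohen's
    d (full precision + truncated display twin), noncentral-t power and the
    ROC are attached.
    """
    g1, g2 = result.group_labels
    x1 = result.scores_in(g1)
    x2 = result.scores_in(g2)
    rule = derive_cutoff(x1, x2)
    defined = [s for s in result.scores if s.defined]
    scores = [s.pct_group1 for s in defined]
    labels = [s.true_group for s in defined]
    tm = confusion_metrics(scores, labels, rule.cutoff, positive_label=g1)
    tm.cutoff_rule = rule
    tm.n_excluded = result.n_undefined()
    tm.separation_p = separation_pvalue(x1, x2)
    d = cohens_d(float(x1.mean()), float(x1.std(ddof=1)),
                 float(x2.mean()), float(x2.std(ddof=1)))
    tm.cohens_d = d
    tm.cohens_d_display = truncate2(d)
    tm.power = power_estimate(abs(d) if not math.isinf(d) else math.inf,
                              x1.size, x2.size, alpha=alpha)
    tm.roc_fpr, tm.roc_tpr, tm.auc = roc_curve(scores, labels, positive_label=g1)
    return tm


def write_metrics_json(tm: TestMetrics, path) -> None:
    from pathlib import Path
    Path(path).write_text(json.dumps(tm.to_dict(), indent=2) + "\n")


def write_roc_tsv(tm: TestMetrics, path) -> None:
    from pathlib import Path
    lines = ["fpr\ttpr"]
    lines += [f"{repr(float(a))}\t{repr(float(b))}"
              for a, b in zip(tm.roc_fpr, tm.roc_tpr)]
    Path(path).write_text("\n".join(lines) + "\n")
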