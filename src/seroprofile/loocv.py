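"""Leave-one-out cross-validated mass-peak discrimination.

The discriminator works per unit m/Z.  For each left-out serum sample, the
remaining N−1 samples ("left in") are screened bin by bin with one-tailed
unequal-variance (Welch) t-tests; bins significant at ``alpha`` whose larger
group-mean area clears a minimum-abundance filter form that fold's
significant-peak set.  Each selected peak carries a peak classification
value (PCV) — the midpoint of the two left-in group means — and the left-out
sample's area at that m/Z classifies to the higher-mean group iff it exceeds
the PCV ("at or below" classifies to the other group).  A sample's score is
the percentage of the fold's peaks that classified to group 1; the two group
score distributions are what all downstream test metrics are computed from.

No multiple-testing correction is applied to the per-bin p-values: the
randomization null (see :mod:`seroprofile.randomization`) is the procedure's
over-fitting control.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ConfigurationError, ValidationError
from .preprocess import SampleProfile

logger = logging.getLogger("seroprofile")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class DiscriminationParams:
    """Peak-selection settings.

    alpha          : per-bin one-tailed significance level (default 0.05)
    min_peak_frac  : abundance floor — a bin is tested only if its larger
                     group-mean area is at least this fraction of the maximum
                     group-mean area anywhere in the left-in dataset
                     (default 0.003, i.e. 0.3%)
    analysis_range : unit-m/Z range searched for discriminatory peaks
                     (default 400–1908; may be narrower than the
                     normalization range)
    """

    alpha: float = 0.05
    min_peak_frac: float = 0.003
    analysis_range: tuple[int, int] = (400, 1908)

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")
        if not 0 <= self.min_peak_frac < 1:
            raise ConfigurationError("min_peak_frac must be in [0, 1)")
        lo, hi = self.analysis_range
        if lo >= hi:
            raise ConfigurationError(f"invalid analysis_range [{lo}, {hi}]")


@dataclass
class SignificantPeak:
    """One discriminatory unit-m/Z peak selected on a left-in dataset."""

    mz: int
    p_value: float
    mean_g1: float
    mean_g2: float
    pcv: float          # classification threshold: midpoint of the two means
    high_group: str     # label of the group with the larger mean
    low_group: str


@dataclass
class SignificantPeakSet:
    """Per-fold selected peaks.  ``left_out_id`` is "none" for full-set training."""

    left_out_id: str
    peaks: list[SignificantPeak]
    group_labels: tuple[str, str] = ("group1", "group2")

    def __post_init__(self) -> None:
        mzs = [p.mz for p in self.peaks]
        if len(mzs) != len(set(mzs)):
            raise ValidationError("duplicate m/Z in significant peak set")

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    @property
    def mz_values(self) -> list[int]:
        return [p.mz for p in self.peaks]


@dataclass
class SampleScore:
    """% of a fold's significant peaks classified to group 1 for one sample."""

    sample_id: str
    true_group: str
    pct_group1: float   # NaN if the fold had no significant peaks
    n_peaks_used: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.pct_group1)

    @property
    def pct_group2(self) -> float:
        return 100.0 - self.pct_group1


@dataclass
class LOOCVResult:
    scores: list[SampleScore]
    peak_count_range: tuple[int, int]
    params: DiscriminationParams
    group_labels: tuple[str, str] = ("group1", "group2")
    warnings: list[str] = field(default_factory=list)

    def scores_in(self, group: str) -> np.ndarray:
        """Defined scores (pct_group1) of samples whose true group is ``group``."""
        return np.array([s.pct_group1 for s in self.scores
                         if s.true_group == group and s.defined])

    def n_undefined(self) -> int:
        return sum(not s.defined for s in self.scores)


# ---------------------------------------------------------------------------
# Welch one-tailed test
# ---------------------------------------------------------------------------

def _welch_p_vec(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Vectorized one-tailed Welch p per column.

    The tail is taken in the direction of the observed mean difference, so
    p = P(T ≥ |t|) under the Welch–Satterthwaite df; equal means give 0.5.
    Degenerate columns (both variances zero): p = 1 if the means are equal,
    else 0.
    """
    n1, n2 = x1.shape[0], x2.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValidationError("each group needs at least 2 samples for a t-test")
    m1 = x1.mean(axis=0)
    m2 = x2.mean(axis=0)
    v1 = x1.var(axis=0, ddof=1)
    v2 = x2.var(axis=0, ddof=1)
    se2 = v1 / n1 + v2 / n2
    degen = se2 == 0
    safe = np.where(degen, 1.0, se2)
    t = np.abs(m1 - m2) / np.sqrt(safe)
    num = safe ** 2
    den = (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
    df = num / np.where(den == 0, 1.0, den)
    p = stats.t.sf(t, df)
    return np.where(degen, np.where(m1 == m2, 1.0, 0.0), p)


def welch_t_one_tailed(xs, ys) -> float:
    """One-tailed unequal-variance t-test p-value, tail per the observed
    mean difference.  Equal means → 0.5; both groups constant and equal → 1.0;
    constant but different → 0.0."""
    x = np.asarray(xs, dtype=float).reshape(-1, 1)
    y = np.asarray(ys, dtype=float).reshape(-1, 1)
    return float(_welch_p_vec(x, y)[0])


# ---------------------------------------------------------------------------
# peak selection and PCV classification
# ---------------------------------------------------------------------------

def _area_matrix(profiles: list[SampleProfile], lo: int, hi: int) -> np.ndarray:
    return np.vstack([p.restricted(lo, hi) for p in profiles])


def select_significant_peaks(group1: list[SampleProfile],
                             group2: list[SampleProfile],
                             params: DiscriminationParams | None = None,
                             group_labels: tuple[str, str] | None = None,
                             left_out_id: str = "none") -> SignificantPeakSet:
    """Screen every unit m/Z in the analysis range on a left-in dataset.

    A bin is kept if (a) its larger group-mean area is at least
    ``min_peak_frac`` of the maximum group-mean area over the whole left-in
    dataset, and (b) the one-tailed Welch p-value is below ``alpha``.  Each
    kept peak records the group means, their midpoint as the PCV, and which
    group had the larger mean.
    """
    params = params or DiscriminationParams()
    if group_labels is None:
        group_labels = (group1[0].group or "group1", group2[0].group or "group2")
    if len(group1) < 2 or len(group2) < 2:
        raise ValidationError("need at least 2 left-in samples per group")
    lo, hi = params.analysis_range
    x1 = _area_matrix(group1, lo, hi)
    x2 = _area_matrix(group2, lo, hi)
    m1 = x1.mean(axis=0)
    m2 = x2.mean(axis=0)
    larger = np.maximum(m1, m2)
    floor = params.min_peak_frac * larger.max() if larger.size else 0.0
    abundant = larger >= floor
    p = _welch_p_vec(x1, x2)
    selected = abundant & (p < params.alpha)
    g1, g2 = group_labels
    peaks = []
    for j in np.flatnonzero(selected):
        hi_grp, lo_grp = (g1, g2) if m1[j] > m2[j] else (g2, g1)
        peaks.append(SignificantPeak(
            mz=int(lo + j), p_value=float(p[j]),
            mean_g1=float(m1[j]), mean_g2=float(m2[j]),
            pcv=float((m1[j] + m2[j]) / 2.0),
            high_group=hi_grp, low_group=lo_grp,
        ))
    if not peaks:
        logger.warning("no significant peaks selected (left_out=%s)", left_out_id)
    return SignificantPeakSet(left_out_id=left_out_id, peaks=peaks,
                              group_labels=group_labels)


def pcv_classify(area: float, peak: SignificantPeak) -> str:
    """Classify one left-out peak area against a PCV threshold.

    Above the PCV → the higher-mean group; at or below → the other group.
    """
    return peak.high_group if area > peak.pcv else peak.low_group


def score_profile(profile: SampleProfile, peak_set: SignificantPeakSet) -> SampleScore:
    """% of the set's peaks whose areas in ``profile`` classify to group 1."""
    g1 = peak_set.group_labels[0]
    n = peak_set.n_peaks
    if n == 0:
        return SampleScore(sample_id=profile.sample_id, true_group=profile.group,
                           pct_group1=float("nan"), n_peaks_used=0)
    hits = sum(
        pcv_classify(profile.area_by_mz[p.mz - profile.lo]
                     if profile.lo <= p.mz <= profile.hi else 0.0, p) == g1
        for p in peak_set.peaks
    )
    return SampleScore(sample_id=profile.sample_id, true_group=profile.group,
                       pct_group1=100.0 * hits / n, n_peaks_used=n)


# ---------------------------------------------------------------------------
# the LOOCV loop
# ---------------------------------------------------------------------------

def loocv_score(profiles: list[SampleProfile],
                params: DiscriminationParams | None = None,
                group_labels: tuple[str, str] | None = None) -> LOOCVResult:
    """Leave-one-sample-out scoring of a two-group cohort.

    For each sample in turn: its profile is removed entirely, significant
    peaks are re-selected on the remaining N−1 samples, and the left-out
    sample's areas are classified peak by peak against that fold's PCVs.
    The left-out sample contributes nothing to selection, means or PCVs.
    A fold with zero significant peaks yields an undefined (NaN) score,
    excluded from downstream metrics with a loud warning.
    """
    params = params or DiscriminationParams()
    if group_labels is None:
        seen: list[str] = []
        for p in profiles:
            if p.group not in seen:
                seen.append(p.group)
        if len(seen) != 2:
            raise ValidationError(f"expected 2 groups, found {seen}")
        group_labels = (seen[0], seen[1])
    g1, g2 = group_labels
    n1 = sum(p.group == g1 for p in profiles)
    n2 = sum(p.group == g2 for p in profiles)
    if n1 < 3 or n2 < 3:
        raise ValidationError(
            f"need at least 3 samples per group for LOOCV (got {n1}, {n2})"
        )
    scores: list[SampleScore] = []
    counts: list[int] = []
    warnings: list[str] = []
    for i, left_out in enumerate(profiles):
        left_in = [p for j, p in enumerate(profiles) if j != i]
        peak_set = select_significant_peaks(
            [p for p in left_in if p.group == g1],
            [p for p in left_in if p.group == g2],
            params, group_labels=group_labels, left_out_id=left_out.sample_id,
        )
        score = score_profile(left_out, peak_set)
        if not score.defined:
            msg = f"fold {left_out.sample_id}: zero significant peaks, score undefined"
            logger.warning(msg)
            warnings.append(msg)
        else:
            counts.append(peak_set.n_peaks)
        scores.append(score)
    rng = (min(counts), max(counts)) if counts else (0, 0)
    return LOOCVResult(scores=scores, peak_count_range=rng, params=params,
                       group_labels=group_labels, warnings=warnings)


def write_scores_tsv(result: LOOCVResult, path) -> None:
    from pathlib import Path
    lines = ["sample_id\ttrue_group\tpct_group1\tn_peaks_used"]
    lines += [
        f"{s.sample_id}\t{s.true_group}\t{repr(s.pct_group1)}\t{s.n_peaks_used}"
        for s in result.scores
    ]
    Path(path).write_text("\n".join(lines) + "\n")
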