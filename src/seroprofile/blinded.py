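"""Training-set / blinded-sample validation.

A discriminator is frozen on a training cohort — a single significant-peak
set selected on *all* training samples, plus the SD-balanced cut-off derived
from the training LOOCV score distributions — and then applied unchanged to
samples the training never saw.  Each blinded sample is scored against the
frozen peak set's PCVs, and its score is compared to the frozen cut-off.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass

from .errors import TrainingError
from .evaluation import CutoffRule, derive_cutoff
from .loocv import (
    DiscriminationParams,
    LOOCVResult,
    SampleScore,
    SignificantPeakSet,
    loocv_score,
    score_profile,
    select_significant_peaks,
)
from .preprocess import SampleProfile

logger = logging.getLogger("seroprofile")


@dataclass
class TrainedDiscriminator:
    peaks: SignificantPeakSet        # selected once on all training samples
    cutoff_rule: CutoffRule          # from the training LOOCV score distributions
    params: DiscriminationParams
    group_labels: tuple[str, str]
    training_manifest_hash: str
    training_loocv: LOOCVResult | None = None


def _training_hash(profiles: list[SampleProfile]) -> str:
    items = sorted((p.sample_id, p.group) for p in profiles)
    return hashlib.sha256(json.dumps(items).encode()).hexdigest()[:16]


def train(profiles: list[SampleProfile],
          params: DiscriminationParams | None = None,
          group_labels: tuple[str, str] | None = None) -> TrainedDiscriminator:
    """Freeze a discriminator on training samples only.

    The cut-off comes from the training LOOCV score distributions; the final
    peak set is selected once on the full training set (left_out_id "none").
    Fails if no peak is significant on the full training set.
    """
    params = params or DiscriminationParams()
    result = loocv_score(profiles, params, group_labels=group_labels)
    g1, g2 = result.group_labels
    rule = derive_cutoff(result.scores_in(g1), result.scores_in(g2))
    peaks = select_significant_peaks(
        [p for p in profiles if p.group == g1],
        [p for p in profiles if p.group == g2],
        params, group_labels=result.group_labels, left_out_id="none",
    )
    if peaks.n_peaks == 0:
        raise TrainingError("no significant peaks on the full training set")
    return TrainedDiscriminator(
        peaks=peaks, cutoff_rule=rule, params=params,
        group_labels=result.group_labels,
        training_manifest_hash=_training_hash(profiles),
        training_loocv=result,
    )


def classify_blinded(disc: TrainedDiscriminator,
                     profile: SampleProfile) -> tuple[SampleScore, str]:
    """Score one blinded sample against the frozen peak set and cut-off.

    Returns (score, predicted label): score strictly above the cut-off
    predicts group 1, at or below predicts group 2.
    """
    score = score_profile(profile, disc.peaks)
    g1, g2 = disc.group_labels
    label = g1 if score.pct_group1 > disc.cutoff_rule.cutoff else g2
    return score, label


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def discriminator_to_dict(disc: TrainedDiscriminator) -> dict:
    return {
        "group_labels": list(disc.group_labels),
        "training_manifest_hash": disc.training_manifest_hash,
        "params": {
            "alpha": disc.params.alpha,
            "min_peak_frac": disc.params.min_peak_frac,
            "analysis_range": list(disc.params.analysis_range),
        },
        "cutoff": {
            "m1": disc.cutoff_rule.m1, "s1": disc.cutoff_rule.s1,
            "m2": disc.cutoff_rule.m2, "s2": disc.cutoff_rule.s2,
            "k": disc.cutoff_rule.k if disc.cutoff_rule.k != float("inf") else None,
            "cutoff": disc.cutoff_rule.cutoff,
        },
        "peaks": [
            {"mz": p.mz, "p_value": p.p_value, "mean_g1": p.mean_g1,
             "mean_g2": p.mean_g2, "pcv": p.pcv,
             "high_group": p.high_group, "low_group": p.low_group}
            for p in disc.peaks.peaks
        ],
    }


def discriminator_from_dict(d: dict) -> TrainedDiscriminator:
    from .loocv import SignificantPeak

    labels = tuple(d["group_labels"])
    peaks = SignificantPeakSet(
        left_out_id="none",
        peaks=[SignificantPeak(**p) for p in d["peaks"]],
        group_labels=labels,
    )
    c = d["cutoff"]
    k = c["k"] if c["k"] is not None else float("inf")
    rule = CutoffRule(m1=c["m1"], s1=c["s1"], m2=c["m2"], s2=c["s2"],
                      k=k, cutoff=c["cutoff"], degenerate=c["k"] is None)
    params = DiscriminationParams(
        alpha=d["params"]["alpha"],
        min_peak_frac=d["params"]["min_peak_frac"],
        analysis_range=tuple(d["params"]["analysis_range"]),
    )
    return TrainedDiscriminator(peaks=peaks, cutoff_rule=rule, params=params,
                                group_labels=labels,
                                training_manifest_hash=d["training_manifest_hash"])
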