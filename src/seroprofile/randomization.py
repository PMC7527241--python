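"""Balanced label randomization — the over-fitting control.

Because thousands of unit-m/Z bins are screened without multiple-testing
correction, apparent group separation could arise from fitting noise.  The
control is to randomly re-assign the group labels — balanced so that group
sizes and the sex / age-band composition of each group are preserved — and
rerun the *identical* LOOCV analysis.  A real physiological difference
collapses toward non-significance under relabeling; residual separation
under relabeling would indicate over-fitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .cohort_io import UNKNOWN, CohortManifest
from .errors import ValidationError
from .evaluation import separation_pvalue
from .loocv import DiscriminationParams, LOOCVResult, loocv_score
from .preprocess import SampleProfile

logger = logging.getLogger("seroprofile")


@dataclass
class ShufflePlan:
    """A deterministic balanced relabeling of the cohort."""

    seed: int
    permuted_group_of: dict[str, str]    # sample_id -> permuted group label
    strata: dict[str, list[str]]         # stratum description -> sample ids
    n_fixed_strata: int = 0              # strata too small to permute


def _age_band(age, width: int) -> str:
    if age == UNKNOWN:
        return UNKNOWN
    return f"{(int(age) // width) * width}s"


def balanced_shuffle(manifest: CohortManifest, seed: int,
                     age_band_width: int = 10) -> ShufflePlan:
    """Permute group labels within (sex × age-band) strata.

    Within each stratum the multiset of group labels is shuffled among its
    members, so overall group sizes and per-stratum (hence per-sex,
    per-age-band) group compositions are conserved exactly for every seed.
    Samples with unknown sex or age form their own strata.  A stratum with a
    single sample keeps its label (logged).
    """
    if age_band_width <= 0:
        raise ValidationError("age_band_width must be positive")
    rng = np.random.default_rng(seed)
    strata: dict[str, list] = {}
    for e in manifest.entries:
        key = f"sex={e.sex},age={_age_band(e.age, age_band_width)}"
        strata.setdefault(key, []).append(e)
    permuted: dict[str, str] = {}
    n_fixed = 0
    for key in sorted(strata):
        members = strata[key]
        if len(members) < 2:
            n_fixed += 1
            logger.info("stratum %s has %d sample(s); labels left fixed",
                        key, len(members))
            for e in members:
                permuted[e.sample_id] = e.group
            continue
        labels = [e.group for e in members]
        shuffled = rng.permutation(labels)
        for e, g in zip(members, shuffled):
            permuted[e.sample_id] = str(g)
    return ShufflePlan(
        seed=seed, permuted_group_of=permuted,
        strata={k: [e.sample_id for e in v] for k, v in strata.items()},
        n_fixed_strata=n_fixed,
    )


def apply_plan(profiles: list[SampleProfile], plan: ShufflePlan) -> list[SampleProfile]:
    """Relabeled copies of the profiles (spectral data untouched)."""
    out = []
    for p in profiles:
        if p.sample_id not in plan.permuted_group_of:
            raise ValidationError(f"sample {p.sample_id!r} absent from shuffle plan")
        out.append(replace(p, group=plan.permuted_group_of[p.sample_id]))
    return out


def randomized_null(profiles: list[SampleProfile], manifest: CohortManifest,
                    params: DiscriminationParams | None = None, *,
                    seed: int, age_band_width: int = 10,
                    ) -> tuple[LOOCVResult, float]:
    """Balanced relabeling followed by the identical LOOCV analysis.

    Returns the randomized LOOCV result and the two-sided Welch separation
    p-value of its score distributions.  Deterministic given the seed.
    """
    plan = balanced_shuffle(manifest, seed, age_band_width=age_band_width)
    shuffled = apply_plan(profiles, plan)
    result = loocv_score(shuffled, params, group_labels=manifest.comparison_labels)
    g1, g2 = manifest.comparison_labels
    p = separation_pvalue(result.scores_in(g1), result.scores_in(g2))
    return result, p


def write_plan_csv(plan: ShufflePlan, manifest: CohortManifest, path) -> None:
    from pathlib import Path
    original = {e.sample_id: e.group for e in manifest.entries}
    lines = ["sample_id,original_group,permuted_group"]
    lines += [
        f"{sid},{original[sid]},{grp}"
        for sid, grp in plan.permuted_group_of.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")
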