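"""Synthetic spectra-cohort generator.

Emulates the statistical structure the discrimination pipeline assumes:
per-sample triplicate positive-ion unit-mass spectra over ~400–2000 m/Z,
two cohorts differing at a configurable set of unit-m/Z peaks with a
configurable standardized effect size, multiplicative within-sample
replicate jitter, and a per-sample global intensity scale (which local
normalization must remove).  Intensities are log-normal: each bin j has a
cohort-level log-mean mu_j, each sample draws its biological level around
mu_j with log-SD ``baseline_sigma``, and planted bins shift the group-1
log-mean by ±delta·baseline_sigma — half of the planted peaks are higher in
group 1 and half higher in group 2, mirroring real profiles in which peaks
rise in either group.

It deliberately omits isotope envelopes, charge states, chemical noise and
instrument drift: it generates exchangeable samples with planted mean
shifts, which is exactly the regime in which the pipeline's statistical
behaviour (type-I control, power, recovery) is interpretable.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .cohort_io import (
    CohortManifest,
    NominalSpectrum,
    RawSpectrum,
    SampleRecord,
    write_manifest,
    write_spectrum_tsv,
)
from .errors import ConfigurationError
from .preprocess import NormalizationParams, SampleProfile, build_profile

logger = logging.getLogger("seroprofile")


@dataclass
class SyntheticConfig:
    """Study-condition knobs for one synthetic cohort.

    Defaults mirror the acquisition described for the real cohorts:
    triplicate spectra over 400–2000 m/Z and ~130 discriminating unit-m/Z
    peaks.  Noise defaults are what direct-infusion serum ESI-MS plausibly
    delivers: ~15% replicate CV and a 0.3 log-SD per-sample loading scale.
    """

    n_g1: int = 25
    n_g2: int = 25
    n_replicates: int = 3
    mz_range: tuple[int, int] = (400, 2000)
    n_discriminating: int = 130
    effect_size: float = 1.5          # per-peak standardized mean shift, SD units
    peak_density: float = 0.2         # fraction of unit-m/Z bins carrying signal
    noise_ratio: float = 1e-4         # relative intensity of non-signal bins
    baseline_mu: float = 2.0          # cohort-level log-mean of signal-bin intensities
    baseline_mu_spread: float = 1.0   # SD of per-bin log-means (peak-to-peak variety)
    baseline_sigma: float = 0.4       # biological log-SD within a group
    replicate_cv: float = 0.15        # within-sample replicate coefficient of variation
    sample_scale_sigma: float = 0.3   # log-SD of the per-sample global scale
    sex_ratio: float = 0.5            # P(female)
    age_range: tuple[int, int] = (35, 79)
    t2dm_frac_g1: float = 0.64        # fraction of group 1 flagged diabetic
    group_labels: tuple[str, str] = ("CABG", "Control")
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_g1, self.n_g2, self.n_replicates) < 1:
            raise ConfigurationError("sample and replicate counts must be ≥ 1")
        if self.effect_size < 0:
            raise ConfigurationError("effect_size must be ≥ 0")
        lo, hi = self.mz_range
        if not 0 < self.peak_density <= 1:
            raise ConfigurationError("peak_density must be in (0, 1]")
        if self.n_discriminating > self.n_signal_bins:
            raise ConfigurationError(
                f"n_discriminating={self.n_discriminating} exceeds the "
                f"{self.n_signal_bins} signal bins of the "
                f"{hi - lo + 1}-bin m/Z range at density {self.peak_density}"
            )
        if not 0 <= self.sex_ratio <= 1 or not 0 <= self.t2dm_frac_g1 <= 1:
            raise ConfigurationError("probabilities must lie in [0, 1]")

    @property
    def n_signal_bins(self) -> int:
        lo, hi = self.mz_range
        return int(round(self.peak_density * (hi - lo + 1)))


@dataclass
class CohortTruth:
    """Planted structure, for parameter-recovery tests."""

    up_in_g1: list[int]     # unit m/Z shifted up in group 1
    up_in_g2: list[int]     # unit m/Z shifted up in group 2
    effect_size: float

    @property
    def planted(self) -> list[int]:
        return sorted(self.up_in_g1 + self.up_in_g2)


# ---------------------------------------------------------------------------
# core generation
# ---------------------------------------------------------------------------

def _draw_cohort(cfg: SyntheticConfig, rng: np.random.Generator):
    """Replicate intensity array (n_samples, n_replicates, n_bins) + truth."""
    lo, hi = cfg.mz_range
    n_bins = hi - lo + 1
    mu = rng.normal(cfg.baseline_mu, cfg.baseline_mu_spread, n_bins)
    # sparse chemical signal: non-signal bins sit near the noise floor
    signal = rng.choice(n_bins, size=cfg.n_signal_bins, replace=False)
    is_signal = np.zeros(n_bins, dtype=bool)
    is_signal[signal] = True
    mu[~is_signal] += math.log(cfg.noise_ratio)
    disc = rng.choice(signal, size=cfg.n_discriminating, replace=False)
    n_up = cfg.n_discriminating - cfg.n_discriminating // 2  # half up, half down
    up, down = disc[:n_up], disc[n_up:]
    shift = np.zeros(n_bins)
    shift[up] = cfg.effect_size * cfg.baseline_sigma
    shift[down] = -cfg.effect_size * cfg.baseline_sigma
    n = cfg.n_g1 + cfg.n_g2
    is_g1 = np.arange(n) < cfg.n_g1
    sigma_rep = math.sqrt(math.log1p(cfg.replicate_cv ** 2))
    out = np.empty((n, cfg.n_replicates, n_bins))
    for i in range(n):
        log_level = rng.normal(mu + (shift if is_g1[i] else 0.0), cfg.baseline_sigma)
        scale = math.exp(rng.normal(0.0, cfg.sample_scale_sigma))
        for r in range(cfg.n_replicates):
            jitter = rng.normal(0.0, sigma_rep, n_bins)
            out[i, r] = np.exp(log_level + jitter) * scale
    truth = CohortTruth(up_in_g1=sorted(int(lo + j) for j in up),
                        up_in_g2=sorted(int(lo + j) for j in down),
                        effect_size=cfg.effect_size)
    return out, truth


def _metadata(cfg: SyntheticConfig, rng: np.random.Generator) -> list[SampleRecord]:
    g1, g2 = cfg.group_labels
    records = []
    for i in range(cfg.n_g1 + cfg.n_g2):
        group = g1 if i < cfg.n_g1 else g2
        sex = "F" if rng.random() < cfg.sex_ratio else "M"
        age = int(rng.integers(cfg.age_range[0], cfg.age_range[1] + 1))
        if group == g1:
            t2dm = "yes" if rng.random() < cfg.t2dm_frac_g1 else "no"
        else:
            t2dm = "no"
        records.append(SampleRecord(
            sample_id=f"{'P' if group == g1 else 'C'}{i + 1:03d}",
            group=group, sex=sex, age=age, t2dm=t2dm,
            replicate_paths=[Path(f"{group}_{i + 1:03d}_r{r}.tsv")
                             for r in range(cfg.n_replicates)],
        ))
    return records


def generate_profiles(cfg: SyntheticConfig,
                      norm_params: NormalizationParams | None = None,
                      peak_mode: str = "bin",
                      ) -> tuple[list[SampleProfile], CohortManifest, CohortTruth]:
    """Generate a cohort in memory and push it through preprocessing.

    Returns replicate-averaged normalized profiles (the same objects the
    file route would produce), the manifest, and the planted truth.
    Deterministic under ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    arr, truth = _draw_cohort(cfg, rng)
    records = _metadata(cfg, rng)
    lo, hi = cfg.mz_range
    norm_params = norm_params or NormalizationParams(mz_range=cfg.mz_range)
    profiles = []
    for i, rec in enumerate(records):
        reps = [NominalSpectrum(lo=lo, hi=hi, intensities=arr[i, r],
                                sample_id=rec.sample_id, replicate_index=r)
                for r in range(cfg.n_replicates)]
        profiles.append(build_profile(reps, norm_params, peak_mode,
                                      sample_id=rec.sample_id, group=rec.group))
    manifest = CohortManifest(entries=records, comparison_labels=cfg.group_labels)
    return profiles, manifest, truth


def generate_cohort(cfg: SyntheticConfig, out_dir) -> Path:
    """Write a cohort to disk: manifest.csv, per-replicate TSV spectra and a
    truth.json sidecar.  Byte-identical across reruns with the same config.

    Raw m/Z points are written with a deterministic sub-unit offset in
    (−0.3, 0.3) so reading them back exercises the rounding rule.
    Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    arr, truth = _draw_cohort(cfg, rng)
    records = _metadata(cfg, rng)
    lo, hi = cfg.mz_range
    bins = np.arange(lo, hi + 1, dtype=float)
    for i, rec in enumerate(records):
        for r, rel_path in enumerate(rec.replicate_paths):
            offsets = rng.uniform(-0.3, 0.3, bins.size)
            spec = RawSpectrum(mz=bins + offsets, intensity=arr[i, r],
                               sample_id=rec.sample_id, replicate_index=r)
            write_spectrum_tsv(spec, out_dir / rel_path)
    manifest = CohortManifest(
        entries=[replace(rec, replicate_paths=[out_dir / p for p in rec.replicate_paths])
                 for rec in records],
        comparison_labels=cfg.group_labels,
    )
    manifest_path = out_dir / "manifest.csv"
    write_manifest(manifest, manifest_path)
    (out_dir / "truth.json").write_text(json.dumps({
        "up_in_g1": truth.up_in_g1,
        "up_in_g2": truth.up_in_g2,
        "effect_size": truth.effect_size,
        "seed": cfg.seed,
    }, indent=2) + "\n")
    return manifest_path


# ---------------------------------------------------------------------------
# presets shaped like the study's comparisons
# ---------------------------------------------------------------------------

#: effect sizes per preset were calibrated once so that the LOOCV score
#: moments land near the corresponding reported group means/SDs (moderate,
#: overlapping score distributions rather than complete separation)
PRESETS: dict[str, dict] = {
    # 25 disease vs 25 control, 64% of disease flagged diabetic
    "cabg_vs_control": dict(n_g1=25, n_g2=25, effect_size=0.8,
                            group_labels=("CABG", "Control")),
    # 20+20 training with 5+5 blinded held out (holdout listed in the truth)
    "training_blinded": dict(n_g1=25, n_g2=25, effect_size=0.95,
                             group_labels=("CABG", "Control")),
    # diabetic vs non-diabetic split within the disease group
    "t2dm_split": dict(n_g1=16, n_g2=9, effect_size=1.5,
                       group_labels=("CABG_T2DM", "CABG"),
                       t2dm_frac_g1=1.0),
}

#: per-group sizes of the blinded holdout in the "training_blinded" preset
BLINDED_HOLDOUT = (5, 5)


def preset_config(name: str, seed: int = 0) -> SyntheticConfig:
    if name not in PRESETS:
        raise ConfigurationError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        )
    return SyntheticConfig(seed=seed, **PRESETS[name])


def generate_paperlike_cohort(name: str, out_dir, seed: int = 0) -> Path:
    """Write a preset cohort to disk; returns the manifest path.

    For "training_blinded" the truth sidecar additionally lists the sample
    ids held out as the blinded set (the last 5 of each group).
    """
    from .cohort_io import read_manifest

    cfg = preset_config(name, seed=seed)
    manifest_path = generate_cohort(cfg, out_dir)
    if name == "training_blinded":
        manifest = read_manifest(manifest_path, comparison_labels=cfg.group_labels)
        g1, g2 = cfg.group_labels
        hold = ([e.sample_id for e in manifest.samples_in(g1)][-BLINDED_HOLDOUT[0]:]
                + [e.sample_id for e in manifest.samples_in(g2)][-BLINDED_HOLDOUT[1]:])
        truth_path = Path(out_dir) / "truth.json"
        truth = json.loads(truth_path.read_text())
        truth["blinded_sample_ids"] = hold
        truth_path.write_text(json.dumps(truth, indent=2) + "\n")
    return manifest_path
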