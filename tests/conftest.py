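"""Shared fixtures: tiny synthetic cohorts and file-format builders."""

from __future__ import annotations

import base64
import struct
from pathlib import Path

import numpy as np
import pytest

from seroprofile import (
    DiscriminationParams,
    NormalizationParams,
    SampleProfile,
    SyntheticConfig,
    generate_profiles,
)


def make_mzml(path: Path, mz, intensity) -> Path:
    """Write a minimal single-scan mzML 1.1 file."""

    def enc(a):
        return base64.b64encode(struct.pack("<%dd" % len(a), *a)).decode()

    xml = f"""<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <run id="r1"><spectrumList count="1">
    <spectrum index="0" id="scan=1" defaultArrayLength="{len(mz)}">
      <binaryDataArrayList count="2">
        <binaryDataArray>
          <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float"/>
          <cvParam cvRef="MS" accession="MS:1000576" name="no compression"/>
          <cvParam cvRef="MS" accession="MS:1000514" name="m/z array"/>
          <binary>{enc(mz)}</binary>
        </binaryDataArray>
        <binaryDataArray>
          <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float"/>
          <cvParam cvRef="MS" accession="MS:1000576" name="no compression"/>
          <cvParam cvRef="MS" accession="MS:1000515" name="intensity array"/>
          <binary>{enc(intensity)}</binary>
        </binaryDataArray>
      </binaryDataArrayList>
    </spectrum>
  </spectrumList></run></mzML>
"""
    path.write_text(xml)
    return path


def make_profile(sample_id: str, group: str, areas, lo: int = 400) -> SampleProfile:
    areas = np.asarray(areas, dtype=float)
    return SampleProfile(sample_id=sample_id, group=group, lo=lo,
                         hi=lo + areas.size - 1, area_by_mz=areas,
                         n_replicates=3)


def separated_profiles(n_per_group: int = 5, n_bins: int = 20,
                       seed: int = 0) -> list[SampleProfile]:
    """Two groups separated cleanly at a handful of bins, noisy elsewhere."""
    rng = np.random.default_rng(seed)
    base = rng.uniform(5, 15, n_bins)
    profiles = []
    for g, label, shift in ((0, "disease", +4.0), (1, "control", 0.0)):
        for i in range(n_per_group):
            areas = base + rng.normal(0, 0.3, n_bins)
            areas[2] += shift      # higher in disease
            areas[7] -= shift      # lower in disease
            areas[13] += shift
            profiles.append(make_profile(f"{label[0]}{i}", label,
                                         np.clip(areas, 0, None)))
    return profiles


@pytest.fixture
def tiny_params() -> DiscriminationParams:
    return DiscriminationParams(analysis_range=(400, 419))


@pytest.fixture
def small_cohort():
    """In-memory synthetic cohort with a clear group effect (n=8+8)."""
    cfg = SyntheticConfig(n_g1=8, n_g2=8, mz_range=(400, 699),
                          n_discriminating=40, effect_size=2.5, seed=42)
    profiles, manifest, truth = generate_profiles(cfg)
    return profiles, manifest, truth


@pytest.fixture
def small_params() -> DiscriminationParams:
    return DiscriminationParams(analysis_range=(400, 699))


@pytest.fixture
def norm_params_small() -> NormalizationParams:
    return NormalizationParams(mz_range=(400, 699))
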