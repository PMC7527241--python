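"""Spectral preprocessing: local normalization, peak areas, replicate averaging.

Direct-infusion serum spectra carry large sample-to-sample differences in
total ion current.  These are removed by *local* normalization: intensities
are rescaled so that every non-overlapping 10-m/Z segment sums to 100, which
makes downstream peak comparisons invariant to any global per-sample scale.
Peak areas are then derived per replicate — either valley-to-valley centroid
areas or, for pre-binned unit-mass data, one-bin-per-peak — and averaged
across the (typically triplicate) replicates into one profile per sample.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .cohort_io import (
    CohortManifest,
    NominalSpectrum,
    nominalize,
    read_spectrum,
)
from .errors import ConfigurationError

logger = logging.getLogger("seroprofile")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class NormalizationParams:
    """Local-normalization settings.

    segment_width : width of the non-overlapping m/Z segments (default 10)
    segment_target: each non-empty segment is scaled to this intensity sum
                    (default 100)
    mz_range      : unit-m/Z acquisition range, inclusive (default 400–2000)
    """

    segment_width: int = 10
    segment_target: float = 100.0
    mz_range: tuple[int, int] = (400, 2000)

    def __post_init__(self) -> None:
        if self.segment_width <= 0:
            raise ConfigurationError("segment_width must be positive")
        if self.segment_target <= 0:
            raise ConfigurationError("segment_target must be positive")
        lo, hi = self.mz_range
        if lo >= hi:
            raise ConfigurationError(f"invalid mz_range [{lo}, {hi}]")


@dataclass
class PeakTable:
    """Valley-to-valley peaks of one replicate spectrum."""

    mz_centroid: np.ndarray   # unit m/Z of each peak's intensity-weighted centre
    area: np.ndarray          # summed intensity between the flanking valleys
    left_valley: np.ndarray   # unit m/Z of each peak's first bin
    right_valley: np.ndarray  # unit m/Z of each peak's last bin
    sample_id: str = ""
    replicate_index: int = 0

    @property
    def n_peaks(self) -> int:
        return int(self.area.size)


@dataclass
class SampleProfile:
    """Replicate-averaged normalized peak areas for one serum sample."""

    sample_id: str
    group: str
    lo: int
    hi: int
    area_by_mz: np.ndarray    # mean area per unit m/Z; absent m/Z = 0
    n_replicates: int = 1

    def __post_init__(self) -> None:
        self.area_by_mz = np.asarray(self.area_by_mz, dtype=float)
        if self.area_by_mz.shape != (self.hi - self.lo + 1,):
            raise ConfigurationError("area vector length does not match m/Z range")

    @property
    def mz(self) -> np.ndarray:
        return np.arange(self.lo, self.hi + 1)

    def restricted(self, lo: int, hi: int) -> np.ndarray:
        """Area vector over [lo, hi]; out-of-profile bins are 0."""
        out = np.zeros(hi - lo + 1)
        a = max(lo, self.lo)
        b = min(hi, self.hi)
        if a <= b:
            out[a - lo:b - lo + 1] = self.area_by_mz[a - self.lo:b - self.lo + 1]
        return out


# ---------------------------------------------------------------------------
# local normalization
# ---------------------------------------------------------------------------

def normalize_local(spec: NominalSpectrum,
                    params: NormalizationParams | None = None) -> NominalSpectrum:
    """Scale each non-overlapping segment to sum to ``segment_target``.

    Segments are [lo + k·w, lo + (k+1)·w) anchored at the range lower bound;
    a partial final segment is scaled like any other.  All-zero segments stay
    zero (they cannot be scaled) and are counted in the log.  The output is
    exactly invariant to any positive global scaling of the input.
    """
    params = params or NormalizationParams()
    lo, hi = params.mz_range
    if spec.lo < lo or spec.hi > hi:
        logger.warning(
            "spectrum %s[%d] range [%d, %d] clipped to [%d, %d]",
            spec.sample_id, spec.replicate_index, spec.lo, spec.hi, lo, hi,
        )
    a = max(spec.lo, lo)
    b = min(spec.hi, hi)
    if a > b:
        raise ConfigurationError("spectrum does not overlap the normalization range")
    v = spec.intensities[a - spec.lo:b - spec.lo + 1]
    seg = (np.arange(a, b + 1) - lo) // params.segment_width
    sums = np.bincount(seg, weights=v)
    n_empty = int(np.count_nonzero(sums == 0))
    if n_empty:
        logger.debug("%d all-zero segment(s) left at zero", n_empty)
    scale = np.where(sums > 0, params.segment_target / np.where(sums > 0, sums, 1.0), 0.0)
    return NominalSpectrum(lo=a, hi=b, intensities=v * scale[seg],
                           sample_id=spec.sample_id,
                           replicate_index=spec.replicate_index)


# ---------------------------------------------------------------------------
# peak detection
# ---------------------------------------------------------------------------

def _valley_indices(v: np.ndarray) -> np.ndarray:
    """Interior bins that are ≤ both neighbours; plateau runs collapse to
    their leftmost bin (ties broken leftward)."""
    n = v.size
    if n < 3:
        return np.array([], dtype=int)
    is_valley = (v[1:-1] <= v[:-2]) & (v[1:-1] <= v[2:])
    idx = np.flatnonzero(is_valley) + 1
    if idx.size == 0:
        return idx
    keep = np.ones(idx.size, dtype=bool)
    keep[1:] = np.diff(idx) > 1
    return idx[keep]


def centroid_peaks(spec: NominalSpectrum, mode: str = "centroid") -> PeakTable:
    """Segment a spectrum into peaks and compute their areas.

    mode "centroid": peaks are maximal runs between consecutive valleys
    (a valley = a bin ≤ both neighbours); a shared valley bin belongs to the
    peak on its left.  Area is the sum of the bin intensities in the run;
    the centroid is the intensity-weighted mean m/Z rounded to unit.
    Zero-area runs are dropped, so the retained areas sum exactly to the
    spectrum's total intensity.

    mode "bin": every unit bin with positive intensity is its own peak —
    the practical default upstream of unit-m/Z discrimination.
    """
    v = spec.intensities
    mzs = spec.mz
    if mode == "bin":
        nz = np.flatnonzero(v > 0)
        return PeakTable(mz_centroid=mzs[nz].astype(float), area=v[nz],
                         left_valley=mzs[nz].astype(float),
                         right_valley=mzs[nz].astype(float),
                         sample_id=spec.sample_id,
                         replicate_index=spec.replicate_index)
    if mode != "centroid":
        raise ConfigurationError(f"unknown peak mode {mode!r}")
    valleys = _valley_indices(v)
    # segment boundaries: each segment ends at a valley (valley bin included
    # on the left), the final segment ends at the last bin
    starts = np.concatenate(([0], valleys + 1))
    ends = np.concatenate((valleys, [v.size - 1]))
    cent, area, lft, rgt = [], [], [], []
    for s, e in zip(starts, ends):
        if s > e:
            continue
        a = float(v[s:e + 1].sum())
        if a <= 0:
            continue
        c = float(np.dot(v[s:e + 1], mzs[s:e + 1]) / a)
        cent.append(float(np.floor(c + 0.5)))  # half away from zero (m/Z > 0)
        area.append(a)
        lft.append(float(mzs[s]))
        rgt.append(float(mzs[e]))
    return PeakTable(mz_centroid=np.array(cent), area=np.array(area),
                     left_valley=np.array(lft), right_valley=np.array(rgt),
                     sample_id=spec.sample_id,
                     replicate_index=spec.replicate_index)


def peak_area_vector(table: PeakTable, lo: int, hi: int) -> np.ndarray:
    """Scatter peak areas onto the unit-m/Z grid (areas at a shared centroid
    bin are summed; centroids outside [lo, hi] are dropped)."""
    out = np.zeros(hi - lo + 1)
    bins = table.mz_centroid.astype(int)
    ok = (bins >= lo) & (bins <= hi)
    np.add.at(out, bins[ok] - lo, table.area[ok])
    return out


# ---------------------------------------------------------------------------
# replicate averaging and the per-sample pipeline
# ---------------------------------------------------------------------------

def average_replicates(vectors: list[np.ndarray], lo: int, hi: int,
                       sample_id: str = "", group: str = "") -> SampleProfile:
    """Arithmetic mean of per-replicate area vectors (all on [lo, hi])."""
    if not vectors:
        raise ConfigurationError("no replicates to average")
    n = hi - lo + 1
    for v in vectors:
        if np.asarray(v).shape != (n,):
            raise ConfigurationError(
                "replicate area vectors cover different m/Z ranges"
            )
    mean = np.mean(np.vstack(vectors), axis=0)
    return SampleProfile(sample_id=sample_id, group=group, lo=lo, hi=hi,
                         area_by_mz=mean, n_replicates=len(vectors))


def build_profile(replicates: list[NominalSpectrum],
                  params: NormalizationParams | None = None,
                  peak_mode: str = "bin",
                  sample_id: str = "", group: str = "") -> SampleProfile:
    """Normalize → peak areas → average, for one sample's replicates."""
    params = params or NormalizationParams()
    vectors = []
    lo = hi = None
    for spec in replicates:
        norm = normalize_local(spec, params)
        if lo is None:
            lo, hi = norm.lo, norm.hi
        elif (norm.lo, norm.hi) != (lo, hi):
            raise ConfigurationError(
                f"replicate ranges differ: [{lo}, {hi}] vs [{norm.lo}, {norm.hi}]"
            )
        table = centroid_peaks(norm, mode=peak_mode)
        vectors.append(peak_area_vector(table, lo, hi))
    return average_replicates(vectors, lo, hi, sample_id=sample_id, group=group)


def profiles_from_manifest(manifest: CohortManifest,
                           params: NormalizationParams | None = None,
                           peak_mode: str = "bin") -> list[SampleProfile]:
    """Read every sample's replicates from disk and build its profile."""
    params = params or NormalizationParams()
    lo, hi = params.mz_range
    profiles = []
    for rec in manifest.entries:
        reps = [
            nominalize(read_spectrum(p, sample_id=rec.sample_id, replicate_index=r),
                       lo=lo, hi=hi)
            for r, p in enumerate(rec.replicate_paths)
        ]
        profiles.append(build_profile(reps, params, peak_mode,
                                      sample_id=rec.sample_id, group=rec.group))
    return profiles


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_profile_tsv(profile: SampleProfile, path) -> None:
    path = Path(path)
    lines = ["mz\tmean_area\tn_replicates"]
    lines += [
        f"{m}\t{float(a)!r}\t{profile.n_replicates}"
        for m, a in zip(profile.mz, profile.area_by_mz)
    ]
    path.write_text("\n".join(lines) + "\n")


def read_profile_tsv(path, sample_id: str = "", group: str = "") -> SampleProfile:
    path = Path(path)
    mzs, areas, nrep = [], [], 1
    for line in path.read_text().splitlines()[1:]:
        m, a, n = line.split("\t")
        mzs.append(int(m))
        areas.append(float(a))
        nrep = int(n)
    return SampleProfile(sample_id=sample_id, group=group,
                         lo=mzs[0], hi=mzs[-1], area_by_mz=np.array(areas),
                         n_replicates=nrep)


def write_norm_sidecar(params: NormalizationParams, peak_mode: str, path) -> None:
    Path(path).write_text(json.dumps({
        "segment_width": params.segment_width,
        "segment_target": params.segment_target,
        "mz_range": list(params.mz_range),
        "peak_mode": peak_mode,
    }, indent=2) + "\n")
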