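"""Cohort manifests and raw-spectrum I/O.

A cohort is described by a CSV manifest (one row per serum sample, with a
binary group label, basic demographics and paths to replicate spectra).
Replicate spectra are read either from mzML or from a plain two-column
m/Z–intensity TSV, and converted to *nominal* (unit-m/Z) spectra: intensity
aggregated per whole-number m/Z bin over a fixed range, the form in which
direct-infusion serum profiles are compared downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, SchemaError, ValidationError

logger = logging.getLogger("seroprofile")

UNKNOWN = "unknown"

MANIFEST_COLUMNS = ["sample_id", "group", "sex", "age", "t2dm", "replicate_paths"]

#: default acquisition range, unit m/Z
DEFAULT_MZ_RANGE = (400, 2000)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SampleRecord:
    """One serum sample: identity, grouping, demographics, replicate files.

    Metadata may be ``"unknown"`` but is never imputed or dropped.
    """

    sample_id: str
    group: str
    sex: str = UNKNOWN          # "F", "M" or "unknown"
    age: int | str = UNKNOWN    # years, or "unknown"
    t2dm: str = UNKNOWN         # "yes", "no" or "unknown"
    replicate_paths: list[Path] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sex = _norm_sex(self.sex)
        self.age = _norm_age(self.age)
        self.t2dm = _norm_t2dm(self.t2dm)

    @property
    def n_replicates(self) -> int:
        return len(self.replicate_paths)


@dataclass
class CohortManifest:
    """A validated two-group cohort.

    ``comparison_labels`` is the ordered pair of group names; by convention
    the first label is the positive/disease group.
    """

    entries: list[SampleRecord]
    comparison_labels: tuple[str, str]

    def __post_init__(self) -> None:
        ids = [e.sample_id for e in self.entries]
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise ValidationError(f"duplicate sample id(s): {', '.join(dupes)}")
        g1, g2 = self.comparison_labels
        for e in self.entries:
            if e.group not in (g1, g2):
                raise ValidationError(
                    f"sample {e.sample_id!r}: group {e.group!r} not in "
                    f"declared pair ({g1!r}, {g2!r})"
                )
            if not e.replicate_paths:
                raise ValidationError(f"sample {e.sample_id!r} has no replicate paths")

    def samples_in(self, group: str) -> list[SampleRecord]:
        return [e for e in self.entries if e.group == group]

    def group_sizes(self) -> tuple[int, int]:
        g1, g2 = self.comparison_labels
        return len(self.samples_in(g1)), len(self.samples_in(g2))


@dataclass
class RawSpectrum:
    """A single replicate acquisition: sorted (m/Z, intensity) points."""

    mz: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""
    replicate_index: int = 0

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise DataError("m/Z and intensity arrays differ in length")
        if np.any(self.intensity < 0):
            raise DataError("negative intensity in spectrum")
        if self.mz.size and np.any(np.diff(self.mz) < 0):
            # tolerated on input, normalised here with a warning
            logger.warning(
                "spectrum %s[%d]: m/Z not sorted; sorting",
                self.sample_id, self.replicate_index,
            )
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]

    @property
    def n_points(self) -> int:
        return int(self.mz.size)


@dataclass
class NominalSpectrum:
    """Unit-m/Z intensity vector for one replicate over [lo, hi] inclusive."""

    lo: int
    hi: int
    intensities: np.ndarray
    sample_id: str = ""
    replicate_index: int = 0

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (self.hi - self.lo + 1,):
            raise DataError(
                f"nominal spectrum length {self.intensities.size} != "
                f"{self.hi - self.lo + 1} for range [{self.lo}, {self.hi}]"
            )
        if np.any(self.intensities < 0):
            raise DataError("negative intensity in nominal spectrum")

    @property
    def mz(self) -> np.ndarray:
        """Unit m/Z values of the bins."""
        return np.arange(self.lo, self.hi + 1)


# ---------------------------------------------------------------------------
# manifest I/O
# ---------------------------------------------------------------------------

def _norm_sex(v) -> str:
    s = str(v).strip().upper()
    if s in {"F", "M"}:
        return s
    return UNKNOWN


def _norm_age(v):
    s = str(v).strip()
    if not s or s.lower() in {"unknown", "na", "nan"}:
        return UNKNOWN
    try:
        age = int(float(s))
    except ValueError:
        return UNKNOWN
    return age if age >= 0 else UNKNOWN


def _norm_t2dm(v) -> str:
    s = str(v).strip().lower()
    if s in {"yes", "y", "1", "true"}:
        return "yes"
    if s in {"no", "n", "0", "false"}:
        return "no"
    return UNKNOWN


def read_manifest(path, comparison_labels: tuple[str, str] | None = None) -> CohortManifest:
    """Read and validate a cohort manifest CSV.

    Columns: sample_id, group, sex, age, t2dm, replicate_paths (semicolon
    separated, resolved relative to the manifest's directory).  If
    ``comparison_labels`` is not given, the two labels are taken in order of
    first appearance (first seen = positive group by convention).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"manifest missing required column(s): {', '.join(missing)}")
    base = path.parent
    entries = []
    for row in df.itertuples(index=False):
        reps = [base / p.strip() for p in str(row.replicate_paths).split(";") if p.strip()]
        entries.append(
            SampleRecord(
                sample_id=str(row.sample_id).strip(),
                group=str(row.group).strip(),
                sex=row.sex, age=row.age, t2dm=row.t2dm,
                replicate_paths=reps,
            )
        )
    if comparison_labels is None:
        seen: list[str] = []
        for e in entries:
            if e.group not in seen:
                seen.append(e.group)
        if len(seen) != 2:
            raise ValidationError(
                f"manifest must contain exactly 2 group labels, found {len(seen)}: {seen}"
            )
        comparison_labels = (seen[0], seen[1])
    return CohortManifest(entries=entries, comparison_labels=comparison_labels)


def write_manifest(manifest: CohortManifest, path) -> None:
    """Write a manifest CSV; replicate paths are stored relative to it."""
    path = Path(path)
    base = path.parent
    rows = []
    for e in manifest.entries:
        reps = []
        for p in e.replicate_paths:
            try:
                reps.append(str(Path(p).relative_to(base)))
            except ValueError:
                reps.append(str(p))
        rows.append(
            dict(sample_id=e.sample_id, group=e.group, sex=e.sex,
                 age=e.age, t2dm=e.t2dm, replicate_paths=";".join(reps))
        )
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# spectrum I/O
# ---------------------------------------------------------------------------

def read_spectrum(path, dialect: str | None = None,
                  sample_id: str = "", replicate_index: int = 0) -> RawSpectrum:
    """Read one replicate spectrum from TSV or mzML.

    ``dialect`` is ``"tsv"`` or ``"mzml"``; inferred from the file suffix if
    omitted.  Zero-intensity points are retained; negative intensities are a
    data error; an unsorted TSV is sorted with a logged warning.
    """
    path = Path(path)
    if dialect is None:
        dialect = "mzml" if path.suffix.lower() == ".mzml" else "tsv"
    if dialect == "tsv":
        return _read_tsv(path, sample_id, replicate_index)
    if dialect == "mzml":
        return _read_mzml(path, sample_id, replicate_index)
    raise ValueError(f"unknown spectrum dialect {dialect!r}")


def _read_tsv(path: Path, sample_id: str, replicate_index: int) -> RawSpectrum:
    mzs, ints = [], []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise DataError(f"{path}:{lineno}: expected 2 tab-separated columns")
        try:
            mz, inten = float(parts[0]), float(parts[1])
        except ValueError as exc:
            raise DataError(f"{path}:{lineno}: non-numeric value") from exc
        if inten < 0:
            raise DataError(f"{path}:{lineno}: negative intensity {inten}")
        mzs.append(mz)
        ints.append(inten)
    return RawSpectrum(np.array(mzs), np.array(ints),
                       sample_id=sample_id, replicate_index=replicate_index)


def _decode_binary_array(node) -> np.ndarray:
    """Decode one mzML <binaryDataArray> (64/32-bit float, plain or zlib)."""
    import base64
    import zlib

    accessions = {c.get("accession") for c in node.iter()
                  if c.tag.endswith("cvParam")}
    dtype = "<f4" if "MS:1000521" in accessions else "<f8"
    binary = next(c for c in node.iter() if c.tag.endswith("}binary"))
    raw = base64.b64decode(binary.text or "")
    if "MS:1000574" in accessions:  # zlib compression
        raw = zlib.decompress(raw)
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _read_mzml(path: Path, sample_id: str, replicate_index: int) -> RawSpectrum:
    """Minimal mzML 1.1 reader: m/z and intensity arrays of the first scan.

    Handles 32/64-bit float arrays, plain or zlib-compressed — the profile
    and centroid exports this pipeline consumes.  Direct infusion: scan
    averaging is assumed done upstream, so extra scans only log a warning.
    """
    from lxml import etree

    tree = etree.parse(str(path))
    spectra = tree.findall(".//{*}spectrumList/{*}spectrum")
    if not spectra:
        raise DataError(f"{path}: mzML file contains no spectra")
    if len(spectra) > 1:
        logger.warning("%s: %d scans present; using the first", path, len(spectra))
    mz_arr = inten_arr = None
    for bda in spectra[0].findall(".//{*}binaryDataArray"):
        accessions = {c.get("accession") for c in bda.iter()
                      if c.tag.endswith("cvParam")}
        if "MS:1000514" in accessions:    # m/z array
            mz_arr = _decode_binary_array(bda)
        elif "MS:1000515" in accessions:  # intensity array
            inten_arr = _decode_binary_array(bda)
    if mz_arr is None or inten_arr is None:
        raise DataError(f"{path}: spectrum lacks m/z or intensity array")
    return RawSpectrum(mz_arr, inten_arr,
                       sample_id=sample_id, replicate_index=replicate_index)


def write_spectrum_tsv(spec: RawSpectrum, path) -> None:
    """Write the TSV dialect.  ``repr`` formatting round-trips exactly."""
    path = Path(path)
    lines = [f"# sample={spec.sample_id} replicate={spec.replicate_index}"]
    lines += [f"{float(m)!r}\t{float(i)!r}" for m, i in zip(spec.mz, spec.intensity)]
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# nominalization
# ---------------------------------------------------------------------------

def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round half away from zero (not banker's rounding)."""
    return np.where(x >= 0, np.floor(x + 0.5), np.ceil(x - 0.5))


def nominalize(raw: RawSpectrum, lo: int = DEFAULT_MZ_RANGE[0],
               hi: int = DEFAULT_MZ_RANGE[1]) -> NominalSpectrum:
    """Aggregate a raw spectrum into whole-unit m/Z bins over [lo, hi].

    Each point is assigned to ``round(m/Z)`` (half away from zero);
    intensities within a bin are summed; points rounding outside the range
    are discarded and counted in the log.  Total in-range intensity is
    conserved exactly.
    """
    if lo >= hi:
        raise ValueError(f"lo must be < hi, got [{lo}, {hi}]")
    bins = _round_half_away(raw.mz).astype(int)
    in_range = (bins >= lo) & (bins <= hi)
    n_discarded = int(np.count_nonzero(~in_range))
    if n_discarded:
        logger.info(
            "nominalize %s[%d]: discarded %d point(s) outside [%d, %d]",
            raw.sample_id, raw.replicate_index, n_discarded, lo, hi,
        )
    intensities = np.zeros(hi - lo + 1)
    np.add.at(intensities, bins[in_range] - lo, raw.intensity[in_range])
    return NominalSpectrum(lo=lo, hi=hi, intensities=intensities,
                           sample_id=raw.sample_id,
                           replicate_index=raw.replicate_index)
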