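"""Readers and writers for the pipeline's tabular formats.

All working data are plain text: profile spectra and peak lists as
two-column (m/z, intensity) tables with a header line, sample manifests as
TSV, and the bundled shared-ion reference table as package data.  Bruker raw
formats, imzML rasters and mzML acquisitions are out of scope; the analysis
operates on peak intensities, not raw acquisitions.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

GROUPS = ("A8", "CS4", "CS8", "CS8+R")
MODALITIES = ("extract", "IMS")

#: Five-level relative-abundance concordance codes and their printed glyphs.
CATEGORIES = ("EQ", "IMS_GT", "IMS_LT", "IMS_GGT", "IMS_LLT")
CATEGORY_GLYPHS = {
    "EQ": "=",
    "IMS_GT": ">",
    "IMS_LT": "<",
    "IMS_GGT": "≫",  # >>
    "IMS_LLT": "≪",  # <<
}

MANIFEST_COLUMNS = ("sample_id", "group", "replicate", "modality", "path")


class FixtureIntegrityError(RuntimeError):
    """Raised when the bundled shared-ion table fails its integrity checks."""


@dataclass
class ProfileSpectrum:
    """Continuous (m/z grid, intensity) trace for one sample and modality."""

    mz: np.ndarray
    intensity: np.ndarray
    sample_id: str | None = None
    modality: str | None = None

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if self.mz.size >= 2 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("m/z grid must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")

    def __len__(self) -> int:
        return self.mz.size


@dataclass
class PeakList:
    """Centroided (m/z, intensity) pairs for one sample and modality.

    The pipeline's working currency.  ``normalized`` marks lists whose
    intensities have been divided by the total ion count and therefore sum
    to one.
    """

    mz: np.ndarray
    intensity: np.ndarray
    sample_id: str | None = None
    modality: str | None = None
    normalized: bool = False

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if self.mz.size >= 2 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("peak m/z values must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        if self.normalized and self.mz.size and abs(self.intensity.sum() - 1.0) > 1e-9:
            raise ValueError("normalized peak list must sum to 1 within 1e-9")

    def __len__(self) -> int:
        return self.mz.size

    def copy(self) -> "PeakList":
        return replace(self, mz=self.mz.copy(), intensity=self.intensity.copy())


@dataclass
class Table1Record:
    """One shared ion of the bundled extract-vs-IMS reference table.

    ``mz_text`` carries the higher-precision m/z variant quoted in running
    text where it differs from the printed table (the two are recorded
    side by side, without adjudication).  ``isotope_flag`` marks ions
    attributed to the C13 isotopologue of the adjacent 1 Da-lower ion;
    those carry no lipid assignment.
    """

    mz: float
    lipid_id: str | None
    isotope_flag: bool
    category: str
    mz_text: float | None = None

    @property
    def glyph(self) -> str:
        return CATEGORY_GLYPHS[self.category]


@dataclass
class SampleManifest:
    """Validated table of study samples (id, group, replicate, modality, path)."""

    frame: pd.DataFrame

    def __post_init__(self):
        df = self.frame
        missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"manifest missing required columns: {missing}")
        bad_group = df.loc[~df["group"].isin(GROUPS)]
        if len(bad_group):
            raise ValueError(
                "manifest rows with unknown group label: "
                + ", ".join(f"row {i} ({g!r})" for i, g in bad_group["group"].items())
            )
        bad_mod = df.loc[~df["modality"].isin(MODALITIES)]
        if len(bad_mod):
            raise ValueError(
                "manifest rows with unknown modality label: "
                + ", ".join(f"row {i} ({m!r})" for i, m in bad_mod["modality"].items())
            )
        dup = df["sample_id"][df["sample_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate sample_id values: {sorted(set(dup))}")

    def __len__(self) -> int:
        return len(self.frame)

    def rows(self):
        return self.frame.itertuples(index=False)


_NUM_RE = re.compile(r"[\s,;\t]+")


def _parse_two_columns(path: Path) -> tuple[np.ndarray, np.ndarray]:
    mzs, intens = [], []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = _NUM_RE.split(line)
            if lineno == 1:
                try:
                    float(fields[0])
                except ValueError:
                    continue  # header line
            if len(fields) < 2:
                raise ValueError(f"{path}: line {lineno}: expected two columns, got {line!r}")
            try:
                mzs.append(float(fields[0]))
                intens.append(float(fields[1]))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-numeric value in {line!r}") from exc
    return np.asarray(mzs), np.asarray(intens)


def _sorted_or_warn(mz: np.ndarray, intensity: np.ndarray, path) -> tuple[np.ndarray, np.ndarray]:
    if mz.size >= 2 and not np.all(np.diff(mz) > 0):
        warnings.warn(f"{path}: m/z values not sorted; sorting on read", stacklevel=3)
        order = np.argsort(mz, kind="stable")
        mz, intensity = mz[order], intensity[order]
    return mz, intensity


def read_peaklist(path, sample_id: str | None = None, modality: str | None = None,
                  normalized: bool = False) -> PeakList:
    """Read a two-column (m/z, intensity) peak list; sorts by m/z on read."""
    path = Path(path)
    mz, intensity = _parse_two_columns(path)
    mz, intensity = _sorted_or_warn(mz, intensity, path)
    return PeakList(mz, intensity, sample_id=sample_id, modality=modality,
                    normalized=normalized)


def write_peaklist(peaks: PeakList, path) -> None:
    """Write a peak list as tab-separated text, m/z and intensity to 10 s.f."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("mz\tintensity\n")
        for m, i in zip(peaks.mz, peaks.intensity):
            fh.write(f"{m:.10g}\t{i:.10g}\n")


def read_profile(path, sample_id: str | None = None, modality: str | None = None) -> ProfileSpectrum:
    """Read a profile spectrum stored as a two-column (m/z, intensity) table."""
    path = Path(path)
    mz, intensity = _parse_two_columns(path)
    mz, intensity = _sorted_or_warn(mz, intensity, path)
    return ProfileSpectrum(mz, intensity, sample_id=sample_id, modality=modality)


def write_profile(spectrum: ProfileSpectrum, path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("mz\tintensity\n")
        for m, i in zip(spectrum.mz, spectrum.intensity):
            fh.write(f"{m:.10g}\t{i:.10g}\n")


def read_manifest(path, check_paths: bool = True) -> SampleManifest:
    """Read and validate a sample manifest (TSV).

    With ``check_paths`` the referenced data files must exist, relative
    paths being resolved against the manifest's directory.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str,
                                            "modality": str, "path": str})
    manifest = SampleManifest(df)
    if check_paths:
        base = path.parent
        for row in manifest.rows():
            p = Path(row.path)
            if not p.is_absolute():
                p = base / p
            if not p.exists():
                raise FileNotFoundError(f"manifest references missing file: {p}")
    return manifest


def write_manifest(manifest: SampleManifest, path) -> None:
    manifest.frame.to_csv(path, sep="\t", index=False)


def load_table1_fixture() -> list[Table1Record]:
    """Load the bundled 25-ion extract-vs-IMS shared-ion reference table."""
    ref = resources.files("lipidims.data").joinpath("table1.tsv")
    with resources.as_file(ref) as p:
        df = pd.read_csv(p, sep="\t")
    records = []
    for row in df.itertuples(index=False):
        category = str(row.category)
        if category not in CATEGORIES:
            raise FixtureIntegrityError(f"unknown category {category!r} at m/z {row.mz}")
        lipid = None if pd.isna(row.lipid_id) else str(row.lipid_id)
        alias = None if pd.isna(row.mz_text) else float(row.mz_text)
        records.append(Table1Record(mz=float(row.mz), lipid_id=lipid,
                                    isotope_flag=bool(row.isotope_flag),
                                    category=category, mz_text=alias))
    if len(records) != 25:
        raise FixtureIntegrityError(f"expected 25 shared-ion records, found {len(records)}")
    flagged = sorted(r.mz for r in records if r.isotope_flag)
    if flagged != [714.6, 884.7, 889.7, 905.4, 913.7]:
        raise FixtureIntegrityError(f"unexpected C13-flagged rows: {flagged}")
    if any(r.isotope_flag and r.lipid_id is not None for r in records):
        raise FixtureIntegrityError("C13-flagged rows must carry no lipid assignment")
    return records
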