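"""Cross-modality comparison of extract and IMS consensus peak lists.

Pairs ions across the two acquisition modes within an m/z tolerance, flags
C13 isotope satellites (+1.00335 Da, lower intensity than the monoisotopic
partner), classifies each shared ion into the five-level relative-abundance
scale (=, <, <<, >, >>: IMS intensity within 10% of the extract, 10-49%
lower/higher, or at least 50% lower/higher), and tallies the detection
overlap between modalities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import CATEGORIES, CATEGORY_GLYPHS, Table1Record
from .synthetic import ISOTOPE_DELTA


@dataclass
class MatchResult:
    """One-to-one pairing of an extract and an IMS peak list within tolerance.

    ``pairs`` holds (extract index, IMS index, delta m/z) triples into the
    two input lists; ``extract_only`` / ``ims_only`` the unmatched indices.
    """

    pairs: list[tuple[int, int, float]]
    extract_only: np.ndarray
    ims_only: np.ndarray
    tolerance: float
    extract: object = None   # the input lists, kept for downstream lookups
    ims: object = None

    @property
    def n_shared(self) -> int:
        return len(self.pairs)

    def pair_mz(self) -> np.ndarray:
        """Consensus m/z per pair (mean of the two partners)."""
        return np.asarray([(self.extract.mz[i] + self.ims.mz[j]) / 2.0
                           for i, j, _ in self.pairs])

    def validate(self) -> None:
        ei = [p[0] for p in self.pairs]
        ii = [p[1] for p in self.pairs]
        assert len(set(ei)) == len(ei) and len(set(ii)) == len(ii), "pairing not one-to-one"
        assert all(abs(d) <= self.tolerance + 1e-12 for _, _, d in self.pairs)
        assert len(self.extract.mz) == len(self.pairs) + len(self.extract_only)
        assert len(self.ims.mz) == len(self.pairs) + len(self.ims_only)


@dataclass
class ConcordanceRecord:
    """Per shared ion: m/z, assignment, isotope flag, signed %-difference, category."""

    mz: float
    lipid_id: str | None
    isotope_flag: bool
    pct_diff: float
    category: str

    @property
    def glyph(self) -> str:
        return CATEGORY_GLYPHS[self.category]


@dataclass
class DetectionSummary:
    """Detection overlap between the two modalities plus concordance tallies."""

    n_extract: int
    n_ims: int
    shared: int
    extract_only: int
    ims_only: int
    total: int
    tallies: dict[str, int]

    def as_dict(self) -> dict:
        return {
            "total": self.total, "extract": self.n_extract, "ims": self.n_ims,
            "shared": self.shared, "extract_only": self.extract_only,
            "ims_only": self.ims_only, "tallies": dict(self.tallies),
        }


def _check_normalization(a, b) -> None:
    na, nb = getattr(a, "normalized", None), getattr(b, "normalized", None)
    if na is not None and nb is not None and na != nb:
        raise ValueError("cannot match a normalized list against an unnormalized one")


def match_peaklists(extract, ims, tolerance: float = 0.25) -> MatchResult:
    """Greedy one-to-one matching of two sorted peak lists.

    Candidate pairs within ``tolerance`` are accepted in order of ascending
    |delta m/z|, ties broken toward the lower-m/z extract peak (then the
    lower-m/z IMS peak), each peak used at most once.  The result is
    therefore independent of input ordering.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    _check_normalization(extract, ims)
    emz = np.asarray(extract.mz, dtype=float)
    imz = np.asarray(ims.mz, dtype=float)

    candidates = []
    j0 = 0
    for i, m in enumerate(emz):
        j0 = np.searchsorted(imz, m - tolerance)
        for j in range(j0, len(imz)):
            d = imz[j] - m
            if d > tolerance:
                break
            candidates.append((abs(d), m, imz[j], i, j, d))
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))

    used_e, used_i = set(), set()
    pairs = []
    for _, _, _, i, j, d in candidates:
        if i in used_e or j in used_i:
            continue
        used_e.add(i)
        used_i.add(j)
        pairs.append((i, j, float(d)))
    pairs.sort(key=lambda p: p[0])
    extract_only = np.asarray([i for i in range(len(emz)) if i not in used_e], dtype=int)
    ims_only = np.asarray([j for j in range(len(imz)) if j not in used_i], dtype=int)
    result = MatchResult(pairs=pairs, extract_only=extract_only, ims_only=ims_only,
                         tolerance=tolerance, extract=extract, ims=ims)
    result.validate()
    return result


def flag_isotopes(peaks, delta: float = ISOTOPE_DELTA, tol: float = 0.1,
                  max_ratio: float = 1.0) -> np.ndarray:
    """Flag peaks that look like C13 satellites of a 1 Da-lower partner.

    Peak p is flagged iff some peak q satisfies
    ``m/z(p) - m/z(q) in [delta - tol, delta + tol]`` and
    ``intensity(p) / intensity(q) <= max_ratio``: a first C13 isotopologue
    cannot exceed its monoisotopic peak for lipids in this mass range.
    """
    mz = np.asarray(peaks.mz, dtype=float)
    inten = np.asarray(peaks.intensity, dtype=float)
    flags = np.zeros(mz.size, dtype=bool)
    for p in range(mz.size):
        lo = np.searchsorted(mz, mz[p] - delta - tol)
        hi = np.searchsorted(mz, mz[p] - delta + tol, side="right")
        for q in range(lo, hi):
            if q == p:
                continue
            if inten[q] > 0 and inten[p] / inten[q] <= max_ratio:
                flags[p] = True
                break
    return flags


def classify_concordance(ims_intensity: float, extract_intensity: float
                         ) -> tuple[float, str]:
    """Signed percent difference of IMS vs extract and its five-level category.

    ``pct = 100 * (ims - extract) / extract``; |pct| < 10 -> EQ,
    10 <= |pct| < 50 -> IMS_GT/IMS_LT by sign, |pct| >= 50 -> IMS_GGT/IMS_LLT.
    Boundaries land in the larger-difference class.
    """
    if extract_intensity <= 0:
        raise ValueError("extract intensity must be positive (ion would be IMS-only)")
    if ims_intensity <= 0:
        raise ValueError("IMS intensity must be positive (ion would be extract-only)")
    pct = 100.0 * (ims_intensity - extract_intensity) / extract_intensity
    a = abs(pct)
    tiny = 1e-9  # float fuzz on boundary ratios; boundaries go to the larger class
    if a < 10.0 - tiny:
        cat = "EQ"
    elif a < 50.0 - tiny:
        cat = "IMS_GT" if pct > 0 else "IMS_LT"
    else:
        cat = "IMS_GGT" if pct > 0 else "IMS_LLT"
    return pct, cat


def build_concordance(match: MatchResult, isotope_flags=None,
                      lipid_ids=None) -> list[ConcordanceRecord]:
    """Concordance records for every matched pair of a MatchResult."""
    records = []
    for k, (i, j, _) in enumerate(match.pairs):
        mz = (match.extract.mz[i] + match.ims.mz[j]) / 2.0
        pct, cat = classify_concordance(match.ims.intensity[j], match.extract.intensity[i])
        flag = bool(isotope_flags[k]) if isotope_flags is not None else False
        lipid = lipid_ids[k] if lipid_ids is not None else None
        records.append(ConcordanceRecord(mz=float(mz), lipid_id=None if flag else lipid,
                                         isotope_flag=flag, pct_diff=float(pct),
                                         category=cat))
    return records


def summarize_detection(match: MatchResult, records) -> DetectionSummary:
    """Tally the detection overlap; enforces the conservation identities."""
    records = list(records)
    if len(records) != len(match.pairs):
        raise ValueError("concordance records do not correspond 1:1 to matched pairs")
    n_extract = len(match.pairs) + len(match.extract_only)
    n_ims = len(match.pairs) + len(match.ims_only)
    shared = len(match.pairs)
    total = n_extract + n_ims - shared
    tallies = {c: 0 for c in CATEGORIES}
    for r in records:
        tallies[r.category] += 1
    if sum(tallies.values()) != shared:
        raise ValueError("category tallies do not partition the shared set")
    return DetectionSummary(n_extract=n_extract, n_ims=n_ims, shared=shared,
                            extract_only=len(match.extract_only),
                            ims_only=len(match.ims_only), total=total,
                            tallies=tallies)


# ---------------------------------------------------------------------------
# reference-table helpers

#: Per-category sampling intervals for the signed percent difference, with a
#: 2-point margin off the 10%/50% decision boundaries.
_PCT_RANGES = {
    "EQ": (-8.0, 8.0),
    "IMS_GT": (12.0, 48.0),
    "IMS_LT": (-48.0, -12.0),
    "IMS_GGT": (52.0, 150.0),
    "IMS_LLT": (-88.0, -52.0),
}


def realize_table_intensities(records: list[Table1Record], seed: int = 0
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Draw (extract, IMS) intensity pairs realizing each record's category.

    Synthetic stand-in for the unpublished per-ion intensities behind the
    reference table: extract intensities are arbitrary positive values and
    the IMS intensity is displaced by a percent difference drawn inside the
    record's category interval, away from the boundaries.
    """
    rng = np.random.default_rng([seed, 41])
    extract = rng.uniform(0.01, 0.1, size=len(records))
    pct = np.asarray([rng.uniform(*_PCT_RANGES[r.category]) for r in records])
    ims = extract * (1.0 + pct / 100.0)
    return extract, ims


def annotate_lipids(mzs, table: list[Table1Record], tol: float = 0.25) -> list[str | None]:
    """Assign lipid identities to consensus m/z values from a reference table."""
    out = []
    for m in np.asarray(mzs, dtype=float):
        hit = None
        best = tol
        for rec in table:
            d = abs(rec.mz - m)
            if d <= best:
                hit, best = rec.lipid_id, d
        out.append(hit)
    return out


def format_concordance_table(records: list[ConcordanceRecord]) -> str:
    """Render concordance records as the five-glyph tabular text report."""
    lines = ["mz\tlipid_id\tisotope\tpct_diff\tabundance"]
    for r in records:
        lipid = r.lipid_id if r.lipid_id else ("**" if r.isotope_flag else "*")
        lines.append(f"{r.mz:.4g}\t{lipid}\t{int(r.isotope_flag)}\t{r.pct_diff:+.1f}\t{r.glyph}")
    return "\n".join(lines) + "\n"
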