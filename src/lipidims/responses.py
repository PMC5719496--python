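"""Classification of per-ion trajectories across exposure and withdrawal.

Each ion's group-mean intensities over A8 -> CS4 -> CS8 -> CS8+R are mapped
onto a three-axis taxonomy of smoke effects:

* direction — inhibited, stimulated or unchanged, from the CS4/A8 and
  CS8/A8 fold changes against a symmetric no-change band;
* progression — sustained (similar effect at both durations), progressive
  (the CS8 effect exceeds CS4's beyond a progression threshold) or
  transient (an effect at CS4 that has returned into the band by CS8);
* recovery — where the CS8+R mean lands relative to CS8 and the control
  band: full (back inside the band), partial (moved toward control beyond
  the progression threshold but still outside), none, or paradoxical
  (moved further away from control).

All decisions are made on fold changes in log space, so classification is
invariant to global intensity rescaling.  Thresholds are folds > 1; the
defaults (1.25-fold change band, 1.15-fold progression band) are
configurable and reported in output metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

DIRECTIONS = ("inhibited", "stimulated", "unchanged")
PROGRESSIONS = ("sustained", "progressive", "transient", "n/a")
RECOVERIES = ("full", "partial", "none", "paradoxical", "n/a")

_EPS = 1e-12


@dataclass
class GroupProfile:
    """Group-mean intensities of one ion, ordered (A8, CS4, CS8, CS8+R)."""

    ion: float                # consensus m/z
    means: np.ndarray
    modality: str | None = None

    def __post_init__(self):
        self.means = np.asarray(self.means, dtype=float)
        if self.means.shape != (4,):
            raise ValueError("a group profile needs exactly 4 group means")
        if np.any(self.means < 0):
            raise ValueError("group means must be non-negative")


@dataclass(frozen=True)
class ResponsePattern:
    """One taxonomy cell: (direction, progression, recovery)."""

    direction: str
    progression: str
    recovery: str

    def __post_init__(self):
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.progression not in PROGRESSIONS:
            raise ValueError(f"unknown progression {self.progression!r}")
        if self.recovery not in RECOVERIES:
            raise ValueError(f"unknown recovery {self.recovery!r}")
        if self.direction == "unchanged" and (self.progression != "n/a" or self.recovery != "n/a"):
            raise ValueError("unchanged ions carry n/a progression and recovery")


def classify_response(profile: GroupProfile, change_threshold: float = 1.25,
                      progress_threshold: float = 1.15) -> ResponsePattern:
    """Assign exactly one taxonomy cell to a group profile.

    Fold changes are taken relative to the A8 control mean; a fold f is
    "changed" when |ln f| >= ln(change_threshold) (boundary folds count as
    changed, mirroring the concordance boundary convention).
    """
    if change_threshold <= 1 or progress_threshold <= 1:
        raise ValueError("thresholds must exceed 1")
    a8, cs4, cs8, csr = profile.means
    if a8 <= 0:
        raise ValueError("A8 mean must be positive; route this ion to a "
                         "presence/absence track instead")
    lb = math.log(change_threshold)
    lp = math.log(progress_threshold)
    tiny = 1e-12  # float fuzz on boundary folds
    l4, l8, lr = (math.log(max(v / a8, _EPS)) for v in (cs4, cs8, csr))

    out4 = abs(l4) >= lb - tiny
    out8 = abs(l8) >= lb - tiny
    if not out4 and not out8:
        return ResponsePattern("unchanged", "n/a", "n/a")

    ref = l8 if out8 else l4
    direction = "inhibited" if ref < 0 else "stimulated"
    s = -1.0 if direction == "inhibited" else 1.0

    if not out8:
        progression = "transient"
    elif s * (l8 - l4) >= lp - tiny:
        progression = "progressive"
    else:
        progression = "sustained"

    if abs(lr) < lb - tiny:
        recovery = "full"
    elif s * (l8 - lr) >= lp - tiny:
        recovery = "partial"
    elif s * (lr - l8) >= lp - tiny:
        recovery = "paradoxical"
    else:
        recovery = "none"
    return ResponsePattern(direction, progression, recovery)


def recovery_fraction(patterns, subset=None) -> float:
    """Fraction of a pattern subset with recovery in {partial, full}.

    ``subset`` is a predicate over ResponsePattern; by default every
    pattern with an assigned (non-n/a) recovery counts.
    """
    patterns = list(patterns)
    if subset is None:
        subset = lambda p: p.recovery != "n/a"  # noqa: E731
    pool = [p for p in patterns if subset(p)]
    if not pool:
        raise ValueError("empty subset: no ions to compute a recovery fraction over")
    return sum(p.recovery in ("partial", "full") for p in pool) / len(pool)


def is_suppressed(pattern: ResponsePattern) -> bool:
    """Persistently smoke-suppressed: inhibited and still outside the band at CS8."""
    return (pattern.direction == "inhibited"
            and pattern.progression in ("sustained", "progressive"))


def suppressed_recovery_fraction(patterns) -> float:
    """Partial-or-full recovery fraction among persistently suppressed ions.

    Transiently inhibited ions are excluded from the denominator: they have
    already returned to control levels before withdrawal, so a recovery
    fraction over them would be vacuous.
    """
    return recovery_fraction(patterns, subset=is_suppressed)


def identify_diagnostic_ions(profiles, shared_mzs, responsive_fold: float = 2.0,
                             stable_band: float = 1.25, mz_tol: float = 0.25
                             ) -> tuple[list[GroupProfile], list[GroupProfile]]:
    """Split shared ions into exposure-responsive and stable internal controls.

    Responsive: |ln(CS8/A8)| >= ln(responsive_fold) — ions whose long-term
    exposure effect is large enough to report smoke exposure.  Stable: all
    four group means within the ``stable_band`` fold of A8 — candidate
    internal negative controls.  ``responsive_fold`` must exceed
    ``stable_band`` so the sets are disjoint.
    """
    if responsive_fold <= stable_band:
        raise ValueError("responsive_fold must exceed stable_band for disjoint sets")
    shared = np.sort(np.asarray(list(shared_mzs), dtype=float))
    responsive, stable = [], []
    for prof in profiles:
        if shared.size == 0 or np.min(np.abs(shared - prof.ion)) > mz_tol:
            continue
        a8 = prof.means[0]
        if a8 <= 0:
            continue
        folds = np.log(np.maximum(prof.means / a8, _EPS))
        if abs(folds[2]) >= math.log(responsive_fold) - 1e-12:
            responsive.append(prof)
        elif np.max(np.abs(folds)) <= math.log(stable_band) + 1e-12:
            stable.append(prof)
    return responsive, stable


def group_profiles_from_matrix(matrix, sample_groups, modality=None,
                               groups=("A8", "CS4", "CS8", "CS8+R")):
    """Build GroupProfiles from an ions x samples matrix and a group map.

    ``sample_groups`` maps each matrix column to its exposure group.  Only
    ions with a positive mean in every group are classifiable and returned;
    the remainder (presence/absence cases) are returned separately.
    """
    import pandas as pd  # local: keeps numpy-only callers light

    matrix = matrix if hasattr(matrix, "columns") else pd.DataFrame(matrix)
    cols_by_group = {g: [c for c in matrix.columns if sample_groups[c] == g]
                     for g in groups}
    for g, cols in cols_by_group.items():
        if not cols:
            raise ValueError(f"no samples for group {g!r}")
    profiles, unclassifiable = [], []
    for mz, row in matrix.iterrows():
        means = np.asarray([row[cols_by_group[g]].mean() for g in groups])
        prof = GroupProfile(ion=float(mz), means=means, modality=modality)
        if np.all(means > 0):
            profiles.append(prof)
        else:
            unclassifiable.append(prof)
    return profiles, unclassifiable
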