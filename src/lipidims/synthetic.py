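"""Synthetic study generator.

Emulates a two-modality MALDI-TOF lipidomics study of cerebral white matter:
four exposure groups (air control A8; cigarette smoke for 4 or 8 weeks, CS4
and CS8; 8 weeks smoke plus 2 weeks recovery, CS8+R), six replicate animals
per group, and each sample measured both as a plated lipid extract and as an
imaging-mass-spectrometry (IMS) tissue mean spectrum.

The generator plants a panel of lipid ions in m/z 600-1300 Da with
modality-dependent detection bias (IMS favours the high-m/z band, extracts
the low/mid bands, shared ions sit mid-range), assigns each ion a
smoke-response category (inhibited or stimulated; sustained, progressive or
transient; with full, partial, no or paradoxical recovery after withdrawal),
optionally attaches a C13 isotope satellite at +1.00335 Da, and renders
profile spectra as sums of Gaussian peaks over a flat baseline with additive
noise and per-replicate lognormal intensity jitter.

Everything downstream of the instrument is therefore testable against the
planted truth without any external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import (GROUPS, MODALITIES, PeakList, ProfileSpectrum, SampleManifest,
                 write_manifest, write_profile)

#: Mass of one C13-for-C12 substitution, Da.
ISOTOPE_DELTA = 1.00335

#: Response-pattern categories the generator can plant.
CATEGORIES_MIX = (
    "stable",
    "inhibited_sustained", "inhibited_progressive", "inhibited_transient",
    "stimulated_sustained", "stimulated_progressive", "stimulated_transient",
)

DEFAULT_EFFECT_MIX = {
    "stable": 0.15,
    "inhibited_sustained": 0.20,
    "inhibited_progressive": 0.20,
    "inhibited_transient": 0.10,
    "stimulated_sustained": 0.15,
    "stimulated_progressive": 0.10,
    "stimulated_transient": 0.10,
}

# Piecewise band weights over (low, mid, high) thirds of the m/z range; with
# the default 600-1300 Da range the band edges fall at 700 and 800 Da.
# Shared ions sit mid-range, IMS-only ions are biased high, extract-only
# ions low/mid.
BAND_WEIGHTS = {
    "shared": (0.15, 0.70, 0.15),
    "extract": (0.35, 0.45, 0.20),
    "IMS": (0.10, 0.15, 0.75),
}


class SyntheticConfigError(ValueError):
    """Raised for infeasible or inconsistent generator configurations."""


@dataclass
class SyntheticConfig:
    """Design constants of the emulated study.

    Defaults reproduce the printed study design: 83 extract ions, 62 IMS
    ions, 25 shared, m/z 600-1300 Da, 4 groups x 6 replicates, and 60% of
    persistently suppressed ions planted with partial or full recovery.
    """

    n_extract_ions: int = 83
    n_ims_ions: int = 62
    n_shared: int = 25
    mz_range: tuple[float, float] = (600.0, 1300.0)
    n_replicates: int = 6
    groups: tuple[str, ...] = GROUPS
    effect_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EFFECT_MIX))
    recovery_fraction: float = 0.60
    isotope_prob: float = 0.20
    isotope_ratio_range: tuple[float, float] = (0.3, 0.6)
    noise_sd: float = 1.0
    baseline_level: float = 5.0
    sigma_log: float = 0.15          # replicate lognormal jitter, log-scale SD
    base_intensity_range: tuple[float, float] = (100.0, 1000.0)
    peak_sigma: float = 0.05         # Gaussian peak SD, Da
    grid_step: float = 0.01          # profile grid spacing, Da
    min_ion_separation: float = 0.6  # Da; must exceed 2x the match tolerance
    match_tolerance: float = 0.25    # Da; documented downstream default
    isotope_tol: float = 0.1         # Da; half-width of the satellite window
    seed: int = 0

    def validate(self) -> None:
        if self.n_shared > min(self.n_extract_ions, self.n_ims_ions):
            raise SyntheticConfigError("n_shared exceeds a modality's ion count")
        if min(self.n_extract_ions, self.n_ims_ions, self.n_shared) < 0:
            raise SyntheticConfigError("ion counts must be non-negative")
        lo, hi = self.mz_range
        if not hi > lo:
            raise SyntheticConfigError("mz_range must be increasing")
        if not 0.0 <= self.recovery_fraction <= 1.0:
            raise SyntheticConfigError("recovery_fraction must be in [0, 1]")
        if abs(sum(self.effect_mix.values()) - 1.0) > 1e-9:
            raise SyntheticConfigError("effect_mix must sum to 1")
        if set(self.effect_mix) - set(CATEGORIES_MIX):
            raise SyntheticConfigError(f"unknown effect_mix keys: {set(self.effect_mix) - set(CATEGORIES_MIX)}")
        if self.min_ion_separation <= 2 * self.match_tolerance:
            raise SyntheticConfigError("min_ion_separation must exceed 2x match_tolerance")
        if self.min_ion_separation >= ISOTOPE_DELTA - self.isotope_tol:
            raise SyntheticConfigError("min_ion_separation collides with the isotope window")
        if self.grid_step <= 0 or self.peak_sigma <= 0:
            raise SyntheticConfigError("grid_step and peak_sigma must be positive")
        if self.n_replicates < 1:
            raise SyntheticConfigError("need at least one replicate")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mz_range"] = list(self.mz_range)
        d["groups"] = list(self.groups)
        d["isotope_ratio_range"] = list(self.isotope_ratio_range)
        d["base_intensity_range"] = list(self.base_intensity_range)
        return d


@dataclass
class IonRecord:
    """One planted ion: location, modality membership, response and satellite."""

    ion_id: int
    mz: float
    membership: str                      # "extract", "IMS" or "shared"
    base_intensity: dict[str, float]     # per member modality, arbitrary units
    category: str                        # effect_mix category
    multipliers: dict[str, float]        # group -> positive scalar, A8 == 1
    recovery: str                        # full / partial / none / paradoxical / n/a
    satellite: tuple[float, float] | None = None   # (m/z, intensity ratio)

    @property
    def modalities(self) -> tuple[str, ...]:
        return MODALITIES if self.membership == "shared" else (self.membership,)


@dataclass
class PlantedTruth:
    """The generator's ground truth: the full ion panel plus its config."""

    ions: list[IonRecord]
    config: SyntheticConfig

    def members(self, modality: str) -> list[IonRecord]:
        if modality not in MODALITIES:
            raise ValueError(f"unknown modality {modality!r}")
        return [i for i in self.ions if modality in i.modalities]

    def counts(self) -> dict[str, int]:
        shared = sum(1 for i in self.ions if i.membership == "shared")
        return {
            "extract": len(self.members("extract")),
            "IMS": len(self.members("IMS")),
            "shared": shared,
            "total": len(self.ions),
        }

    def validate(self) -> None:
        """Check the planted multipliers against their category's ordering."""
        for ion in self.ions:
            m = ion.multipliers
            groups = self.config.groups
            if any(m[g] <= 0 for g in groups):
                raise AssertionError(f"ion {ion.ion_id}: non-positive multiplier")
            if m.get("A8", 1.0) != 1.0:
                raise AssertionError(f"ion {ion.ion_id}: A8 multiplier must be 1")
            if len(groups) < 4:
                continue
            cat = ion.category
            m4, m8 = m["CS4"], m["CS8"]
            if cat == "stable":
                assert m4 == m8 == m["CS8+R"] == 1.0
            elif cat == "inhibited_progressive":
                assert 1.0 > m4 > m8, f"ion {ion.ion_id}: progressive inhibition order"
            elif cat == "stimulated_progressive":
                assert 1.0 < m4 < m8, f"ion {ion.ion_id}: progressive stimulation order"
            elif cat == "inhibited_sustained":
                assert m4 == m8 < 1.0
            elif cat == "stimulated_sustained":
                assert m4 == m8 > 1.0
            elif cat == "inhibited_transient":
                assert m4 < 1.0 and m8 == 1.0
            elif cat == "stimulated_transient":
                assert m4 > 1.0 and m8 == 1.0

    def to_yaml(self, path) -> None:
        payload = {
            "config": self.config.to_dict(),
            "ions": [
                {**asdict(i), "satellite": list(i.satellite) if i.satellite else None}
                for i in self.ions
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PlantedTruth":
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh)
        cfgd = payload["config"]
        cfgd["mz_range"] = tuple(cfgd["mz_range"])
        cfgd["groups"] = tuple(cfgd["groups"])
        cfgd["isotope_ratio_range"] = tuple(cfgd["isotope_ratio_range"])
        cfgd["base_intensity_range"] = tuple(cfgd["base_intensity_range"])
        config = SyntheticConfig(**cfgd)
        ions = []
        for d in payload["ions"]:
            sat = tuple(d["satellite"]) if d["satellite"] else None
            ions.append(IonRecord(**{**d, "satellite": sat}))
        return cls(ions=ions, config=config)


# ---------------------------------------------------------------------------
# panel construction

def _band_edges(mz_range):
    lo, hi = mz_range
    span = hi - lo
    return lo + span / 7.0, lo + 2.0 * span / 7.0


def _draw_mz(rng, membership, config):
    lo, hi = config.mz_range
    e1, e2 = _band_edges(config.mz_range)
    # keep room for the satellite and the peak wings inside the range
    lo_s, hi_s = lo + 0.5, hi - (ISOTOPE_DELTA + 0.6)
    bands = [(max(lo_s, lo), min(e1, hi_s)),
             (max(lo_s, e1), min(e2, hi_s)),
             (max(lo_s, e2), hi_s)]
    w = np.asarray(BAND_WEIGHTS[membership], dtype=float)
    b = rng.choice(3, p=w / w.sum())
    blo, bhi = bands[b]
    return float(rng.uniform(blo, bhi))


def _spacing_ok(d: float, config: SyntheticConfig) -> bool:
    """No two non-isotope peaks may be closer than min_ion_separation or sit
    inside the (widened) isotope window around +1.00335 Da."""
    if d < config.min_ion_separation:
        return False
    margin = 0.1
    if (ISOTOPE_DELTA - config.isotope_tol - margin) <= d <= (ISOTOPE_DELTA + config.isotope_tol + margin):
        return False
    return True


def _plant_multipliers(rng, category: str, recovery_fraction: float,
                       groups: tuple[str, ...]):
    """Draw group multipliers and a recovery label consistent with a category.

    Magnitudes are drawn with margins of >=2 group-mean noise SDs from the
    downstream classifier's default decision boundaries (1.25-fold change
    band, 1.15-fold progression band) so planted categories are recoverable
    at the default replicate noise.
    """
    if category == "stable":
        mult = {g: 1.0 for g in groups}
        return mult, "n/a"

    direction, progression = category.split("_")
    s = -1.0 if direction == "inhibited" else 1.0

    if progression == "sustained":
        mag = rng.uniform(0.35, 0.48) if s < 0 else rng.uniform(2.1, 2.8)
        m4 = m8 = mag
    elif progression == "progressive":
        if s < 0:
            m4 = rng.uniform(0.5, 0.6)
            m8 = m4 / rng.uniform(1.5, 1.8)
        else:
            m4 = rng.uniform(1.6, 2.0)
            m8 = m4 * rng.uniform(1.5, 1.8)
    else:  # transient: CS4 effect, CS8 back at control level
        m4 = rng.uniform(0.35, 0.5) if s < 0 else rng.uniform(2.0, 2.8)
        m8 = 1.0

    if progression == "transient":
        # already normalized before withdrawal; CS8+R stays at control level
        recovery, mr = "full", 1.0
    elif rng.random() < recovery_fraction:
        if rng.random() < 0.5:
            recovery, mr = "full", 1.0
        else:
            recovery = "partial"
            l8 = abs(math.log(m8))
            u = rng.uniform(math.log(1.44) + 0.05, l8 - math.log(1.3) - 0.05)
            mr = math.exp(s * u)
    else:
        if rng.random() < 0.75:
            recovery, mr = "none", m8
        else:
            recovery = "paradoxical"
            mr = m8 * math.exp(s * rng.uniform(0.25, 0.45))

    mult = {g: 1.0 for g in groups}
    if "CS4" in mult:
        mult["CS4"] = m4
    if "CS8" in mult:
        mult["CS8"] = m8
    if "CS8+R" in mult:
        mult["CS8+R"] = mr
    return mult, recovery


def _balance_base_intensities(ions: list[IonRecord], config: SyntheticConfig,
                              rng) -> bool:
    """Equalize each group's total ion current with control, per modality.

    Planted multipliers describe effects on TIC-normalized (relative)
    abundances — the scale every downstream statistic lives on, since raw
    MALDI intensities are not quantitative.  Normalization divides by the
    summed peak intensities, so a fold change survives it exactly only when
    the group's total ion current matches control's.  The drawn base
    intensities are therefore projected (least squares, with positivity
    clipping) onto the subspace where, for every non-control group g and
    modality, sum_i b_i * (1 + satellite ratio_i) * (m_i(g) - 1) = 0.

    Degenerate panels where some group's effects are all one-signed (no
    positive solution exists) are left unbalanced for that constraint.
    """
    groups_eff = [g for g in config.groups if g != "A8"]
    if not groups_eff:
        return True
    lo, hi = config.base_intensity_range
    for modality in MODALITIES:
        members = [i for i in ions if modality in i.modalities]
        if not members:
            continue
        w = np.asarray([1.0 + (i.satellite[1] if i.satellite else 0.0) for i in members])
        A = np.asarray([[wi * (ion.multipliers[g] - 1.0) for wi, ion in zip(w, members)]
                        for g in groups_eff])
        # drop unbalanceable (one-signed) and null constraint rows
        keep = [r for r in range(A.shape[0])
                if (A[r] > 1e-12).any() and (A[r] < -1e-12).any()]
        A = A[keep]
        if not len(A):
            continue
        blo, bhi = 0.05 * lo, 20.0 * hi
        b = None
        for redraw in range(10):
            if redraw == 0:
                b = np.asarray([i.base_intensity[modality] for i in members])
            else:
                b = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(members)))
            for _ in range(100):
                lam = np.linalg.lstsq(A @ A.T, A @ b, rcond=None)[0]
                proj = b - A.T @ lam
                b = np.clip(proj, blo, bhi)
                if np.allclose(proj, b, rtol=0, atol=1e-9 * hi):
                    break
            # active-set polish: hold clipped variables at their bounds and
            # re-project the free ones so the constraints hold exactly
            free = (b > blo * (1 + 1e-9)) & (b < bhi * (1 - 1e-9))
            if free.any():
                Af = A[:, free]
                lam = np.linalg.lstsq(Af @ Af.T, A @ b, rcond=None)[0]
                b[free] = b[free] - Af.T @ lam
            ok = (np.abs(A @ b).max() / max(b.sum(), 1.0) <= 1e-9) and (b > 0).all()
            if ok:
                break
        else:
            return False
        for ion, bi in zip(members, b):
            ion.base_intensity[modality] = float(bi)
    return True


def generate_ion_panel(config: SyntheticConfig) -> PlantedTruth:
    """Place the ion panel and plant per-ion responses and satellites.

    Rejection-samples monoisotopic positions band by band under two hard
    constraints evaluated over *all* planted peaks (satellites included):
    pairwise separation of at least ``min_ion_separation`` and no
    non-isotope pair inside the widened C13 window, so downstream matching
    and satellite flagging are unambiguous on noiseless data.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 17])
    memberships = (["shared"] * config.n_shared
                   + ["extract"] * (config.n_extract_ions - config.n_shared)
                   + ["IMS"] * (config.n_ims_ions - config.n_shared))
    lo_i, hi_i = config.base_intensity_range
    lo_r, hi_r = config.isotope_ratio_range
    categories = list(config.effect_mix)
    probs = np.asarray([config.effect_mix[c] for c in categories])

    for _attempt in range(20):
        occupied: list[float] = []
        ions: list[IonRecord] = []
        failed = False
        for ion_id, membership in enumerate(memberships):
            placed = False
            for _try in range(4000):
                mz = _draw_mz(rng, membership, config)
                has_sat = rng.random() < config.isotope_prob
                sat_mz = mz + ISOTOPE_DELTA
                ok = all(_spacing_ok(abs(mz - x), config) for x in occupied)
                if ok and has_sat:
                    ok = all(x == mz or _spacing_ok(abs(sat_mz - x), config)
                             for x in occupied)
                if not ok:
                    continue
                category = str(rng.choice(categories, p=probs / probs.sum()))
                mult, recovery = _plant_multipliers(
                    rng, category, config.recovery_fraction, config.groups)
                base = {m: float(np.exp(rng.uniform(np.log(lo_i), np.log(hi_i))))
                        for m in (MODALITIES if membership == "shared" else (membership,))}
                satellite = (sat_mz, float(rng.uniform(lo_r, hi_r))) if has_sat else None
                ions.append(IonRecord(ion_id=ion_id, mz=mz, membership=membership,
                                      base_intensity=base, category=category,
                                      multipliers=mult, recovery=recovery,
                                      satellite=satellite))
                occupied.append(mz)
                if has_sat:
                    occupied.append(sat_mz)
                placed = True
                break
            if not placed:
                failed = True
                break
        if not failed:
            if not _balance_base_intensities(ions, config, rng):
                continue  # retry with freshly drawn positions and responses
            truth = PlantedTruth(ions=ions, config=config)
            truth.validate()
            return truth
    raise SyntheticConfigError(
        "could not place the requested ion panel: too many ions for the m/z "
        "range at the configured minimum separation, or no compositionally "
        "balanced intensity assignment exists for the drawn responses")


# ---------------------------------------------------------------------------
# forward model

def _spectrum_rng(config: SyntheticConfig, group: str, replicate: int, modality: str):
    gi = list(config.groups).index(group)
    mi = MODALITIES.index(modality)
    return np.random.default_rng([config.seed, 29, gi, replicate, mi])


def generate_profile_spectrum(truth: PlantedTruth, group: str, replicate: int,
                              modality: str, config: SyntheticConfig | None = None
                              ) -> ProfileSpectrum:
    """Render one profile spectrum: Gaussian peaks over baseline plus noise.

    Peak height = base intensity x group multiplier x a per-(ion, replicate)
    lognormal jitter; the C13 satellite shares its parent's jitter so the
    planted intensity ratio is preserved exactly.  Deterministic given the
    config seed, group, replicate and modality.
    """
    config = config or truth.config
    if group not in config.groups:
        raise ValueError(f"unknown group {group!r}")
    if modality not in MODALITIES:
        raise ValueError(f"unknown modality {modality!r}")
    lo, hi = config.mz_range
    grid = np.arange(lo, hi + config.grid_step / 2, config.grid_step)
    intens = np.full(grid.shape, float(config.baseline_level))
    rng = _spectrum_rng(config, group, replicate, modality)
    sig = config.peak_sigma
    half = 8.0 * sig
    for ion in truth.members(modality):
        jitter = float(np.exp(rng.normal(0.0, config.sigma_log))) if config.sigma_log > 0 else 1.0
        height = ion.base_intensity[modality] * ion.multipliers[group] * jitter
        centers = [(ion.mz, height)]
        if ion.satellite is not None:
            centers.append((ion.satellite[0], height * ion.satellite[1]))
        for c, h in centers:
            i0 = np.searchsorted(grid, c - half)
            i1 = np.searchsorted(grid, c + half)
            x = grid[i0:i1]
            intens[i0:i1] += h * np.exp(-0.5 * ((x - c) / sig) ** 2)
    if config.noise_sd > 0:
        intens += rng.normal(0.0, config.noise_sd, size=grid.size)
        np.clip(intens, 0.0, None, out=intens)
    sample_id = f"{group}_r{replicate}_{modality}"
    return ProfileSpectrum(grid, intens, sample_id=sample_id, modality=modality)


@dataclass
class StudyData:
    """A full synthetic study: spectra for every cell, manifest and truth."""

    config: SyntheticConfig
    truth: PlantedTruth
    manifest: SampleManifest
    spectra: dict[tuple[str, int, str], ProfileSpectrum]

    def write(self, outdir) -> Path:
        outdir = Path(outdir)
        try:
            outdir.mkdir(parents=True, exist_ok=True)
        except OSError as exc:
            raise OSError(f"cannot create output directory {outdir}: {exc}") from exc
        rows = []
        for (group, rep, modality), spec in self.spectra.items():
            fname = f"{spec.sample_id}.tsv"
            write_profile(spec, outdir / fname)
            rows.append((spec.sample_id, group, rep, modality, fname))
        frame = pd.DataFrame(rows, columns=["sample_id", "group", "replicate",
                                            "modality", "path"])
        manifest = SampleManifest(frame)
        write_manifest(manifest, outdir / "manifest.tsv")
        self.truth.to_yaml(outdir / "truth.yaml")
        return outdir


def generate_study(config: SyntheticConfig, outdir=None) -> StudyData:
    """Generate the full study: groups x replicates x modalities spectra.

    With ``outdir`` given, spectra, manifest and the planted truth are also
    written to disk as plain text; manifest rows correspond 1:1 to the
    emitted files.
    """
    truth = generate_ion_panel(config)
    spectra = {}
    rows = []
    for group in config.groups:
        for rep in range(config.n_replicates):
            for modality in MODALITIES:
                spec = generate_profile_spectrum(truth, group, rep, modality, config)
                spectra[(group, rep, modality)] = spec
                rows.append((spec.sample_id, group, rep, modality, f"{spec.sample_id}.tsv"))
    frame = pd.DataFrame(rows, columns=["sample_id", "group", "replicate",
                                        "modality", "path"])
    study = StudyData(config=config, truth=truth, manifest=SampleManifest(frame),
                      spectra=spectra)
    if outdir is not None:
        study.write(outdir)
    return study
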