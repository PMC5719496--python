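"""End-to-end orchestration from a single configuration.

Composes the stages — ingest or simulate, peak picking, TIC normalization,
replicate aggregation, isotope flagging, cross-modality matching and
concordance, intensity matrices with z-scoring / clustering / PCA, and
response-pattern classification — into one reproducible run with a
machine-readable summary and a provenance block (config hash, seed,
versions).  Conservation identities (total = extract + IMS - shared;
concordance tallies partition the shared set) are enforced before anything
is written.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import (GROUPS, MODALITIES, PeakList, SampleManifest, read_manifest,
                 read_profile, write_peaklist)
from .preprocess import aggregate_replicates, pick_peaks, tic_normalize
from .crossmodal import (build_concordance, flag_isotopes,
                         format_concordance_table, match_peaklists,
                         summarize_detection)
from .multivariate import (build_intensity_matrix, cut_dendrogram,
                           hierarchical_cluster, pca, plot_heatmap,
                           plot_pca_scores, zscore_rows)
from .responses import (classify_response, group_profiles_from_matrix,
                        identify_diagnostic_ions, is_suppressed,
                        recovery_fraction, suppressed_recovery_fraction)
from .synthetic import SyntheticConfig, generate_study

log = logging.getLogger("lipidims")

SCHEMA_VERSION = 1


class PipelineStageError(RuntimeError):
    """A stage failure, carrying the stage name and sample context."""


@dataclass
class PipelineConfig:
    """Every knob of the pipeline in one place.

    Exactly one of ``synthetic`` or ``manifest_path`` provides the data.
    CLI flags override file values; the effective config is serialized into
    the output directory for provenance.
    """

    synthetic: SyntheticConfig | None = None
    manifest_path: str | None = None
    mz_min: float = 600.0
    mz_max: float = 1300.0
    snr_threshold: float = 3.0
    centroid_window: float = 0.1
    cluster_tol: float = 0.25
    min_frequency: float = 0.5
    match_tolerance: float = 0.25
    isotope_tol: float = 0.1
    isotope_max_ratio: float = 1.0
    exclude_isotopes: bool = True
    change_threshold: float = 1.25
    progress_threshold: float = 1.15
    responsive_fold: float = 2.0
    stable_band: float = 1.25
    linkage: str = "complete"
    n_clusters: int = 6
    n_components: int = 3
    scale_pca: bool = True
    outdir: str | None = None
    seed: int = 0
    log_level: str = "INFO"
    make_plots: bool = False

    def validate(self) -> None:
        if (self.synthetic is None) == (self.manifest_path is None):
            raise ValueError("exactly one of synthetic config or manifest_path is required")
        for name in ("snr_threshold", "centroid_window", "cluster_tol",
                     "match_tolerance", "isotope_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.change_threshold <= 1 or self.progress_threshold <= 1:
            raise ValueError("fold thresholds must exceed 1")
        if not self.mz_max > self.mz_min:
            raise ValueError("mz window must be increasing")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["synthetic"] = self.synthetic.to_dict() if self.synthetic else None
        return d

    def config_hash(self) -> str:
        """Hash over the analysis-relevant fields (output location excluded)."""
        d = self.to_dict()
        for volatile in ("outdir", "log_level", "make_plots"):
            d.pop(volatile, None)
        payload = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh) or {}
        syn = d.pop("synthetic", None)
        cfg = cls(**d)
        if syn:
            for key in ("mz_range", "groups", "isotope_ratio_range", "base_intensity_range"):
                if key in syn:
                    syn[key] = tuple(syn[key])
            cfg.synthetic = SyntheticConfig(**syn)
        return cfg


@dataclass
class PipelineResult:
    """Everything a run produced, summary first."""

    summary: dict
    consensus: dict = field(default_factory=dict)        # (group, modality) -> ConsensusPeakList
    match: object = None
    concordance: list = field(default_factory=list)
    matrices: dict = field(default_factory=dict)         # modality -> DataFrame
    patterns: dict = field(default_factory=dict)         # modality -> {mz: ResponsePattern}
    truth: object = None


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineStageError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapper
    return deco


@_stage("ingest")
def _load_samples(config: PipelineConfig):
    """Return (sample records, truth or None); each record carries a spectrum."""
    if config.synthetic is not None:
        study = generate_study(config.synthetic)
        records = [
            {"sample_id": spec.sample_id, "group": g, "replicate": r,
             "modality": m, "spectrum": spec}
            for (g, r, m), spec in study.spectra.items()
        ]
        return records, study.truth
    manifest = read_manifest(config.manifest_path)
    base = Path(config.manifest_path).parent
    records = []
    for row in manifest.rows():
        p = Path(row.path)
        if not p.is_absolute():
            p = base / p
        spec = read_profile(p, sample_id=row.sample_id, modality=row.modality)
        records.append({"sample_id": row.sample_id, "group": row.group,
                        "replicate": int(row.replicate), "modality": row.modality,
                        "spectrum": spec})
    return records, None


@_stage("pick+normalize")
def _pick_all(records, config: PipelineConfig):
    for rec in records:
        try:
            peaks = pick_peaks(rec["spectrum"], snr_threshold=config.snr_threshold,
                               window=config.centroid_window,
                               mz_min=config.mz_min, mz_max=config.mz_max)
            rec["peaks"] = tic_normalize(peaks)
        except Exception as exc:
            raise RuntimeError(f"sample {rec['sample_id']}: {exc}") from exc
    return records


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis and return the run report."""
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    records, truth = _load_samples(config)
    records = _pick_all(records, config)

    groups = sorted({r["group"] for r in records}, key=lambda g: GROUPS.index(g))
    modalities = sorted({r["modality"] for r in records}, key=lambda m: MODALITIES.index(m))

    # per group x modality consensus, with satellite exclusion
    consensus = {}
    n_satellites = {m: 0 for m in modalities}
    for g in groups:
        for m in modalities:
            pls = [r["peaks"] for r in records if r["group"] == g and r["modality"] == m]
            cpl = aggregate_replicates(pls, cluster_tol=config.cluster_tol,
                                       min_frequency=config.min_frequency, group=g)
            flags = flag_isotopes(cpl, tol=config.isotope_tol,
                                  max_ratio=config.isotope_max_ratio)
            if config.exclude_isotopes:
                n_satellites[m] += int(flags.sum()) if g == "A8" else 0
                cpl = cpl.subset(~flags)
            consensus[(g, m)] = cpl

    # cross-modality detection + concordance on the control group
    ctrl = "A8" if "A8" in groups else groups[0]
    summary: dict = {"schema_version": SCHEMA_VERSION, "seed": config.seed,
                     "config_hash": config.config_hash(),
                     "versions": {"lipidims": __version__,
                                  "numpy": np.__version__,
                                  "pandas": pd.__version__}}
    match = concord = detection = None
    if len(modalities) == 2:
        ext, ims = consensus[(ctrl, "extract")], consensus[(ctrl, "IMS")]
        match = match_peaklists(ext, ims, tolerance=config.match_tolerance)
        concord = build_concordance(match)
        detection = summarize_detection(match, concord)
        assert detection.total == detection.n_extract + detection.n_ims - detection.shared
        summary["detection"] = detection.as_dict()
        summary["isotope_satellites_excluded"] = n_satellites
    else:
        log.info("single modality present; matching/concordance skipped")

    # per-modality matrices, clustering, PCA, response patterns
    matrices, patterns_all = {}, {}
    summary["modalities"] = {}
    group_map = {r["sample_id"]: r["group"] for r in records}
    canonical = all(g in groups for g in GROUPS)
    for m in modalities:
        pls = [r["peaks"] for r in records if r["modality"] == m]
        mat = build_intensity_matrix(pls, cluster_tol=config.cluster_tol,
                                     min_frequency=config.min_frequency)
        if config.exclude_isotopes and len(mat):
            row_cpl = PeakList(mat.index.to_numpy(), mat.to_numpy().mean(axis=1))
            flags = flag_isotopes(row_cpl, tol=config.isotope_tol,
                                  max_ratio=config.isotope_max_ratio)
            mat = mat.loc[~flags]
        matrices[m] = mat
        msum: dict = {"n_ions": int(len(mat))}

        # group-mean matrix drives the heat-map statistics
        gm = pd.DataFrame({g: mat[[c for c in mat.columns if group_map[c] == g]].mean(axis=1)
                           for g in groups})
        if len(gm) >= 2 and gm.shape[1] >= 2:
            z = zscore_rows(gm)
            dendro = hierarchical_cluster(z, linkage=config.linkage)
            k = min(config.n_clusters, len(gm))
            labels = cut_dendrogram(dendro, k)
            msum["clusters"] = {"k": k, "sizes": np.bincount(labels).tolist()}
            p = pca(mat.T, n_components=min(config.n_components,
                                            max(1, min(mat.shape) - 1)),
                    scale=config.scale_pca)
            msum["pca_explained_variance"] = [round(float(v), 6)
                                              for v in p.explained_variance_ratio]
            msum["pca_group_separation"] = _separation(p.scores,
                                                       [group_map[c] for c in mat.columns])
        else:
            dendro = labels = p = None

        if canonical:
            profiles, skipped = group_profiles_from_matrix(mat, group_map, modality=m)
            pats = {prof.ion: classify_response(prof, config.change_threshold,
                                                config.progress_threshold)
                    for prof in profiles}
            patterns_all[m] = pats
            counts: dict[str, int] = {}
            for pat in pats.values():
                key = f"{pat.direction}/{pat.progression}/{pat.recovery}"
                counts[key] = counts.get(key, 0) + 1
            suppressed = [p_ for p_ in pats.values() if is_suppressed(p_)]
            msum["patterns"] = {
                "counts": dict(sorted(counts.items())),
                "n_classified": len(pats),
                "n_unclassifiable": len(skipped),
                "n_suppressed": len(suppressed),
            }
            if suppressed:
                msum["patterns"]["recovery_fraction_suppressed"] = round(
                    suppressed_recovery_fraction(pats.values()), 6)
            inhibited = [p_ for p_ in pats.values() if p_.direction == "inhibited"]
            if inhibited:
                msum["patterns"]["recovery_fraction_all_inhibited"] = round(
                    recovery_fraction(pats.values(),
                                      subset=lambda q: q.direction == "inhibited"), 6)
        else:
            log.info("groups %s lack the full exposure design; "
                     "response-pattern stage skipped", groups)
            msum["patterns"] = "skipped: full A8/CS4/CS8/CS8+R design required"
        summary["modalities"][m] = msum

        if config.outdir and dendro is not None and config.make_plots:
            outdir = Path(config.outdir)
            plot_heatmap(z, outdir / f"heatmap_{m}.png", leaf_order=dendro.leaf_order)
            plot_pca_scores(p, [group_map[c] for c in mat.columns],
                            outdir / f"pca_{m}.png")

    # diagnostic ions: responsive vs stable among shared ions (IMS view)
    if match is not None and canonical and "IMS" in patterns_all:
        profiles, _ = group_profiles_from_matrix(matrices["IMS"], group_map,
                                                 modality="IMS")
        responsive, stable = identify_diagnostic_ions(
            profiles, match.pair_mz(), responsive_fold=config.responsive_fold,
            stable_band=config.stable_band, mz_tol=config.match_tolerance)
        summary["diagnostic_ions"] = {
            "responsive": [round(p_.ion, 4) for p_ in responsive],
            "stable": [round(p_.ion, 4) for p_ in stable],
        }

    if detection is not None:
        assert sum(detection.tallies.values()) == detection.shared

    result = PipelineResult(summary=summary, consensus=consensus, match=match,
                            concordance=concord or [], matrices=matrices,
                            patterns=patterns_all, truth=truth)
    if config.outdir:
        _write_outputs(result, config)
    return result


def _separation(scores: np.ndarray, groups: list[str]) -> dict:
    """Between-group centroid distance vs mean within-group spread, on PC1-2."""
    pts = scores[:, : min(2, scores.shape[1])]
    uniq = sorted(set(groups))
    cent = {g: pts[[i for i, gg in enumerate(groups) if gg == g]].mean(axis=0)
            for g in uniq}
    within = float(np.mean([np.linalg.norm(pts[i] - cent[g])
                            for i, g in enumerate(groups)]))
    out = {}
    if "A8" in uniq:
        for g in uniq:
            if g == "A8":
                continue
            between = float(np.linalg.norm(cent[g] - cent["A8"]))
            out[f"A8_vs_{g}"] = round(between / within if within > 0 else np.inf, 4)
    return out


def _write_outputs(result: PipelineResult, config: PipelineConfig) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "effective_config.yaml")
    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(result.summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    for (g, m), cpl in result.consensus.items():
        pl = PeakList(cpl.mz, cpl.intensity, sample_id=f"{g}_{m}_consensus",
                      modality=m)
        write_peaklist(pl, outdir / f"consensus_{g}_{m}.tsv".replace("+", "plus"))
    if result.concordance:
        (outdir / "concordance.tsv").write_text(
            format_concordance_table(result.concordance), encoding="utf-8")
    for m, mat in result.matrices.items():
        mat.to_csv(outdir / f"matrix_{m}.tsv", sep="\t", float_format="%.8g")
    for m, pats in result.patterns.items():
        rows = [(mz, p.direction, p.progression, p.recovery)
                for mz, p in sorted(pats.items())]
        pd.DataFrame(rows, columns=["mz", "direction", "progression", "recovery"]
                     ).to_csv(outdir / f"patterns_{m}.tsv", sep="\t", index=False)
    log.info("outputs written to %s", outdir)
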