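"""Profile spectra -> centroided peak lists -> replicate consensus.

Three stages: SNR-thresholded peak picking with intensity-weighted
centroiding, total-ion-count (TIC) normalization, and single-linkage
aggregation of replicate peak lists into a per-group consensus with
detection frequencies.  Normalization happens per spectrum, before
aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import find_peaks

from .io import PeakList, ProfileSpectrum


@dataclass
class ConsensusPeakList:
    """Group-level consensus ions: m/z, mean normalized intensity, frequency."""

    mz: np.ndarray
    intensity: np.ndarray
    frequency: np.ndarray     # fraction of replicates detecting the ion
    group: str | None = None
    modality: str | None = None
    n_replicates: int = 0
    normalized: bool = True   # built from TIC-normalized replicates

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.frequency = np.asarray(self.frequency, dtype=float)
        if not (self.mz.shape == self.intensity.shape == self.frequency.shape):
            raise ValueError("consensus arrays must have equal shapes")
        if self.mz.size >= 2 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("consensus m/z must be strictly increasing")
        if np.any((self.frequency <= 0) | (self.frequency > 1 + 1e-12)):
            raise ValueError("detection frequency must lie in (0, 1]")

    def __len__(self) -> int:
        return self.mz.size

    def subset(self, mask) -> "ConsensusPeakList":
        mask = np.asarray(mask, dtype=bool)
        return replace(self, mz=self.mz[mask], intensity=self.intensity[mask],
                       frequency=self.frequency[mask])


def pick_peaks(spectrum: ProfileSpectrum, snr_threshold: float = 3.0,
               window: float = 0.1, mz_min: float = 600.0,
               mz_max: float = 1300.0) -> PeakList:
    """Centroid a profile spectrum into a peak list.

    The trace is levelled by its median; the noise level is the median
    absolute deviation of the levelled trace times 1.4826 (the Gaussian
    consistency factor).  Candidates are strict local maxima exceeding
    ``snr_threshold`` times the noise level; each centroid is the
    intensity-weighted mean m/z over +/- ``window`` Da and the reported
    intensity is the levelled apex height.  Only the configured analysis
    range (default 600-1300 Da) is searched.
    """
    if snr_threshold <= 0 or window <= 0:
        raise ValueError("snr_threshold and window must be positive")
    sel = (spectrum.mz >= mz_min) & (spectrum.mz <= mz_max)
    mz = spectrum.mz[sel]
    y = spectrum.intensity[sel]
    if mz.size < 3:
        raise ValueError("spectrum has fewer than 3 points in the analysis range")
    level = float(np.median(y))
    resid = y - level
    noise = 1.4826 * float(np.median(np.abs(resid)))
    top = float(resid.max(initial=0.0))
    if top <= 0:
        return PeakList(np.empty(0), np.empty(0), sample_id=spectrum.sample_id,
                        modality=spectrum.modality)
    # absolute floor guards the noiseless case (MAD = 0) against float dust
    floor = max(snr_threshold * noise, 1e-9 * top)
    idx, _ = find_peaks(resid, height=floor)
    cm, ci = [], []
    for i in idx:
        mask = np.abs(mz - mz[i]) <= window
        w = np.clip(resid[mask], 0.0, None)
        tot = w.sum()
        centroid = float((w * mz[mask]).sum() / tot) if tot > 0 else float(mz[i])
        cm.append(centroid)
        ci.append(float(resid[i]))
    cm = np.asarray(cm)
    ci = np.asarray(ci)
    order = np.argsort(cm, kind="stable")
    cm, ci = cm[order], ci[order]
    # adjacent noise maxima can centroid to (near-)identical m/z; keep the
    # most intense of any centroids closer than one grid step
    step = float(np.median(np.diff(mz)))
    keep_m, keep_i = [], []
    for m, i in zip(cm, ci):
        if keep_m and m - keep_m[-1] < step:
            if i > keep_i[-1]:
                keep_m[-1], keep_i[-1] = m, i
        else:
            keep_m.append(m)
            keep_i.append(i)
    return PeakList(np.asarray(keep_m), np.asarray(keep_i),
                    sample_id=spectrum.sample_id, modality=spectrum.modality)


def tic_normalize(peaks: PeakList) -> PeakList:
    """Divide intensities by the total ion count so they sum to one."""
    if len(peaks) == 0:
        raise ValueError("cannot TIC-normalize an empty peak list")
    total = float(peaks.intensity.sum())
    if total <= 0:
        raise ValueError("cannot TIC-normalize: all intensities are zero")
    out = peaks.copy()
    out.intensity = out.intensity / total
    out.normalized = True
    return out


def _cluster_1d(values: np.ndarray, tol: float) -> np.ndarray:
    """Single-linkage grouping on a line: split where the sorted gap > tol.

    Returns a cluster label per element, in sorted-value order of the input
    (which must already be sorted ascending).
    """
    labels = np.zeros(values.size, dtype=int)
    if values.size:
        labels[1:] = np.cumsum(np.diff(values) > tol)
    return labels


def aggregate_replicates(peaklists, cluster_tol: float = 0.25,
                         min_frequency: float = 0.5,
                         absent_as_zero: bool = True,
                         group: str | None = None) -> ConsensusPeakList:
    """Fuse replicate peak lists of one group/modality into a consensus.

    Peaks pooled across replicates are grouped by single linkage within
    ``cluster_tol`` Da; each replicate contributes at most one peak (its
    most intense) per consensus ion.  Consensus m/z is the mean of the
    contributing peaks; consensus intensity is the mean normalized
    intensity over *all* replicates with absent treated as zero (or over
    detections only if ``absent_as_zero`` is false).  Clusters detected in
    fewer than ``min_frequency`` of replicates are dropped.
    """
    peaklists = list(peaklists)
    if not peaklists:
        raise ValueError("no peak lists to aggregate")
    if cluster_tol <= 0:
        raise ValueError("cluster_tol must be positive")
    modalities = {p.modality for p in peaklists}
    if len(modalities) > 1:
        raise ValueError(f"mixed modalities in aggregation: {sorted(map(str, modalities))}")
    if not all(p.normalized for p in peaklists):
        raise ValueError("aggregate_replicates expects TIC-normalized inputs")
    n_rep = len(peaklists)

    mz = np.concatenate([p.mz for p in peaklists]) if peaklists else np.empty(0)
    inten = np.concatenate([p.intensity for p in peaklists])
    rep = np.concatenate([np.full(len(p), k) for k, p in enumerate(peaklists)])
    if mz.size == 0:
        return ConsensusPeakList(np.empty(0), np.empty(0), np.empty(0),
                                 group=group, modality=peaklists[0].modality,
                                 n_replicates=n_rep)
    order = np.argsort(mz, kind="stable")
    mz, inten, rep = mz[order], inten[order], rep[order]
    labels = _cluster_1d(mz, cluster_tol)

    cms, cis, cfs = [], [], []
    for lab in np.unique(labels):
        m = labels == lab
        # at most one (the most intense) peak per replicate
        best: dict[int, int] = {}
        for j in np.flatnonzero(m):
            r = int(rep[j])
            if r not in best or inten[j] > inten[best[r]]:
                best[r] = j
        js = np.asarray(sorted(best.values()))
        n_det = len(best)
        freq = n_det / n_rep
        if freq < min_frequency - 1e-12:
            continue
        denom = n_rep if absent_as_zero else n_det
        cms.append(float(mz[js].mean()))
        cis.append(float(inten[js].sum() / denom))
        cfs.append(freq)
    order = np.argsort(cms, kind="stable")
    cms = np.asarray(cms)[order]
    cis = np.asarray(cis)[order]
    cfs = np.asarray(cfs)[order]
    return ConsensusPeakList(cms, cis, cfs, group=group,
                             modality=peaklists[0].modality, n_replicates=n_rep)
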