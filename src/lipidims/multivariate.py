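"""Heat-map statistics and score plots for the intensity matrix.

Re-implements the analysis stack behind the study's heat maps and score
plots: per-ion (row) z-scoring, agglomerative hierarchical clustering on
Euclidean distances with a declared deterministic tie-break, dendrogram
cutting into k groups, and principal component analysis of the sample x ion
matrix.  The implementations are self-contained; library decompositions are
used only as independent oracles in the test suite.

The intensity matrix is a pandas DataFrame with ion identifiers (consensus
m/z) as the row index and sample or group identifiers as columns; absent
ions carry zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import _cluster_1d

LINKAGES = ("complete", "average", "single")


@dataclass
class Dendrogram:
    """Agglomerative merge sequence over n leaves.

    ``merges`` lists (cluster a, cluster b, height) with scipy-style ids:
    leaves are 0..n-1 and the i-th merge creates cluster n+i.  ``leaf_order``
    is the left-to-right display order.
    """

    merges: list[tuple[int, int, float]]
    n_leaves: int
    leaf_order: list[int]
    linkage: str = "complete"

    def __post_init__(self):
        if len(self.merges) != self.n_leaves - 1:
            raise ValueError("a dendrogram over n leaves must have n-1 merges")

    def heights(self) -> np.ndarray:
        return np.asarray([h for _, _, h in self.merges])


@dataclass
class PCAResult:
    """Scores (observation x component), loadings (variable x component) and
    explained-variance fractions of a principal component analysis."""

    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    mean: np.ndarray
    scale: np.ndarray


def build_intensity_matrix(peaklists, cluster_tol: float = 0.25,
                           min_frequency: float = 0.5) -> pd.DataFrame:
    """Align peak lists across samples into an ions x samples matrix.

    Peaks pooled over all samples are grouped by single linkage within
    ``cluster_tol`` Da; rows are the consensus m/z of clusters detected in
    at least ``min_frequency`` of the samples, and a sample's entry is its
    most intense peak in the cluster (zero if absent).
    """
    peaklists = list(peaklists)
    if not peaklists:
        raise ValueError("no peak lists given")
    ids = [p.sample_id or f"sample{k}" for k, p in enumerate(peaklists)]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample identifiers")
    mz = np.concatenate([p.mz for p in peaklists])
    inten = np.concatenate([p.intensity for p in peaklists])
    samp = np.concatenate([np.full(len(p), k) for k, p in enumerate(peaklists)])
    if mz.size == 0:
        return pd.DataFrame(np.empty((0, len(ids))), columns=ids)
    order = np.argsort(mz, kind="stable")
    mz, inten, samp = mz[order], inten[order], samp[order]
    labels = _cluster_1d(mz, cluster_tol)
    rows, row_mz = [], []
    n = len(peaklists)
    for lab in np.unique(labels):
        sel = labels == lab
        detected = np.unique(samp[sel])
        if detected.size / n < min_frequency - 1e-12:
            continue
        vals = np.zeros(n)
        for j in np.flatnonzero(sel):
            k = int(samp[j])
            vals[k] = max(vals[k], inten[j])
        rows.append(vals)
        row_mz.append(float(mz[sel].mean()))
    order = np.argsort(row_mz, kind="stable")
    mat = pd.DataFrame(np.asarray(rows)[order] if rows else np.empty((0, n)),
                       index=np.asarray(row_mz)[order] if rows else [],
                       columns=ids)
    mat.index.name = "mz"
    return mat


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Center each row on its mean and scale to unit sample SD (n-1).

    Constant rows (SD ~ 0) are returned as all-zero with a warning, the
    declared degenerate-case policy.
    """
    if matrix.shape[1] < 2:
        raise ValueError("row z-scoring needs at least 2 columns (SD undefined)")
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    degenerate = sd[:, 0] <= 1e-12 * np.maximum(np.abs(mean[:, 0]), 1.0)
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} constant row(s) z-scored to zero",
                      stacklevel=2)
    safe_sd = np.where(sd == 0, 1.0, sd)
    z = (values - mean) / safe_sd
    z[degenerate] = 0.0
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)


# ---------------------------------------------------------------------------
# agglomerative clustering

def _update(linkage: str, d_ak: float, d_bk: float, na: int, nb: int) -> float:
    if linkage == "single":
        return min(d_ak, d_bk)
    if linkage == "complete":
        return max(d_ak, d_bk)
    # average: size-weighted (UPGMA)
    return (na * d_ak + nb * d_bk) / (na + nb)


def hierarchical_cluster(matrix, linkage: str = "complete") -> Dendrogram:
    """Agglomerative clustering of the rows under Euclidean distance.

    Lance-Williams agglomeration with a deterministic tie-break: among
    minimum-distance cluster pairs the one with the lexicographically
    smallest (a, b) cluster ids merges first (ids are scipy-style: leaves
    0..n-1, the i-th merge creates id n+i).
    """
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    X = matrix.to_numpy(dtype=float) if hasattr(matrix, "to_numpy") else np.asarray(matrix, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 rows to cluster")
    if not np.all(np.isfinite(X)):
        raise ValueError("matrix contains non-finite values")

    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(np.linalg.norm(X[i] - X[j]))
    active = {i: 1 for i in range(n)}  # cluster id -> size
    merges = []
    children: dict[int, tuple[int, int]] = {}
    next_id = n
    for _ in range(n - 1):
        (a, b) = min(dist, key=lambda p: (dist[p], p))
        h = dist[(a, b)]
        na, nb = active.pop(a), active.pop(b)
        for k in list(active):
            d_ak = dist.pop((min(a, k), max(a, k)))
            d_bk = dist.pop((min(b, k), max(b, k)))
            dist[(k, next_id)] = _update(linkage, d_ak, d_bk, na, nb)
        del dist[(a, b)]
        merges.append((a, b, h))
        children[next_id] = (a, b)
        active[next_id] = na + nb
        next_id += 1

    def _leaves(c: int) -> list[int]:
        if c < n:
            return [c]
        a, b = children[c]
        return _leaves(a) + _leaves(b)

    leaf_order = _leaves(next_id - 1)
    return Dendrogram(merges=merges, n_leaves=n, leaf_order=leaf_order,
                      linkage=linkage)


def cut_dendrogram(dendro: Dendrogram, k: int) -> np.ndarray:
    """Partition the leaves into k clusters by severing the k-1 last merges.

    Returns an integer label per leaf; labels are numbered by each
    cluster's smallest leaf index, so they are stable under leaf
    reordering.
    """
    n = dendro.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}]")
    parent = list(range(n + len(dendro.merges)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step, (a, b, _) in enumerate(dendro.merges[: n - k]):
        new = n + step
        parent[find(a)] = new
        parent[find(b)] = new
    roots: dict[int, list[int]] = {}
    for leaf in range(n):
        roots.setdefault(find(leaf), []).append(leaf)
    labels = np.empty(n, dtype=int)
    for lab, (_, leaves) in enumerate(sorted(roots.items(), key=lambda kv: min(kv[1]))):
        labels[leaves] = lab
    return labels


def pca(matrix, n_components: int | None = None, scale: bool = True) -> PCAResult:
    """Principal component analysis of observations (rows) x variables.

    Columns are mean-centered and, with ``scale`` (the default, since peak
    intensities span decades), divided by their sample SD; zero-variance
    columns are left unscaled.  Computed by singular value decomposition;
    scores are U*S, loadings the right singular vectors, and the
    explained-variance fractions are relative to the total variance so they
    sum to 1 over the full rank.
    """
    X = matrix.to_numpy(dtype=float) if hasattr(matrix, "to_numpy") else np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 observations")
    mean = X.mean(axis=0)
    Xc = X - mean
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        sd = np.where(sd <= 0, 1.0, sd)
    else:
        sd = np.ones(X.shape[1])
    Xs = Xc / sd
    U, S, Vt = np.linalg.svd(Xs, full_matrices=False)
    tol = S.max(initial=0.0) * max(Xs.shape) * np.finfo(float).eps
    rank = int((S > tol).sum())
    if n_components is None:
        n_components = rank
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds matrix rank {rank}")
    var = S ** 2
    ratio = var / var.sum() if var.sum() > 0 else var
    return PCAResult(scores=(U * S)[:, :n_components],
                     loadings=Vt.T[:, :n_components],
                     explained_variance_ratio=ratio[:n_components],
                     mean=mean, scale=sd)


def plot_heatmap(zmatrix: pd.DataFrame, path, leaf_order=None,
                 clip: float = 1.0) -> None:
    """Thin export of the clustered z-score heat map.

    Six-color diverging palette over z in [-clip, +clip] (clipped), rows in
    dendrogram leaf order; a rendering convenience, not part of the tested
    numerical core.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.colors import BoundaryNorm, ListedColormap

    data = zmatrix.to_numpy(dtype=float)
    if leaf_order is not None:
        data = data[list(leaf_order)]
    data = np.clip(data, -clip, clip)
    palette = ListedColormap(["#08306b", "#2171b5", "#c6dbef",
                              "#fee0d2", "#fb6a4a", "#99000d"])
    norm = BoundaryNorm(np.linspace(-clip, clip, 7), palette.N)
    fig, ax = plt.subplots(figsize=(4, 6))
    im = ax.pcolormesh(data, cmap=palette, norm=norm)
    ax.set_xticks(np.arange(data.shape[1]) + 0.5)
    ax.set_xticklabels(zmatrix.columns, rotation=90, fontsize=6)
    ax.set_yticks([])
    ax.set_ylabel("lipid ions")
    fig.colorbar(im, ax=ax, label="z score")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_pca_scores(result: PCAResult, sample_groups, path) -> None:
    """Thin export of a 2-D PCA score plot colored by exposure group."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    groups = list(sample_groups)
    for g in sorted(set(groups)):
        sel = [i for i, gg in enumerate(groups) if gg == g]
        ax.scatter(result.scores[sel, 0], result.scores[sel, 1], label=g, s=20)
    evr = result.explained_variance_ratio
    ax.set_xlabel(f"PC1 ({100 * evr[0]:.1f}%)")
    if evr.size > 1:
        ax.set_ylabel(f"PC2 ({100 * evr[1]:.1f}%)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
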