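"""From fused latents to interpretable morphological states.

Clustering (Louvain communities on a kNN graph), 2-D UMAP embedding,
per-cluster latent z-score clustergrams, correlated feature groups,
neighbour-similarity (homogeneity) scoring with the fusion-weight sweep,
classical morphometrics, marker quantification and cluster composition.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import networkx as nx
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.ndimage import binary_dilation
from scipy.spatial.distance import cdist
from skimage.filters import sobel
from skimage.measure import regionprops
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.neighbors import NearestNeighbors

from .encoders import combine_latents

__all__ = [
    "KNNLouvain",
    "cluster_latents",
    "embed_umap",
    "zscore_matrix",
    "feature_correlation_groups",
    "homogeneity_score",
    "weight_sweep",
    "morphometrics",
    "quantify_markers",
    "cluster_composition",
]


# ---------------------------------------------------------------------------
# clustering and embedding
# ---------------------------------------------------------------------------

class KNNLouvain(BaseEstimator, ClusterMixin):
    """Louvain community detection on a Euclidean kNN graph of latents.

    Labels are contiguous integers from 0, ordered by decreasing community
    size; an optional ``merge_map`` (raw label -> merged label) reproduces a
    manual post-merge of raw communities into named clusters.
    """

    def __init__(self, knn_k: int = 15, resolution: float = 1.0,
                 seed: int = 0, merge_map: dict | None = None):
        self.knn_k = knn_k
        self.resolution = resolution
        self.seed = seed
        self.merge_map = merge_map

    def fit_predict(self, X, y=None) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        n = len(X)
        if n <= self.knn_k:
            raise ValueError(f"need more than knn_k={self.knn_k} points, got {n}")
        if np.all(X == X[0]):
            # degenerate input: neighbour ranking is meaningless
            self.labels_ = np.zeros(n, dtype=int)
            return self.labels_
        nn = NearestNeighbors(n_neighbors=self.knn_k + 1).fit(X)
        _, idx = nn.kneighbors(X)
        G = nx.Graph()
        G.add_nodes_from(range(n))
        for i in range(n):
            for j in idx[i, 1:]:
                G.add_edge(i, int(j))
        comms = nx.community.louvain_communities(
            G, resolution=self.resolution, seed=self.seed)
        comms = sorted(comms, key=lambda c: (-len(c), min(c)))
        labels = np.empty(n, dtype=int)
        for lab, members in enumerate(comms):
            labels[list(members)] = lab
        if self.merge_map:
            merged = np.array([self.merge_map.get(int(l), int(l))
                               for l in labels])
            # re-index contiguously, preserving merged-label order
            uniq = {v: i for i, v in enumerate(dict.fromkeys(merged.tolist()))}
            labels = np.array([uniq[v] for v in merged])
        self.labels_ = labels
        return labels

    def fit(self, X, y=None):
        self.fit_predict(X)
        return self


def cluster_latents(latents, knn_k: int = 15, resolution: float = 1.0,
                    seed: int = 0, merge_map: dict | None = None) -> np.ndarray:
    return KNNLouvain(knn_k=knn_k, resolution=resolution, seed=seed,
                      merge_map=merge_map).fit_predict(latents)


def embed_umap(latents, n_neighbors: int = 15, min_dist: float = 0.1,
               seed: int = 0) -> np.ndarray:
    """2-D UMAP embedding; deterministic for a fixed seed."""
    import umap

    X = np.asarray(latents, dtype=float)
    if len(X) < n_neighbors:
        raise ValueError("need at least n_neighbors points")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(n_neighbors=n_neighbors, min_dist=min_dist,
                            n_components=2, random_state=seed)
        coords = reducer.fit_transform(X)
    return np.asarray(coords, dtype=float)


# ---------------------------------------------------------------------------
# z-scores and feature groups
# ---------------------------------------------------------------------------

def zscore_matrix(latents, labels):
    """Per-cluster latent z-scores with hierarchical orderings.

    ``Z[c, f] = (mean of feature f in cluster c - dataset mean) / dataset sd``.
    Returns ``(Z, cluster_ids, row_order, col_order)`` where the orders come
    from average-linkage agglomeration of rows and columns.  Zero-variance
    features get z-score 0 with a warning.
    """
    X = np.asarray(latents, dtype=float)
    labels = np.asarray(labels)
    cluster_ids = np.unique(labels)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    dead = sd == 0
    if dead.any():
        warnings.warn(f"{int(dead.sum())} zero-variance features; z-scores set to 0")
        sd = np.where(dead, 1.0, sd)
    Z = np.stack([(X[labels == c].mean(axis=0) - mu) / sd for c in cluster_ids])
    Z[:, dead] = 0.0

    def _order(M):
        if len(M) < 3:
            return np.arange(len(M))
        return leaves_list(linkage(M, method="average"))

    return Z, cluster_ids, _order(Z), _order(Z.T)


def feature_correlation_groups(latents, n_groups: int):
    """Pearson feature-feature correlation matrix and a hierarchical cut.

    Constant features are excluded (their correlation is undefined) with a
    warning.  Returns ``(corr, kept_feature_indices, groups)`` where
    ``groups`` is a list of ``n_groups`` index arrays into the original
    feature axis.
    """
    X = np.asarray(latents, dtype=float)
    if X.shape[1] < 2 or X.shape[0] < 3:
        raise ValueError("need >= 2 features and >= 3 samples")
    sd = X.std(axis=0)
    kept = np.nonzero(sd > 0)[0]
    if len(kept) < X.shape[1]:
        warnings.warn(f"excluded {X.shape[1] - len(kept)} constant features")
    corr = np.corrcoef(X[:, kept], rowvar=False)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    from scipy.cluster.hierarchy import fcluster
    from scipy.spatial.distance import squareform
    link = linkage(squareform(dist, checks=False), method="average")
    cut = fcluster(link, t=min(n_groups, len(kept)), criterion="maxclust")
    groups = [kept[cut == g] for g in np.unique(cut)]
    return corr, kept, groups


# ---------------------------------------------------------------------------
# homogeneity and the fusion-weight sweep
# ---------------------------------------------------------------------------

def homogeneity_score(latents, types, n_neighbors: int = 20):
    """Neighbour-similarity score per type.

    For each cell, the fraction of its ``n_neighbors`` nearest Euclidean
    neighbours (self excluded; distance ties broken by index order) sharing
    the cell's type; ``H_C`` averages this fraction over all cells of type C.
    Returns ``(per_type: dict, mean_score: float)``.
    """
    X = np.asarray(latents, dtype=float)
    types = np.asarray(types)
    n = len(X)
    if n_neighbors >= n:
        raise ValueError("n_neighbors must be smaller than the number of cells")
    frac = np.empty(n)
    block = max(1, int(2e7 // max(n, 1)))
    for start in range(0, n, block):
        stop = min(n, start + block)
        d = cdist(X[start:stop], X)
        for i in range(start, stop):
            row = d[i - start].copy()
            row[i] = np.inf          # exclude self
            nbrs = np.argsort(row, kind="stable")[:n_neighbors]
            frac[i] = np.mean(types[nbrs] == types[i])
    per_type = {t: float(frac[types == t].mean()) for t in np.unique(types)}
    return per_type, float(np.mean(list(per_type.values())))


def weight_sweep(z_shape, z_texture, types, w_grid=None, n_neighbors: int = 20):
    """Mean homogeneity versus fusion weight; returns (table, argmax w).

    Recomputes the fused latents for every w on the grid and scores the mean
    neighbour similarity across types; the maximising w (H_max) identifies
    the best shape/texture balance for the dataset.
    """
    if w_grid is None:
        w_grid = np.linspace(0.0, 1.0, 11)
    w_grid = np.asarray(list(w_grid), dtype=float)
    if w_grid.size == 0:
        raise ValueError("empty weight grid")
    scores = []
    for w in w_grid:
        fused = combine_latents(z_shape, z_texture, float(w))
        _, mean_h = homogeneity_score(fused, types, n_neighbors=n_neighbors)
        scores.append(mean_h)
    table = pd.DataFrame({"w": w_grid, "mean_homogeneity": scores})
    best = float(w_grid[int(np.argmax(scores))])
    return table, best


# ---------------------------------------------------------------------------
# morphometrics, markers, composition
# ---------------------------------------------------------------------------

def morphometrics(mask, image=None, um_per_px: float | None = None) -> dict:
    """Area, eccentricity and edge strength of one cell.

    Area is the mask pixel count (scaled to um^2 when calibrated);
    eccentricity comes from the mask's second central moments; edge strength
    is the maximum Sobel gradient magnitude of the brightfield inside the
    mask dilated by 2 px, so the rim is included.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    props = regionprops(mask.astype(int))[0]
    area = float(props.area)
    if um_per_px is not None:
        area *= um_per_px**2
    out = {"area": area, "eccentricity": float(props.eccentricity)}
    if image is not None:
        grad = sobel(np.asarray(image, dtype=float))
        region = binary_dilation(mask, iterations=2)
        strength = float(grad[region].max())
        # clamp float noise so a constant image reports exactly zero
        out["edge_strength"] = strength if strength > 1e-12 else 0.0
    return out


def quantify_markers(detection_mask, marker_frames: dict,
                     frame_time_min: float, marker_times_min,
                     max_dt_min: float | None = None) -> dict:
    """Background-subtracted mean marker intensity per channel for one cell.

    ``marker_frames`` maps channel name -> stack (T_m, H, W) aligned with
    ``marker_times_min``.  The marker frame nearest in time to the
    brightfield frame is used, provided it lies within ``max_dt_min``
    (default: half the marker interval); otherwise the channel is NaN.
    Background is the median over non-cell pixels of the marker frame, so
    values near background can be slightly negative.
    """
    mask = np.asarray(detection_mask).astype(bool)
    times = np.asarray(marker_times_min, dtype=float)
    if max_dt_min is None:
        max_dt_min = (np.median(np.diff(times)) / 2.0) if len(times) > 1 else np.inf
    out = {}
    k = int(np.argmin(np.abs(times - frame_time_min)))
    usable = abs(times[k] - frame_time_min) <= max_dt_min
    for channel, stack in marker_frames.items():
        if not usable:
            out[channel] = float("nan")
            continue
        frame = np.asarray(stack, dtype=float)
        frame = frame[k] if frame.ndim == 3 else frame
        background = float(np.median(frame[~mask]))
        out[channel] = float(frame[mask].mean() - background)
    return out


def cluster_composition(labels, types, balanced_sample: int | None = None,
                        seed: int = 0) -> pd.DataFrame:
    """Fractional type composition of each cluster; rows sum to 1.

    With ``balanced_sample`` set, an equal number of cells per type is
    subsampled (seeded) before computing, so overrepresented types do not
    dominate the fractions.  Empty clusters get a zero row with a warning.
    """
    labels = np.asarray(labels)
    types = np.asarray(types)
    if balanced_sample is not None:
        rng = np.random.default_rng(seed)
        keep = []
        for t in np.unique(types):
            idx = np.nonzero(types == t)[0]
            if len(idx) < balanced_sample:
                raise ValueError(f"type {t!r} has fewer than {balanced_sample} cells")
            keep.append(rng.choice(idx, size=balanced_sample, replace=False))
        keep = np.concatenate(keep)
        labels, types = labels[keep], types[keep]
    table = pd.crosstab(pd.Series(labels, name="cluster"),
                        pd.Series(types, name="type"))
    sums = table.sum(axis=1)
    empty = sums == 0
    if empty.any():
        warnings.warn(f"clusters {list(table.index[empty])} are empty")
    frac = table.div(sums.replace(0, np.nan), axis=0).fillna(0.0)
    return frac
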