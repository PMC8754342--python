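"""State-transition dynamics from validated frame-to-frame cell pairing.

Instead of assembling full trajectories, cells are linked only between
adjacent frames under two stringent rules: a source cell must be *isolated*
(its nearest same-frame neighbour farther than D0) and its nearest
next-frame cell must lie closer than the maximum travel distance D1.  The
resulting links, together with per-cell cluster labels, yield row-stochastic
transition matrices, instantaneous velocities, UMAP-space vector fields and
condition comparisons — without the error-prone business of long tracks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import chi2_contingency

__all__ = [
    "LinkageSet",
    "TransitionMatrix",
    "link_pairs",
    "suggest_d0",
    "transition_matrix",
    "velocities",
    "transition_vector_field",
    "population_dynamics",
]

_DET_COLS = ("frame", "cell_id", "y", "x")


@dataclass
class LinkageSet:
    """Validated (cell@t -> cell@t+1) pairs with their distances."""

    links: pd.DataFrame      # columns: frame, src_id, dst_id, distance_px
    d0: float
    d1: float

    def __len__(self):
        return len(self.links)


@dataclass
class TransitionMatrix:
    """Row-stochastic cluster transition probabilities and raw counts."""

    P: np.ndarray
    counts: np.ndarray
    frame_interval_min: float = 3.0
    undefined_rows: list = field(default_factory=list)


def _detections_frame(detections) -> pd.DataFrame:
    df = pd.DataFrame(detections) if not isinstance(detections, pd.DataFrame) \
        else detections
    missing = [c for c in _DET_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"detections table lacks columns {missing}")
    if not np.isfinite(df[["y", "x"]].to_numpy()).all():
        raise ValueError("centroids must be finite")
    return df


def suggest_d0(detections, factor: float = 1.5) -> float:
    """Default isolation radius: ``factor`` x mean nearest-neighbour distance.

    Computed per frame over the whole dataset; setting D0 above the average
    spacing keeps only clearly isolated cells in the linkage analysis.
    """
    df = _detections_frame(detections)
    nn_dists = []
    for _, sub in df.groupby("frame"):
        pts = sub[["y", "x"]].to_numpy()
        if len(pts) < 2:
            continue
        d = cdist(pts, pts)
        np.fill_diagonal(d, np.inf)
        nn_dists.extend(d.min(axis=1))
    if not nn_dists:
        raise ValueError("need at least one frame with two cells")
    return factor * float(np.mean(nn_dists))


def link_pairs(detections, d0: float, d1: float,
               exclude_border: bool = True) -> LinkageSet:
    """Pair isolated cells with their nearest next-frame cell.

    For every cell i in frame t whose nearest same-frame neighbour is
    farther than ``d0``: find its nearest cell k in frame t+1 and link them
    if that distance is below ``d1``.  If two sources select the same
    target, the closer pair wins (ties broken by source order), so each cell
    appears in at most one link per role.  Detections flagged
    ``touches_border`` are excluded when ``exclude_border``.  A single frame
    yields an empty LinkageSet.
    """
    if d0 <= 0 or d1 <= 0:
        raise ValueError("d0 and d1 must be positive")
    df = _detections_frame(detections)
    if exclude_border and "touches_border" in df.columns:
        df = df[~df["touches_border"].astype(bool)]
    frames = np.sort(df["frame"].unique())
    rows = []
    by_frame = {t: sub.reset_index(drop=True) for t, sub in df.groupby("frame")}
    for t in frames:
        if t + 1 not in by_frame:
            continue
        src = by_frame[t]
        dst = by_frame[t + 1]
        src_pts = src[["y", "x"]].to_numpy()
        dst_pts = dst[["y", "x"]].to_numpy()
        if len(src_pts) > 1:
            same = cdist(src_pts, src_pts)
            np.fill_diagonal(same, np.inf)
            isolated = same.min(axis=1) > d0
        else:
            isolated = np.ones(len(src_pts), dtype=bool)
        if not isolated.any() or len(dst_pts) == 0:
            continue
        cross = cdist(src_pts[isolated], dst_pts)
        nearest = cross.argmin(axis=1)
        dists = cross[np.arange(len(cross)), nearest]
        candidates = [
            (int(src.loc[src.index[isolated][i], "cell_id"]),
             int(dst.loc[nearest[i], "cell_id"]), float(dists[i]))
            for i in range(len(nearest)) if dists[i] < d1
        ]
        # collision rule: one winner per target, the closer source
        best: dict[int, tuple[int, float]] = {}
        for src_id, dst_id, dist in candidates:
            if dst_id not in best or dist < best[dst_id][1]:
                best[dst_id] = (src_id, dist)
        for dst_id, (src_id, dist) in sorted(best.items()):
            rows.append((int(t), src_id, dst_id, dist))
    links = pd.DataFrame(rows, columns=["frame", "src_id", "dst_id",
                                        "distance_px"])
    return LinkageSet(links=links, d0=float(d0), d1=float(d1))


def transition_matrix(linkages: LinkageSet, labels,
                      n_clusters: int | None = None,
                      frame_interval_min: float = 3.0) -> TransitionMatrix:
    """Estimate P(X_{t+1} = j | X_t = i) = f_ij / sum_k f_ik from links.

    ``labels`` maps (frame, cell_id) -> cluster label, either as a dict or a
    DataFrame with columns frame, cell_id, cluster.  Links whose endpoints
    lack a label are excluded with a warning; rows with zero counts are left
    NaN and listed in ``undefined_rows``.
    """
    if isinstance(labels, pd.DataFrame):
        labels = {(int(r.frame), int(r.cell_id)): int(r.cluster)
                  for r in labels.itertuples()}
    src_lab, dst_lab, skipped = [], [], 0
    for row in linkages.links.itertuples():
        a = labels.get((int(row.frame), int(row.src_id)))
        b = labels.get((int(row.frame) + 1, int(row.dst_id)))
        if a is None or b is None:
            skipped += 1
            continue
        src_lab.append(a)
        dst_lab.append(b)
    if skipped:
        warnings.warn(f"excluded {skipped} links with unlabeled endpoints")
    if n_clusters is None:
        n_clusters = (max(src_lab + dst_lab) + 1) if src_lab else 0
    counts = np.zeros((n_clusters, n_clusters), dtype=int)
    np.add.at(counts, (src_lab, dst_lab), 1)
    row_sums = counts.sum(axis=1)
    P = np.full((n_clusters, n_clusters), np.nan)
    nonzero = row_sums > 0
    P[nonzero] = counts[nonzero] / row_sums[nonzero, None]
    return TransitionMatrix(P=P, counts=counts,
                            frame_interval_min=frame_interval_min,
                            undefined_rows=list(np.nonzero(~nonzero)[0]))


def velocities(linkages: LinkageSet, minutes_per_frame: float,
               um_per_px: float = 1.0, labels=None):
    """Instantaneous speed per link, optionally grouped by source cluster.

    Speed = link distance (um if calibrated) / frame interval (min).
    Returns ``(per_link, summary)`` where ``summary`` has mean/median speed
    per source-cell cluster (None when no labels are given).
    """
    if minutes_per_frame <= 0:
        raise ValueError("minutes_per_frame must be positive")
    per_link = linkages.links.copy()
    per_link["speed"] = per_link["distance_px"] * um_per_px / minutes_per_frame
    summary = None
    if labels is not None:
        if isinstance(labels, pd.DataFrame):
            labels = {(int(r.frame), int(r.cell_id)): int(r.cluster)
                      for r in labels.itertuples()}
        per_link["cluster"] = [
            labels.get((int(r.frame), int(r.src_id)), -1)
            for r in per_link.itertuples()]
        per_link = per_link[per_link["cluster"] >= 0]
        summary = per_link.groupby("cluster")["speed"] \
            .agg(["mean", "median", "count"]).reset_index()
    return per_link, summary


def transition_vector_field(start_xy, end_xy, grid_size: int = 10) -> pd.DataFrame:
    """Mean latent-embedding displacement per grid cell.

    ``start_xy`` / ``end_xy`` are the 2-D embedding coordinates of each
    link's source and target crop.  The embedding extent is divided into a
    ``grid_size`` x ``grid_size`` grid; each cell stores the mean
    displacement vector, the mean displacement magnitude and the link count
    (NaN components mark empty cells).
    """
    start = np.asarray(start_xy, dtype=float)
    end = np.asarray(end_xy, dtype=float)
    if start.shape != end.shape or start.ndim != 2 or start.shape[1] != 2:
        raise ValueError("start/end must be matching (n, 2) arrays")
    disp = end - start
    mag = np.linalg.norm(disp, axis=1)
    xmin, ymin = start.min(axis=0)
    xmax, ymax = start.max(axis=0)
    xedges = np.linspace(xmin, xmax, grid_size + 1)
    yedges = np.linspace(ymin, ymax, grid_size + 1)
    ix = np.clip(np.searchsorted(xedges, start[:, 0], side="right") - 1,
                 0, grid_size - 1)
    iy = np.clip(np.searchsorted(yedges, start[:, 1], side="right") - 1,
                 0, grid_size - 1)
    rows = []
    for gx in range(grid_size):
        for gy in range(grid_size):
            sel = (ix == gx) & (iy == gy)
            n = int(sel.sum())
            if n:
                rows.append((gx, gy, float(disp[sel, 0].mean()),
                             float(disp[sel, 1].mean()),
                             float(mag[sel].mean()), n))
            else:
                rows.append((gx, gy, np.nan, np.nan, np.nan, 0))
    return pd.DataFrame(rows, columns=["grid_x", "grid_y", "dx", "dy",
                                       "magnitude", "n"])


def population_dynamics(state_table: pd.DataFrame,
                        endpoint_fraction: float = 0.05):
    """Per-cluster fraction time series and an endpoint condition test.

    ``state_table`` needs columns frame, cluster and condition.  Fractions
    are computed per condition and frame (each row sums to 1).  With at
    least two conditions, a chi-square test of independence (no continuity
    correction) between treatment and cluster identity is run on the counts
    pooled over the last ``endpoint_fraction`` of frames; cells with
    expected counts below 5 are flagged.  Returns ``(fractions, test)``
    where ``test`` is None for a single condition.
    """
    df = state_table
    for col in ("frame", "cluster", "condition"):
        if col not in df.columns:
            raise ValueError(f"state table lacks column {col!r}")
    counts = df.groupby(["condition", "frame", "cluster"]).size() \
        .unstack(fill_value=0)
    fractions = counts.div(counts.sum(axis=1), axis=0)
    conditions = df["condition"].unique()
    test = None
    if len(conditions) >= 2:
        t_max = df["frame"].max()
        window = max(1, int(np.ceil((t_max + 1) * endpoint_fraction)))
        endpoint = df[df["frame"] > t_max - window]
        table = pd.crosstab(endpoint["condition"], endpoint["cluster"])
        stat, p, dof, expected = chi2_contingency(table.to_numpy(),
                                                  correction=False)
        test = {"statistic": float(stat), "p_value": float(p), "dof": int(dof),
                "low_expected": bool((expected < 5).any())}
    return fractions, test
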