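"""Independent brute-force oracles used by the unit and acceptance tests.

These are deliberately literal, loop-based implementations kept separate
from the package code they check.
"""

import numpy as np


def brute_force_homogeneity(X, types, n_neighbors):
    """Exhaustive pairwise-distance neighbour-similarity score per type."""
    X = np.asarray(X, dtype=float)
    types = np.asarray(types)
    n = len(X)
    fractions = np.empty(n)
    for i in range(n):
        dists = np.array([np.linalg.norm(X[i] - X[j]) if j != i else np.inf
                          for j in range(n)])
        order = np.argsort(dists, kind="stable")[:n_neighbors]
        fractions[i] = sum(types[j] == types[i] for j in order) / n_neighbors
    per_type = {t: float(np.mean([fractions[i] for i in range(n)
                                  if types[i] == t]))
                for t in np.unique(types)}
    return per_type, float(np.mean(list(per_type.values())))


def brute_force_links(frames, d0, d1):
    """Literal transcription of the pairwise linking rules.

    ``frames`` maps frame index -> list of (cell_id, y, x).  A source cell i
    in frame t is considered only if d(i, j) > d0 for every other cell j of
    frame t; it is paired with the nearest cell k of frame t+1 provided
    d(i, k) < d1.  When several sources select the same target, the closest
    source wins (first in order on exact ties).  Returns a set of
    (t, src_id, dst_id) triples.
    """
    links = set()
    for t in sorted(frames):
        if t + 1 not in frames:
            continue
        src = frames[t]
        dst = frames[t + 1]
        candidates = []
        for (i_id, iy, ix) in src:
            isolated = True
            for (j_id, jy, jx) in src:
                if j_id == i_id:
                    continue
                if np.hypot(iy - jy, ix - jx) <= d0:
                    isolated = False
                    break
            if not isolated or not dst:
                continue
            dists = [np.hypot(iy - ky, ix - kx) for (_, ky, kx) in dst]
            k_best = int(np.argmin(dists))
            if dists[k_best] < d1:
                candidates.append((i_id, dst[k_best][0], dists[k_best]))
        winners = {}
        for src_id, dst_id, dist in candidates:
            if dst_id not in winners or dist < winners[dst_id][1]:
                winners[dst_id] = (src_id, dist)
        for dst_id, (src_id, _) in winners.items():
            links.add((t, src_id, dst_id))
    return links


def random_frame_pair(rng, n_max=300, box=400.0):
    """A random two-frame detection table for linking-oracle comparisons."""
    import pandas as pd

    rows = []
    for t in (0, 1):
        n = int(rng.integers(2, n_max + 1))
        ys = rng.uniform(0, box, n)
        xs = rng.uniform(0, box, n)
        for i in range(n):
            rows.append((t, i, ys[i], xs[i]))
    return pd.DataFrame(rows, columns=["frame", "cell_id", "y", "x"])
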