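"""Synthetic microscopy fixtures with known ground truth.

Emulates the observable structure of transmitted-light time-lapse data at the
level the rest of the pipeline consumes: blob-like cells with controllable
size, elongation, edge contrast and granularity; paired pseudo-fluorescence
frames (a smoothed cytoplasm signal); crop populations drawn from distinct
phenotype classes; and movies of motile cells whose class membership switches
according to a known Markov chain.  Every generator is deterministic given a
seed, so downstream stages can be tested against exact ground truth.

Cells are rendered as rotated ellipses with a smooth random boundary
perturbation.  Brightfield convention: background at 0.5 of the dynamic
range, interiors and granules darker, a thin halo just outside the rim
brighter — the look of a round cell in defocused transmitted light.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import CellCrop

__all__ = [
    "CellPhenotypeSpec",
    "SceneSpec",
    "MarkovModel",
    "render_cell",
    "make_crop_dataset",
    "simulate_markov_states",
    "simulate_tracks",
    "simulate_movie",
    "write_movie_tiff",
]


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class CellPhenotypeSpec:
    """Parameters of one morphological class.

    Areas are in px^2; ``eccentricity_mean`` in [0, 1); ``edge_contrast`` is
    the amplitude of the dark rim at the cell boundary; ``granule_density``
    is expected granule count per px^2 of cell area; ``interior_level`` is a
    signed offset of the interior from the 0.5 background.
    """

    class_id: int = 0
    area_mean: float = 400.0
    area_sd: float = 40.0
    eccentricity_mean: float = 0.3
    eccentricity_sd: float = 0.1
    edge_contrast: float = 0.25
    granule_density: float = 0.0
    granule_darkness: float = 0.25
    interior_level: float = -0.05
    #: sd of the low-harmonic radial boundary perturbation (fraction of radius)
    boundary_jitter: float = 0.015

    def __post_init__(self):
        if self.area_mean <= 0:
            raise ValueError("area_mean must be positive")
        if self.area_mean < 4.0:
            raise ValueError("degenerate spec: area_mean below 4 px^2")
        if not 0.0 <= self.eccentricity_mean < 1.0:
            raise ValueError("eccentricity_mean must lie in [0, 1)")
        if self.granule_density < 0:
            raise ValueError("granule_density must be >= 0")
        if self.edge_contrast < 0:
            raise ValueError("edge_contrast must be >= 0")


@dataclass
class SceneSpec:
    """Geometry and acquisition parameters of a simulated movie."""

    frame_shape: tuple[int, int] = (512, 512)
    n_cells: int = 30
    um_per_px: float = 0.325
    minutes_per_frame: float = 3.0
    background_level: float = 0.5
    noise_sd: float = 0.02
    #: per-class isotropic random-walk step scale, px / frame (sd per axis)
    step_sd: tuple[float, ...] = (2.0,)
    exclusion_radius: float = 40.0
    border_margin: float = 24.0

    def __post_init__(self):
        if self.minutes_per_frame <= 0:
            raise ValueError("minutes_per_frame must be positive")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


@dataclass
class MarkovModel:
    """A k-state Markov chain: row-stochastic transition matrix + initial law."""

    P: np.ndarray
    pi: np.ndarray | None = None

    def __post_init__(self):
        self.P = np.asarray(self.P, dtype=float)
        if self.P.ndim != 2 or self.P.shape[0] != self.P.shape[1]:
            raise ValueError("P must be square")
        if np.any(self.P < 0):
            raise ValueError("P entries must be non-negative")
        if not np.allclose(self.P.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("rows of P must sum to 1")
        if self.pi is None:
            self.pi = np.full(self.P.shape[0], 1.0 / self.P.shape[0])
        self.pi = np.asarray(self.pi, dtype=float)
        if self.pi.shape != (self.P.shape[0],) or np.any(self.pi < 0) \
                or not np.isclose(self.pi.sum(), 1.0, atol=1e-12):
            raise ValueError("pi must be a length-k simplex vector")

    @property
    def n_states(self) -> int:
        return self.P.shape[0]


# ---------------------------------------------------------------------------
# single-cell rendering
# ---------------------------------------------------------------------------

def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _boundary_perturbation(rng, amplitude=0.015, harmonics=(3, 4, 5, 6)):
    # harmonics >= 3 roughen the outline without biasing the second moments,
    # so the spec's eccentricity stays in control of elongation
    coef = rng.normal(0.0, amplitude, size=len(harmonics))
    phase = rng.uniform(0, 2 * np.pi, size=len(harmonics))

    def perturb(phi):
        out = np.zeros_like(phi)
        for m, c, p in zip(harmonics, coef, phase):
            out += c * np.cos(m * phi + p)
        return out

    return perturb


def render_cell(spec: CellPhenotypeSpec, seed=0, patch_size: int | None = None,
                noise_sd: float = 0.02):
    """Render one cell: (brightfield patch, boolean mask, fluorescence patch).

    The mask is a single connected component (rotated ellipse with a smooth
    low-harmonic boundary perturbation).  Brightfield shows the interior
    level, a dark rim of amplitude ``edge_contrast`` with a faint outer halo,
    and Poisson-placed dark granules.  Fluorescence is a smoothed copy of the
    mask plus noise, emulating a cytoplasm stain.
    """
    rng = _as_rng(seed)
    area = max(4.0, rng.normal(spec.area_mean, spec.area_sd)) if spec.area_sd > 0 \
        else spec.area_mean
    ecc = float(np.clip(rng.normal(spec.eccentricity_mean, spec.eccentricity_sd), 0.0, 0.95)) \
        if spec.eccentricity_sd > 0 else spec.eccentricity_mean
    # semi-axes from area = pi*a*b with b = a*sqrt(1-e^2)
    a = np.sqrt(area / (np.pi * np.sqrt(1.0 - ecc**2)))
    b = a * np.sqrt(1.0 - ecc**2)
    theta = rng.uniform(0.0, np.pi)
    perturb = _boundary_perturbation(rng, amplitude=spec.boundary_jitter)

    if patch_size is None:
        patch_size = int(2 * np.ceil(1.4 * max(a, b)) + 9)
    h = w = int(patch_size)
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    dy, dx = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = (dx * ct + dy * st) / a
    v = (-dx * st + dy * ct) / b
    rho = np.sqrt(u**2 + v**2)
    phi = np.arctan2(v, u)
    boundary = 1.0 + perturb(phi)
    mask = rho <= boundary

    # keep the largest connected component (perturbation is small; this is a guard)
    lab, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum(mask, lab, range(1, n + 1))
        mask = lab == (1 + int(np.argmax(sizes)))

    rel = rho / np.maximum(boundary, 1e-9)   # 0 centre, 1 at boundary
    bf = np.full((h, w), 0.5)
    interior_core = np.clip(1.0 - rel, 0.0, 1.0) ** 0.5
    bf += spec.interior_level * interior_core * mask
    rim = np.exp(-((rel - 1.0) / 0.10) ** 2) * mask
    bf -= spec.edge_contrast * rim
    halo = np.exp(-((rel - 1.12) / 0.08) ** 2) * (~mask)
    bf += 0.5 * spec.edge_contrast * halo

    n_gran = rng.poisson(spec.granule_density * area)
    if n_gran > 0:
        inside = np.argwhere((rel < 0.8) & mask)
        if len(inside):
            picks = inside[rng.integers(0, len(inside), size=n_gran)]
            stamp = np.zeros((h, w))
            stamp[picks[:, 0], picks[:, 1]] += 1.0
            stamp = ndimage.gaussian_filter(stamp, 1.1)
            peak = 1.0 / (2 * np.pi * 1.1**2)  # unit-count gaussian peak
            bf -= spec.granule_darkness * np.minimum(stamp / peak, 1.5) * mask

    bf += rng.normal(0.0, noise_sd, size=(h, w))
    bf = np.clip(bf, 0.0, 1.0)

    fluor = ndimage.gaussian_filter(mask.astype(float), 1.5) * 0.8
    fluor += rng.normal(0.0, noise_sd, size=(h, w))
    fluor = np.clip(fluor, 0.0, 1.0)
    return bf, mask, fluor


# ---------------------------------------------------------------------------
# crop populations
# ---------------------------------------------------------------------------

def make_crop_dataset(specs, n_per_class: int, seed=0, patch_size: int = 64):
    """Labelled crop population: ``n_per_class`` crops of each phenotype class.

    Returns ``(crops, labels)`` where ``crops`` is a list of
    :class:`~upside.core.CellCrop` (condition = "class<i>") and ``labels`` the
    integer class per crop.  Deterministic given the seed.
    """
    specs = list(specs)
    if not specs:
        raise ValueError("empty spec list")
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    crops, labels = [], []
    centre = ((patch_size - 1) / 2.0, (patch_size - 1) / 2.0)
    for i, spec in enumerate(specs):
        for j in range(n_per_class):
            bf, mask, _ = render_cell(spec, rng, patch_size=patch_size)
            crops.append(CellCrop(bf, mask, centre, frame=0,
                                  condition=f"class{i}",
                                  crop_id=len(crops)))
            labels.append(i)
    return crops, np.asarray(labels, dtype=int)


# ---------------------------------------------------------------------------
# Markov dynamics
# ---------------------------------------------------------------------------

def simulate_markov_states(model: MarkovModel, n_cells: int, T: int, seed=0):
    """State sequences (n_cells, T) sampled from the chain."""
    if T < 2:
        raise ValueError("T must be >= 2")
    rng = _as_rng(seed)
    k = model.n_states
    states = np.empty((n_cells, T), dtype=int)
    states[:, 0] = rng.choice(k, size=n_cells, p=model.pi)
    cum = np.cumsum(model.P, axis=1)
    for t in range(1, T):
        u = rng.random(n_cells)
        states[:, t] = (u[:, None] > cum[states[:, t - 1]]).sum(axis=1)
    return states


def count_transitions(states: np.ndarray, k: int | None = None) -> np.ndarray:
    """Direct-counting estimate of one-step transition counts f_ij."""
    states = np.asarray(states)
    if k is None:
        k = int(states.max()) + 1
    counts = np.zeros((k, k), dtype=int)
    np.add.at(counts, (states[:, :-1].ravel(), states[:, 1:].ravel()), 1)
    return counts


# ---------------------------------------------------------------------------
# movies
# ---------------------------------------------------------------------------

def simulate_tracks(scene: SceneSpec, model: MarkovModel, T: int, seed=0) -> pd.DataFrame:
    """Ground-truth tracks (cell_id, frame, y, x, state) without rendering.

    Cells perform an isotropic Gaussian random walk whose per-axis step sd is
    ``scene.step_sd[state at the source frame]``; positions reflect at a
    border margin.  Initial centroids respect ``scene.exclusion_radius``.
    """
    rng = _as_rng(seed)
    k = model.n_states
    step_sd = np.asarray(scene.step_sd, dtype=float)
    if step_sd.size == 1:
        step_sd = np.repeat(step_sd, k)
    if step_sd.size != k:
        raise ValueError("step_sd must have one entry per state (or one shared)")

    H, W = scene.frame_shape
    m = scene.border_margin
    positions = np.empty((scene.n_cells, 2))
    placed = 0
    for _ in range(20000):
        if placed == scene.n_cells:
            break
        cand = rng.uniform([m, m], [H - m, W - m])
        if placed == 0 or np.all(np.linalg.norm(positions[:placed] - cand, axis=1)
                                 >= scene.exclusion_radius):
            positions[placed] = cand
            placed += 1
    if placed < scene.n_cells:
        raise ValueError(
            f"overcrowded scene: placed only {placed}/{scene.n_cells} cells with "
            f"exclusion radius {scene.exclusion_radius} in frame {scene.frame_shape}")

    states = simulate_markov_states(model, scene.n_cells, T, rng)
    rows = []
    pos = positions.copy()
    for t in range(T):
        for c in range(scene.n_cells):
            rows.append((c, t, pos[c, 0], pos[c, 1], states[c, t]))
        if t < T - 1:
            steps = rng.normal(0.0, 1.0, size=(scene.n_cells, 2)) \
                * step_sd[states[:, t]][:, None]
            pos = pos + steps
            # reflect into the margin box
            pos[:, 0] = np.clip(np.abs(pos[:, 0] - m) + m, None, None)
            pos[:, 0] = np.where(pos[:, 0] > H - m, 2 * (H - m) - pos[:, 0], pos[:, 0])
            pos[:, 1] = np.clip(np.abs(pos[:, 1] - m) + m, None, None)
            pos[:, 1] = np.where(pos[:, 1] > W - m, 2 * (W - m) - pos[:, 1], pos[:, 1])
    return pd.DataFrame(rows, columns=["cell_id", "frame", "y", "x", "state"])


def simulate_movie(scene: SceneSpec, model: MarkovModel, specs, T: int, seed=0):
    """Rendered movie: (brightfield stack, fluorescence stack, tracks).

    Each cell's rendered phenotype at frame t follows its Markov state at t;
    the track table carries the ground truth.  No divisions or deaths: every
    frame contains exactly ``scene.n_cells`` cells.
    """
    specs = list(specs)
    if len(specs) != model.n_states:
        raise ValueError("number of phenotype specs must match Markov states")
    rng = _as_rng(seed)
    tracks = simulate_tracks(scene, model, T, rng)
    H, W = scene.frame_shape
    bf_stack = np.empty((T, H, W))
    fl_stack = np.empty((T, H, W))
    for t in range(T):
        dev = np.zeros((H, W))
        fl = np.zeros((H, W))
        sub = tracks[tracks["frame"] == t]
        for _, row in sub.iterrows():
            spec = specs[int(row["state"])]
            bf, mask, fluor = render_cell(spec, rng, noise_sd=0.0)
            ph, pw = bf.shape
            r0 = int(round(row["y"])) - ph // 2
            c0 = int(round(row["x"])) - pw // 2
            r1, c1 = r0 + ph, c0 + pw
            pr0, pc0 = max(0, -r0), max(0, -c0)
            pr1, pc1 = ph - max(0, r1 - H), pw - max(0, c1 - W)
            fr0, fc0 = max(0, r0), max(0, c0)
            fr1, fc1 = min(H, r1), min(W, c1)
            dev[fr0:fr1, fc0:fc1] += bf[pr0:pr1, pc0:pc1] - 0.5
            fl[fr0:fr1, fc0:fc1] = np.maximum(fl[fr0:fr1, fc0:fc1],
                                              fluor[pr0:pr1, pc0:pc1])
        noise = rng.normal(0.0, scene.noise_sd, size=(H, W))
        bf_stack[t] = np.clip(scene.background_level + dev + noise, 0.0, 1.0)
        fl_stack[t] = np.clip(fl + rng.normal(0.0, scene.noise_sd, size=(H, W)),
                              0.0, 1.0)
    return bf_stack, fl_stack, tracks


def write_movie_tiff(path, stack, bit_depth: int = 16) -> None:
    """Write a float [0, 1] stack as a multi-page unsigned-integer TIFF."""
    import tifffile

    stack = np.asarray(stack, dtype=float)
    if bit_depth == 8:
        data = np.clip(np.round(stack * 255), 0, 255).astype(np.uint8)
    elif bit_depth == 16:
        data = np.clip(np.round(stack * 65535), 0, 65535).astype(np.uint16)
    else:
        raise ValueError("bit_depth must be 8 or 16")
    tifffile.imwrite(path, data)
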