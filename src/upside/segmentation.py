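"""Label-free segmentation: brightfield -> synthetic fluorescence -> objects.

A small patch-wise encoder-decoder regresses the cytoplasm-fluorescence
image from the brightfield image; objects are then segmented from the
*predicted* fluorescence (Otsu threshold + distance-transform watershed) and
per-cell crops are cut around the detected centroids.  Training on stained
pairs and inference on unstained movies means the time-lapse itself never
needs a fluorescent label.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops
from skimage.segmentation import watershed
from skimage.feature import peak_local_max
from sklearn.base import BaseEstimator, RegressorMixin

from ._nn import MLP, Adam
from .core import CellCrop, Detection

__all__ = [
    "LabelFreePredictor",
    "train_labelfree",
    "predict_fluorescence",
    "segment_frame",
    "evaluate_prediction",
    "cut_crops",
]


def _tile_coords(n: int, patch: int, stride: int):
    starts = list(range(0, max(n - patch, 0) + 1, stride))
    if starts[-1] != n - patch and n > patch:
        starts.append(n - patch)
    return starts


class LabelFreePredictor(BaseEstimator, RegressorMixin):
    """Patch-wise dense encoder-decoder for fluorescence prediction.

    Overlapping ``patch_size`` tiles of the brightfield frame are flattened,
    passed through a bottleneck MLP, and regressed against the matching
    fluorescence tiles (mean-squared-error loss, Adam).  Whole-frame
    inference stitches overlapping tile predictions with uniform blending.

    Parameters
    ----------
    patch_size : side of the square training/inference tile (px).
    hidden : width of the bottleneck layer.
    steps : number of Adam steps.
    batch_size, lr, seed : optimisation settings.
    """

    def __init__(self, patch_size: int = 32, hidden: int = 128,
                 steps: int = 500, batch_size: int = 32, lr: float = 1e-3,
                 seed: int = 0):
        self.patch_size = patch_size
        self.hidden = hidden
        self.steps = steps
        self.batch_size = batch_size
        self.lr = lr
        self.seed = seed

    # -- training -----------------------------------------------------------
    def _extract_pairs(self, pairs, stride):
        X, Y = [], []
        p = self.patch_size
        for bf, fl in pairs:
            bf = np.asarray(bf, dtype=float)
            fl = np.asarray(fl, dtype=float)
            if bf.shape != fl.shape:
                raise ValueError("brightfield/fluorescence shapes differ")
            if bf.ndim != 2:
                raise ValueError("frames must be 2-D")
            for r in _tile_coords(bf.shape[0], p, stride):
                for c in _tile_coords(bf.shape[1], p, stride):
                    X.append(bf[r:r + p, c:c + p].ravel())
                    Y.append(fl[r:r + p, c:c + p].ravel())
        return np.asarray(X), np.asarray(Y)

    def fit(self, pairs, stride: int | None = None):
        """Fit on a list of (brightfield, fluorescence) frame pairs."""
        if self.steps <= 0:
            raise ValueError("steps must be positive")
        pairs = list(pairs)
        if not pairs:
            raise ValueError("no training pairs supplied")
        stride = stride or self.patch_size // 2
        X, Y = self._extract_pairs(pairs, stride)
        rng = np.random.default_rng(self.seed)
        d = self.patch_size**2
        self.net_ = MLP([d, self.hidden, d], rng, out="sigmoid")
        opt = Adam(self.net_.params, lr=self.lr)
        self.loss_history_ = []
        n = len(X)
        for _ in range(self.steps):
            idx = rng.integers(0, n, size=min(self.batch_size, n))
            xb, yb = X[idx], Y[idx]
            pred = self.net_.forward(xb)
            resid = pred - yb
            self.loss_history_.append(float((resid**2).mean()))
            self.net_.backward(2.0 * resid / resid.size)
            opt.step(self.net_.grads)
        return self

    # -- inference ----------------------------------------------------------
    def predict(self, frame, stride: int | None = None) -> np.ndarray:
        """Predict the fluorescence image for one brightfield frame."""
        frame = np.asarray(frame, dtype=float)
        if frame.ndim != 2:
            raise ValueError("frame must be 2-D")
        p = self.patch_size
        stride = stride or p // 2
        if frame.shape[0] < p or frame.shape[1] < p:
            raise ValueError(f"frame smaller than patch size {p}")
        acc = np.zeros(frame.shape)
        weight = np.zeros(frame.shape)
        tiles, coords = [], []
        for r in _tile_coords(frame.shape[0], p, stride):
            for c in _tile_coords(frame.shape[1], p, stride):
                tiles.append(frame[r:r + p, c:c + p].ravel())
                coords.append((r, c))
        preds = self.net_.forward(np.asarray(tiles))
        for (r, c), pred in zip(coords, preds):
            acc[r:r + p, c:c + p] += pred.reshape(p, p)
            weight[r:r + p, c:c + p] += 1.0
        return acc / weight

    def holdout_loss(self, pairs) -> float:
        """Mean squared error on (brightfield, fluorescence) pairs."""
        X, Y = self._extract_pairs(list(pairs), self.patch_size)
        pred = self.net_.forward(X)
        return float(((pred - Y) ** 2).mean())


def train_labelfree(pairs, steps: int = 500, seed: int = 0,
                    **kwargs) -> LabelFreePredictor:
    """Train a :class:`LabelFreePredictor` on paired frames."""
    return LabelFreePredictor(steps=steps, seed=seed, **kwargs).fit(pairs)


def predict_fluorescence(model: LabelFreePredictor, frame) -> np.ndarray:
    return model.predict(frame)


def evaluate_prediction(pred, truth) -> float:
    """Pearson correlation between a predicted and a true fluorescence image.

    Symmetric and invariant to affine rescaling of either argument.  Raises
    on zero-variance input, where the coefficient is undefined.
    """
    pred = np.asarray(pred, dtype=float).ravel()
    truth = np.asarray(truth, dtype=float).ravel()
    if pred.shape != truth.shape:
        raise ValueError("shapes differ")
    if pred.std() == 0 or truth.std() == 0:
        raise ValueError("Pearson correlation undefined for zero-variance input")
    return float(np.corrcoef(pred, truth)[0, 1])


def segment_frame(pred_frame, min_area: int = 30, max_area: int = 100000,
                  min_distance: int = 7) -> list[Detection]:
    """Segment objects from a predicted fluorescence frame.

    Global Otsu threshold, distance-transform watershed to split touching
    objects, then an area gate [min_area, max_area].  Returns disjoint
    detections with centroids, mask patches and border flags.
    """
    frame = np.asarray(pred_frame, dtype=float)
    if not np.isfinite(frame).any():
        raise ValueError("frame contains no finite values")
    lo, hi = np.nanmin(frame), np.nanmax(frame)
    if hi - lo < 1e-9:
        return []
    binary = frame > threshold_otsu(frame)
    if not binary.any():
        return []
    dist = ndimage.distance_transform_edt(binary)
    peaks = peak_local_max(dist, min_distance=min_distance, labels=binary)
    markers = np.zeros(frame.shape, dtype=int)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        labels = cc_label(binary)
    else:
        labels = watershed(-dist, markers, mask=binary)
    detections: list[Detection] = []
    H, W = frame.shape
    for prop in regionprops(labels):
        if not (min_area <= prop.area <= max_area):
            continue
        r0, c0, r1, c1 = prop.bbox
        touches = r0 == 0 or c0 == 0 or r1 == H or c1 == W
        detections.append(Detection(
            frame=0, centroid=tuple(prop.centroid), mask=prop.image,
            offset=(r0, c0), area=int(prop.area), touches_border=touches,
            detection_id=len(detections)))
    return detections


def cut_crops(bf_frame, detections, crop_size: int = 64,
              frame_index: int = 0, condition: str = "") -> list[CellCrop]:
    """Cut fixed-size crops around detection centroids.

    Border crops are padded with the frame's median background intensity;
    each crop carries the detection's mask patch placed into the same window.
    """
    if crop_size % 2 == 0:
        raise ValueError("crop_size must be odd-square; use an odd size")
    frame = np.asarray(bf_frame, dtype=float)
    half = crop_size // 2
    pad_val = float(np.median(frame))
    crops = []
    for det in detections:
        r = int(round(det.centroid[0]))
        c = int(round(det.centroid[1]))
        img = np.full((crop_size, crop_size), pad_val)
        msk = np.zeros((crop_size, crop_size), dtype=bool)
        r0, c0 = r - half, c - half
        fr0, fc0 = max(0, r0), max(0, c0)
        fr1 = min(frame.shape[0], r0 + crop_size)
        fc1 = min(frame.shape[1], c0 + crop_size)
        img[fr0 - r0:fr1 - r0, fc0 - c0:fc1 - c0] = frame[fr0:fr1, fc0:fc1]
        # place the detection's mask patch in frame coordinates
        mr0, mc0 = det.offset
        mrows, mcols = np.nonzero(det.mask)
        rr = mrows + mr0 - r0
        cc = mcols + mc0 - c0
        keep = (rr >= 0) & (rr < crop_size) & (cc >= 0) & (cc < crop_size)
        msk[rr[keep], cc[keep]] = True
        crops.append(CellCrop(img, msk, det.centroid, frame=frame_index,
                              condition=condition, crop_id=det.detection_id))
    return crops
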