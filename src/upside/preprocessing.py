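"""Pose normalisation of cell crops into mask and texture images.

Each live crop is reduced to the two canonical inputs of the twin
autoencoders:

* a **mask image** — the binary silhouette, re-centred, rotated so the
  second-moment major axis is vertical, and reflected so pixel mass is
  biased to the top and the right;
* a **texture image** — the brightfield interior under the same pose,
  standardised to zero mean / unit variance and then mapped linearly onto
  [0, 1], with every pixel outside the mask fixed at 0.5.

Removing pose this way makes the learned encodings invariant to rotation
and reflection, so latent variance is spent on shape and texture rather
than on orientation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import transform as sktransform
from skimage.measure import regionprops

from .core import CellCrop

__all__ = [
    "CanonicalCrop",
    "CropCanonicalizer",
    "canonicalize_crop",
    "make_mask_image",
    "make_texture_image",
]


@dataclass
class CanonicalCrop:
    """A pose-normalised crop: aligned mask + brightfield and the pose used."""

    mask: np.ndarray          # boolean, canonical size
    image: np.ndarray         # aligned brightfield, canonical size
    rotation_deg: float
    flip_vertical: bool
    flip_horizontal: bool
    scale: float
    degenerate_texture: bool = False


def _orientation_and_ratio(mask: np.ndarray) -> tuple[float, float]:
    """Major-axis angle (deg, vs the vertical/row axis) and axis-length ratio."""
    props = regionprops(mask.astype(int))[0]
    angle = np.degrees(props.orientation)  # 0 when major axis is vertical
    minor = max(props.axis_minor_length, 1e-9)
    return angle, props.axis_major_length / minor


def canonicalize_crop(crop: CellCrop, size: int = 64, margin: float = 0.10,
                      tie_ratio: float = 1.05) -> CanonicalCrop:
    """Re-centre, rotate vertical, reflect mass to top/right, fit to frame.

    Rotation is skipped when the moment-axis ratio is below ``tie_ratio``
    (near-circular cells have no defined orientation).  Rescaling is applied
    only when the aligned mask would overflow the canonical frame minus its
    margin, so absolute cell size is preserved for typical crops.
    """
    mask = np.asarray(crop.mask).astype(bool)
    image = np.asarray(crop.image, dtype=float)
    if not mask.any():
        raise ValueError("empty mask")
    border = np.concatenate([mask[0], mask[-1], mask[:, 0], mask[:, -1]])
    if border.mean() > 0.5:
        raise ValueError("mask touches more than half of the crop border")

    # embed in a working canvas large enough for any rotation
    canvas = max(size * 2, int(np.ceil(np.hypot(*mask.shape))) + 4)
    img_c = np.full((canvas, canvas), 0.5)
    msk_c = np.zeros((canvas, canvas), dtype=bool)
    r0 = (canvas - mask.shape[0]) // 2
    c0 = (canvas - mask.shape[1]) // 2
    img_c[r0:r0 + mask.shape[0], c0:c0 + mask.shape[1]] = image
    msk_c[r0:r0 + mask.shape[0], c0:c0 + mask.shape[1]] = mask

    centre = (canvas - 1) / 2.0

    def recentre(img, msk):
        cy, cx = ndimage.center_of_mass(msk)
        shift = (centre - cy, centre - cx)
        img = ndimage.shift(img, shift, order=1, cval=0.5)
        msk = ndimage.shift(msk.astype(float), shift, order=0, cval=0.0) > 0.5
        return img, msk

    img_c, msk_c = recentre(img_c, msk_c)

    angle, ratio = _orientation_and_ratio(msk_c)
    rotation = float(angle) if ratio >= tie_ratio else 0.0
    if rotation != 0.0:
        img_c = sktransform.rotate(img_c, -rotation, order=1, cval=0.5)
        msk_c = sktransform.rotate(msk_c.astype(float), -rotation,
                                   order=0, cval=0.0) > 0.5
        img_c, msk_c = recentre(img_c, msk_c)

    cy, cx = ndimage.center_of_mass(msk_c)
    flip_v = cy > centre   # mass should sit in the top half
    flip_h = cx < centre   # and in the right half
    if flip_v:
        img_c, msk_c = img_c[::-1].copy(), msk_c[::-1].copy()
    if flip_h:
        img_c, msk_c = img_c[:, ::-1].copy(), msk_c[:, ::-1].copy()

    rows = np.any(msk_c, axis=1).nonzero()[0]
    cols = np.any(msk_c, axis=0).nonzero()[0]
    extent = max(rows[-1] - rows[0] + 1, cols[-1] - cols[0] + 1)
    allowed = size * (1.0 - margin)
    scale = min(1.0, allowed / extent)
    if scale < 1.0:
        img_c = sktransform.rescale(img_c, scale, order=1, cval=0.5,
                                    mode="constant")
        msk_c = sktransform.rescale(msk_c.astype(float), scale, order=0,
                                    cval=0.0, mode="constant") > 0.5
        pad = canvas - img_c.shape[0]
        img_c = np.pad(img_c, ((0, pad), (0, pad)), constant_values=0.5)
        msk_c = np.pad(msk_c, ((0, pad), (0, pad)))
        img_c, msk_c = recentre(img_c, msk_c)

    half = size // 2
    lo = int(round(centre)) - half
    win = slice(lo, lo + size)
    img_out = img_c[win, win]
    msk_out = msk_c[win, win]
    if not msk_out.any():
        raise ValueError("mask vanished during canonicalisation")
    return CanonicalCrop(mask=msk_out, image=img_out, rotation_deg=rotation,
                         flip_vertical=bool(flip_v), flip_horizontal=bool(flip_h),
                         scale=scale)


def make_mask_image(canonical: CanonicalCrop) -> np.ndarray:
    """Binary {0, 1} float image of the canonical silhouette."""
    return canonical.mask.astype(float)


def make_texture_image(canonical: CanonicalCrop) -> np.ndarray:
    """Standardised interior texture on [0, 1] with exterior fixed at 0.5.

    Interior pixels are z-scored then mapped linearly so min = 0 and
    max = 1 exactly.  A constant interior is degenerate: the whole image
    becomes 0.5 and the crop is flagged.
    """
    mask = canonical.mask
    out = np.full(mask.shape, 0.5)
    interior = canonical.image[mask]
    if interior.size < 2 or interior.std() < 1e-12:
        canonical.degenerate_texture = True
        return out
    z = (interior - interior.mean()) / interior.std()
    out[mask] = (z - z.min()) / (z.max() - z.min())
    return out


class CropCanonicalizer:
    """Transformer: list of crops -> (mask image stack, texture image stack).

    sklearn-style ``transform`` surface; stateless, so ``fit`` is a no-op.
    Poses are kept in ``poses_`` after the last transform for provenance.
    """

    def __init__(self, size: int = 64, margin: float = 0.10,
                 tie_ratio: float = 1.05):
        self.size = size
        self.margin = margin
        self.tie_ratio = tie_ratio

    def get_params(self, deep=True):
        return {"size": self.size, "margin": self.margin,
                "tie_ratio": self.tie_ratio}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, crops=None, y=None):
        return self

    def transform(self, crops):
        masks, textures, poses = [], [], []
        for crop in crops:
            canon = canonicalize_crop(crop, size=self.size, margin=self.margin,
                                      tie_ratio=self.tie_ratio)
            masks.append(make_mask_image(canon))
            textures.append(make_texture_image(canon))
            poses.append((getattr(crop, "crop_id", -1), canon.rotation_deg,
                          canon.flip_vertical, canon.flip_horizontal,
                          canon.scale, canon.degenerate_texture))
        self.poses_ = poses
        return np.asarray(masks), np.asarray(textures)

    fit_transform = transform
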