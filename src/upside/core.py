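"""Shared data containers used across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class CellCrop:
    """One segmented cell: a brightfield patch with its binary mask.

    ``centroid`` is (row, col) in frame coordinates, 0-based; ``frame`` is the
    0-based movie frame index; ``condition`` is a free-form experimental label
    (treatment arm, cell type, ...).
    """

    image: np.ndarray
    mask: np.ndarray
    centroid: tuple[float, float]
    frame: int = 0
    condition: str = ""
    crop_id: int = -1

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=float)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask shapes differ")


@dataclass
class Detection:
    """A segmented object in one frame.

    ``mask`` is a binary patch whose top-left corner sits at ``offset``
    (row, col) in the frame; ``centroid`` is in frame coordinates.
    """

    frame: int
    centroid: tuple[float, float]
    mask: np.ndarray
    offset: tuple[int, int] = (0, 0)
    area: int = field(default=0)
    touches_border: bool = False
    detection_id: int = -1

    def __post_init__(self):
        self.mask = np.asarray(self.mask).astype(bool)
        if self.area == 0:
            self.area = int(self.mask.sum())
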