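"""Axis-aligned bounding boxes in 0-based, half-open pixel coordinates.

Every box in this package uses the same convention: ``x`` runs along image
columns, ``y`` along rows, and a box covers the pixel rectangle
``[x_min, x_max) x [y_min, y_max)``.  Only the Pascal VOC layer in
:mod:`eyespot.annotations` converts to/from VOC's 1-based inclusive indices.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

#: Class names accepted by the annotation layer; one per detection scheme.
CLASS_VOCABULARY = ("spot", "eyespot", "element", "marginal_eyespot")


@dataclass(frozen=True)
class Box:
    """A labelled, optionally scored bounding box.

    ``score`` is ``None`` for ground truth and a probability in [0, 1] for a
    detection.
    """

    x_min: float
    y_min: float
    x_max: float
    y_max: float
    label: str = "element"
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(f"degenerate box: {self}")
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score outside [0, 1]: {self.score}")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        """(x, y) of the box center."""
        return (0.5 * (self.x_min + self.x_max), 0.5 * (self.y_min + self.y_max))

    def clipped(self, width: int, height: int) -> "Box":
        """Clip to an image of the given size; raises if nothing remains."""
        return replace(
            self,
            x_min=max(0.0, self.x_min),
            y_min=max(0.0, self.y_min),
            x_max=min(float(width), self.x_max),
            y_max=min(float(height), self.y_max),
        )

    def as_array(self) -> np.ndarray:
        return np.array([self.x_min, self.y_min, self.x_max, self.y_max], dtype=float)


def boxes_to_array(boxes: Sequence[Box]) -> np.ndarray:
    """Stack boxes into an (N, 4) float array of (x_min, y_min, x_max, y_max)."""
    if len(boxes) == 0:
        return np.zeros((0, 4), dtype=float)
    return np.stack([b.as_array() for b in boxes])


def iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between two (N, 4) / (M, 4) arrays of half-open boxes."""
    a = np.asarray(a, dtype=float).reshape(-1, 4)
    b = np.asarray(b, dtype=float).reshape(-1, 4)
    ix = np.maximum(
        0.0,
        np.minimum(a[:, None, 2], b[None, :, 2]) - np.maximum(a[:, None, 0], b[None, :, 0]),
    )
    iy = np.maximum(
        0.0,
        np.minimum(a[:, None, 3], b[None, :, 3]) - np.maximum(a[:, None, 1], b[None, :, 1]),
    )
    inter = ix * iy
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(union > 0, inter / union, 0.0)
    return out


def mask_to_box(mask: np.ndarray, label: str = "element") -> Box:
    """Tight half-open box around the nonzero pixels of a mask."""
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("empty mask has no bounding box")
    return Box(
        x_min=float(cols.min()),
        y_min=float(rows.min()),
        x_max=float(cols.max() + 1),
        y_max=float(rows.max() + 1),
        label=label,
    )
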