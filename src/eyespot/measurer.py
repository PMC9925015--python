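"""From detections to calibrated area measurements.

For every detected eyespot: extract a square crop around the box, resize it
to the segmenter's input size, segment, undo the resize (nearest neighbor,
so label sets are preserved), count pixels per region and convert to mm²
through the pixel scale (default 1 mm = 28.944 px, i.e. area_mm² =
area_px / 28.944²).

The two-class path recovers the center morphologically: invert the rings
mask, delete every 8-connected component of the inverse that touches the
crop boundary, and keep the components enclosed by the rings.  A broken
ring lets the center leak to the boundary and yields an (explicitly logged)
empty center.

The whole-wing baseline segments the full image instead and splits it into
eyespots by connected-component labelling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage.segmentation import find_boundaries
from skimage.transform import resize as _sk_resize

from .annotations import MeasurementRecord
from .boxes import Box
from .synthetic import DEFAULT_PX_PER_MM

logger = logging.getLogger(__name__)

_STRUCT8 = np.ones((3, 3), dtype=bool)  # 8-connectivity


@dataclass(frozen=True)
class CropGeometry:
    """Where a crop came from and how it was padded at image borders."""

    image_id: str
    center: tuple[float, float]  # (row, col) in the source image
    side: int
    pad_top: int = 0
    pad_left: int = 0
    pad_bottom: int = 0
    pad_right: int = 0
    model_input_size: int = 128

    def __post_init__(self) -> None:
        if self.side <= 0:
            raise ValueError("crop side must be positive")


def extract_crop(
    image: np.ndarray,
    box: Optional[Box] = None,
    center: Optional[tuple[float, float]] = None,
    side: Optional[int] = None,
    margin_factor: float = 1.25,
    image_id: str = "image",
    model_input_size: int = 128,
) -> tuple[np.ndarray, CropGeometry]:
    """Square crop around a box (or explicit center + side).

    The side is ``margin_factor * max(box width, height)`` rounded to int;
    border overflow is padded with replicated edge pixels and recorded in
    the geometry.
    """
    h, w = image.shape[:2]
    if box is not None:
        cx, cy = box.center
        center = (cy, cx)
        side = int(round(margin_factor * max(box.width, box.height)))
    elif center is None or side is None:
        raise ValueError("provide either a box or center and side")
    if side <= 0:
        raise ValueError("degenerate box: crop side would be zero")
    r0 = int(round(center[0])) - side // 2
    c0 = int(round(center[1])) - side // 2
    r1, c1 = r0 + side, c0 + side
    pad_top = max(0, -r0)
    pad_left = max(0, -c0)
    pad_bottom = max(0, r1 - h)
    pad_right = max(0, c1 - w)
    crop = image[max(0, r0) : min(h, r1), max(0, c0) : min(w, c1)]
    if pad_top or pad_left or pad_bottom or pad_right:
        crop = np.pad(
            crop,
            ((pad_top, pad_bottom), (pad_left, pad_right)) + ((0, 0),) * (image.ndim - 2),
            mode="edge",
        )
    geom = CropGeometry(
        image_id=image_id,
        center=(float(center[0]), float(center[1])),
        side=side,
        pad_top=pad_top,
        pad_left=pad_left,
        pad_bottom=pad_bottom,
        pad_right=pad_right,
        model_input_size=model_input_size,
    )
    return crop, geom


def resize_crop(crop: np.ndarray, size: int = 128) -> np.ndarray:
    """Bilinear resize of an RGB crop to the model input size."""
    if crop.shape[0] == size and crop.shape[1] == size:
        return crop.astype(np.float32)
    out = _sk_resize(crop, (size, size), order=1, anti_aliasing=False, preserve_range=True)
    return out.astype(np.float32)


def inverse_resize_mask(mask: np.ndarray, geom: CropGeometry) -> np.ndarray:
    """Nearest-neighbor resize of a label mask back to the crop's true side."""
    side = geom.side
    if mask.shape == (side, side):
        return mask.copy()
    out = _sk_resize(mask, (side, side), order=0, anti_aliasing=False, preserve_range=True)
    return out.astype(mask.dtype)


def strip_padding(mask: np.ndarray, geom: CropGeometry) -> np.ndarray:
    """Zero out border-replicated pixels so they never count as area."""
    out = mask.copy()
    if geom.pad_top:
        out[: geom.pad_top] = 0
    if geom.pad_bottom:
        out[-geom.pad_bottom :] = 0
    if geom.pad_left:
        out[:, : geom.pad_left] = 0
    if geom.pad_right:
        out[:, -geom.pad_right :] = 0
    return out


def isolate_center(rings_mask: np.ndarray) -> np.ndarray:
    """Center mask from a two-class rings mask via border-clearing morphology.

    Inverts the mask, removes every 8-connected component touching the crop
    boundary, and returns the union of the remaining (ring-enclosed)
    components.  An empty result (e.g. a broken ring leaking to the border)
    is valid and logged.
    """
    rings = np.asarray(rings_mask) > 0
    negative = ~rings
    labels, n = ndimage.label(negative, structure=_STRUCT8)
    if n == 0:
        return np.zeros_like(rings, dtype=np.uint8)
    border = np.unique(
        np.concatenate([labels[0], labels[-1], labels[:, 0], labels[:, -1]])
    )
    keep = np.setdiff1d(np.arange(1, n + 1), border)
    if keep.size == 0:
        logger.warning("isolate_center: no enclosed component (broken or absent ring)")
        return np.zeros_like(rings, dtype=np.uint8)
    if keep.size > 1:
        logger.warning("isolate_center: %d enclosed components kept", keep.size)
    return np.isin(labels, keep).astype(np.uint8)


def measure(
    center_mask: np.ndarray,
    rings_mask: np.ndarray,
    geom: CropGeometry,
    px_per_mm: float = DEFAULT_PX_PER_MM,
    eyespot_id: int = 0,
) -> MeasurementRecord:
    """Pixel counts and mm² areas of one eyespot.

    Masks are binary, at the crop's original scale, and must be disjoint;
    mm² = px / px_per_mm².
    """
    center = np.asarray(center_mask) > 0
    rings = np.asarray(rings_mask) > 0
    if center.shape != rings.shape:
        raise ValueError("center and rings masks differ in shape")
    if np.any(center & rings):
        raise ValueError("center and rings masks overlap")
    if center.shape == (geom.side, geom.side):
        center = strip_padding(center, geom).astype(bool)
        rings = strip_padding(rings, geom).astype(bool)
    c_px = float(center.sum())
    r_px = float(rings.sum())
    scale = px_per_mm**2
    return MeasurementRecord(
        image_id=geom.image_id,
        eyespot_id=eyespot_id,
        center_area_px=c_px,
        rings_area_px=r_px,
        center_area_mm2=c_px / scale,
        rings_area_mm2=r_px / scale,
        px_per_mm=px_per_mm,
        crop_center_row=geom.center[0],
        crop_center_col=geom.center[1],
        crop_side=float(geom.side),
    )


def whole_wing_split(mask: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """Split a whole-wing label mask into per-eyespot (center, rings) pairs.

    Connected components (8-connectivity) of rings ∪ center define the
    eyespots; a component without center pixels yields center = 0 with a
    warning.
    """
    mask = np.asarray(mask)
    fg = mask > 0
    labels, n = ndimage.label(fg, structure=_STRUCT8)
    out = []
    for k in range(1, n + 1):
        comp = labels == k
        center = (comp & (mask == 2)).astype(np.uint8)
        rings = (comp & (mask == 1)).astype(np.uint8)
        if center.sum() == 0:
            logger.warning("whole_wing_split: component %d has rings but no center", k)
        out.append((center, rings))
    return out


def run_measurement_pipeline(
    image: np.ndarray,
    detections: Sequence[Box],
    seg_model,
    px_per_mm: float = DEFAULT_PX_PER_MM,
    margin_factor: float = 1.25,
    image_id: str = "image",
) -> list[MeasurementRecord]:
    """Measure every (post-NMS) detection on one image.

    Per-crop failures are logged and skipped, never fatal.
    """
    from .segmenter import segment  # local import to avoid a cycle

    size = seg_model.config.input_size
    records = []
    for i, det in enumerate(detections):
        try:
            crop, geom = extract_crop(
                image, box=det, margin_factor=margin_factor,
                image_id=image_id, model_input_size=size,
            )
            resized = resize_crop(crop, size)
            labels = segment(seg_model, resized)
            if seg_model.config.n_classes == 3:
                center_small = (labels == 2).astype(np.uint8)
                rings_small = (labels == 1).astype(np.uint8)
            else:
                rings_small = (labels == 1).astype(np.uint8)
                center_small = isolate_center(rings_small)
            center = inverse_resize_mask(center_small, geom)
            rings = inverse_resize_mask(rings_small, geom)
            rings[center > 0] = 0  # keep masks disjoint after nearest resize
            records.append(measure(center, rings, geom, px_per_mm, eyespot_id=i))
        except Exception:  # noqa: BLE001 - per-crop robustness is the contract
            logger.exception("measurement failed for detection %d on %s", i, image_id)
    return records


def draw_overlay(
    image: np.ndarray,
    items: Sequence[tuple[CropGeometry, np.ndarray, np.ndarray]],
) -> np.ndarray:
    """Paint center (cyan) and rings (magenta) contours back onto the image."""
    out = np.asarray(image, dtype=np.float32).copy()
    h, w = out.shape[:2]
    for geom, center, rings in items:
        r0 = int(round(geom.center[0])) - geom.side // 2
        c0 = int(round(geom.center[1])) - geom.side // 2
        for mask, col in ((rings, (1.0, 0.0, 1.0)), (center, (0.0, 1.0, 1.0))):
            bound = find_boundaries(mask > 0, mode="outer")
            rr, cc = np.nonzero(bound)
            rr = rr + r0
            cc = cc + c0
            ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
            out[rr[ok], cc[ok]] = col
    return out
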