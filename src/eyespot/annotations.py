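"""Readers and writers for the on-disk formats the pipeline touches.

Formats: Pascal VOC XML bounding-box annotations (the dialect written by
labelImg), single-channel PNG label masks, measurement CSVs and dataset
manifests.  Internal coordinates are always 0-based half-open
(:mod:`eyespot.boxes`); only this layer converts to VOC's 1-based inclusive
pixel indices (``x_min = xmin - 1``, ``x_max = xmax`` on read).
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .boxes import Box, CLASS_VOCABULARY

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = ["image_path", "xml_path", "mask_path", "split", "seed"]


@dataclass(frozen=True)
class ImageMeta:
    """Size metadata carried by a VOC annotation file."""

    filename: str
    width: int
    height: int
    depth: int = 3


@dataclass(frozen=True)
class MeasurementRecord:
    """Areas of one eyespot in pixels and mm², with crop traceability.

    ``total`` always equals ``center + rings`` in both units; the mm² values
    are the pixel counts divided by ``px_per_mm`` squared.
    """

    image_id: str
    eyespot_id: int
    center_area_px: float
    rings_area_px: float
    center_area_mm2: float
    rings_area_mm2: float
    px_per_mm: float
    crop_center_row: float = 0.0
    crop_center_col: float = 0.0
    crop_side: float = 0.0

    @property
    def total_area_px(self) -> float:
        return self.center_area_px + self.rings_area_px

    @property
    def total_area_mm2(self) -> float:
        return self.center_area_mm2 + self.rings_area_mm2

    def __post_init__(self) -> None:
        if self.center_area_px < 0 or self.rings_area_px < 0:
            raise ValueError("areas must be non-negative")
        for px, mm2 in (
            (self.center_area_px, self.center_area_mm2),
            (self.rings_area_px, self.rings_area_mm2),
        ):
            if abs(mm2 - px / self.px_per_mm**2) > 1e-9 * max(1.0, abs(mm2)):
                raise ValueError("mm² areas inconsistent with pixel areas and scale")


# ---------------------------------------------------------------------------
# Pascal VOC XML
# ---------------------------------------------------------------------------

def read_voc_xml(path) -> tuple[ImageMeta, list[Box]]:
    """Parse a Pascal VOC XML file into image metadata and internal boxes."""
    tree = ET.parse(str(path))
    root = tree.getroot()
    size = root.find("size")
    if size is None:
        raise ValueError(f"{path}: missing <size> element")
    meta = ImageMeta(
        filename=root.findtext("filename", default=""),
        width=int(size.findtext("width")),
        height=int(size.findtext("height")),
        depth=int(size.findtext("depth", default="3")),
    )
    boxes: list[Box] = []
    for i, obj in enumerate(root.iter("object")):
        name = obj.findtext("name")
        if name not in CLASS_VOCABULARY:
            raise ValueError(f"{path}: object {i} has unknown class {name!r}")
        bnd = obj.find("bndbox")
        if bnd is None:
            raise ValueError(f"{path}: object {i} has no <bndbox>")
        xmin = float(bnd.findtext("xmin"))
        ymin = float(bnd.findtext("ymin"))
        xmax = float(bnd.findtext("xmax"))
        ymax = float(bnd.findtext("ymax"))
        score_text = obj.findtext("score")
        score = float(score_text) if score_text is not None else None
        try:
            box = Box(
                x_min=xmin - 1.0,
                y_min=ymin - 1.0,
                x_max=xmax,
                y_max=ymax,
                label=name,
                score=score,
            ).clipped(meta.width, meta.height)
        except ValueError as exc:
            raise ValueError(f"{path}: object {i}: {exc}") from exc
        boxes.append(box)
    return meta, boxes


def write_voc_xml(path, meta: ImageMeta, boxes: Sequence[Box]) -> None:
    """Write boxes as Pascal VOC XML (inverse of :func:`read_voc_xml`).

    Non-integer coordinates are rounded to the nearest pixel and the rounding
    is logged at debug level.
    """
    root = ET.Element("annotation")
    ET.SubElement(root, "folder").text = str(Path(str(path)).parent.name)
    ET.SubElement(root, "filename").text = meta.filename
    size = ET.SubElement(root, "size")
    ET.SubElement(size, "width").text = str(meta.width)
    ET.SubElement(size, "height").text = str(meta.height)
    ET.SubElement(size, "depth").text = str(meta.depth)
    ET.SubElement(root, "segmented").text = "0"
    for box in boxes:
        coords = (box.x_min, box.y_min, box.x_max, box.y_max)
        if any(abs(c - round(c)) > 1e-9 for c in coords):
            logger.debug("rounding non-integer box %s for VOC export", box)
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "name").text = box.label
        ET.SubElement(obj, "pose").text = "Unspecified"
        ET.SubElement(obj, "truncated").text = "0"
        ET.SubElement(obj, "difficult").text = "0"
        bnd = ET.SubElement(obj, "bndbox")
        ET.SubElement(bnd, "xmin").text = str(int(round(box.x_min)) + 1)
        ET.SubElement(bnd, "ymin").text = str(int(round(box.y_min)) + 1)
        ET.SubElement(bnd, "xmax").text = str(int(round(box.x_max)))
        ET.SubElement(bnd, "ymax").text = str(int(round(box.y_max)))
        if box.score is not None:
            ET.SubElement(obj, "score").text = f"{box.score:.6f}"
    ET.indent(root)
    ET.ElementTree(root).write(str(path), encoding="unicode", xml_declaration=False)


# ---------------------------------------------------------------------------
# Label masks (single-channel PNG)
# ---------------------------------------------------------------------------

def write_mask_png(path, mask: np.ndarray) -> None:
    """Write an integer label mask as an 8-bit single-channel PNG."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    Image.fromarray(mask.astype(np.uint8), mode="L").save(str(path))


def read_mask_png(path, n_classes: int = 3) -> np.ndarray:
    """Read a label mask and validate its labels against the class count."""
    img = Image.open(str(path))
    if img.mode != "L":
        raise ValueError(f"{path}: expected single-channel mask, got mode {img.mode}")
    mask = np.asarray(img, dtype=np.uint8)
    bad = np.setdiff1d(np.unique(mask), np.arange(n_classes))
    if bad.size:
        raise ValueError(f"{path}: unexpected label values {bad.tolist()} for {n_classes} classes")
    return mask


# ---------------------------------------------------------------------------
# Image PNG helpers
# ---------------------------------------------------------------------------

def write_image_png(path, image: np.ndarray) -> None:
    """Write a float RGB image in [0, 1] as an 8-bit PNG."""
    arr = np.clip(np.asarray(image), 0.0, 1.0)
    Image.fromarray((arr * 255.0 + 0.5).astype(np.uint8)).save(str(path))


def read_image_png(path) -> np.ndarray:
    """Read an image as float RGB in [0, 1] (the /255 normalization)."""
    arr = np.asarray(Image.open(str(path)).convert("RGB"), dtype=np.float32)
    return arr / 255.0


# ---------------------------------------------------------------------------
# Measurement CSVs
# ---------------------------------------------------------------------------

_CSV_COLUMNS = [
    "image_id",
    "eyespot_id",
    "center_area_px",
    "rings_area_px",
    "total_area_px",
    "center_area_mm2",
    "rings_area_mm2",
    "total_area_mm2",
    "px_per_mm",
    "crop_center_row",
    "crop_center_col",
    "crop_side",
]


def write_measurements_csv(path, records: Iterable[MeasurementRecord]) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "image_id": r.image_id,
                "eyespot_id": r.eyespot_id,
                "center_area_px": r.center_area_px,
                "rings_area_px": r.rings_area_px,
                "total_area_px": r.total_area_px,
                "center_area_mm2": r.center_area_mm2,
                "rings_area_mm2": r.rings_area_mm2,
                "total_area_mm2": r.total_area_mm2,
                "px_per_mm": r.px_per_mm,
                "crop_center_row": r.crop_center_row,
                "crop_center_col": r.crop_center_col,
                "crop_side": r.crop_side,
            }
        )
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(str(path), index=False)


def read_measurements_csv(path) -> pd.DataFrame:
    df = pd.read_csv(str(path))
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# Manifests
# ---------------------------------------------------------------------------

def write_manifest(path, rows: Sequence[dict]) -> None:
    pd.DataFrame(list(rows), columns=MANIFEST_COLUMNS).to_csv(str(path), index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(str(path))
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing columns {sorted(missing)}")
    return df
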