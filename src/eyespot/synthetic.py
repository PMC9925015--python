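"""Seeded synthetic wing scenes and eyespot crops with exact ground truth.

The generator emulates the two kinds of data the pipeline consumes:

* *scenes* — wing-like images containing several pattern elements: simple
  one-color **spots** and three-region **eyespots** (white center, black
  disc, orange outer ring) on a low-contrast textured background with
  vein-like curves;
* *crops* — square single-eyespot patches, the input of the segmentation
  stage, with a three-class label mask (0 background, 1 rings, 2 center).

Rasterization rule: a pixel belongs to a disc iff its *center* lies inside
the (possibly eccentric, rotated) ellipse.  True areas are pixel counts of
the rendered per-element masks, so mask/area consistency is exact by
construction.  All randomness flows from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .boxes import Box, mask_to_box
from . import annotations as anio

#: Label values used by every mask in the package.
BACKGROUND, RINGS, CENTER = 0, 1, 2

#: Calibration used by the demo data: 1 mm = 28.944 px.
DEFAULT_PX_PER_MM = 28.944

_CENTER_COLOR = np.array([0.93, 0.93, 0.88])
_BLACK_COLOR = np.array([0.10, 0.08, 0.06])
_ORANGE_COLOR = np.array([0.82, 0.52, 0.12])
_SPOT_COLORS = np.array([[0.12, 0.09, 0.07], [0.75, 0.45, 0.10], [0.85, 0.80, 0.70]])
_WING_COLOR = np.array([0.52, 0.42, 0.30])


@dataclass(frozen=True)
class ElementSpec:
    """Geometry and colors of one pattern element before rasterization."""

    kind: str  # "spot" | "eyespot"
    subtype: str  # "marginal" | "discal" | "none"
    center: tuple[float, float]  # (row, col)
    radii: tuple[float, ...]  # eyespot: (r_center, r_black, r_orange); spot: (r,)
    colors: np.ndarray  # (3, 3) for eyespot, (1, 3) for spot
    eccentricity: float = 0.0  # minor axis = r * (1 - ecc)
    angle: float = 0.0  # major-axis rotation, radians

    def __post_init__(self) -> None:
        if self.kind not in ("spot", "eyespot"):
            raise ValueError(f"unknown element kind {self.kind!r}")
        if self.kind == "eyespot":
            rc, rb, ro = self.radii
            if not (0 < rc < rb < ro):
                raise ValueError(f"eyespot radii must satisfy 0 < r_center < r_black < r_orange, got {self.radii}")
        elif self.radii[0] <= 0:
            raise ValueError("spot radius must be positive")
        if not (0.0 <= self.eccentricity <= 0.3):
            raise ValueError("eccentricity must lie in [0, 0.3]")

    @property
    def outer_radius(self) -> float:
        return self.radii[-1]


@dataclass
class SceneGroundTruth:
    """Per-scene annotation: specs, tight boxes, disjoint per-element masks
    and exact pixel areas.  ``masks[i]`` holds labels {0, 1, 2}."""

    elements: list[ElementSpec]
    boxes: list[Box]
    masks: list[np.ndarray]
    true_center_area_px: np.ndarray
    true_rings_area_px: np.ndarray
    px_per_mm: float = DEFAULT_PX_PER_MM

    @property
    def true_total_area_px(self) -> np.ndarray:
        return self.true_center_area_px + self.true_rings_area_px

    def combined_mask(self, shape: Optional[tuple[int, int]] = None) -> np.ndarray:
        """Union of the disjoint per-element masks as one label raster."""
        if shape is None:
            if not self.masks:
                raise ValueError("cannot infer shape of an empty scene")
            shape = self.masks[0].shape
        out = np.zeros(shape, dtype=np.uint8)
        for m in self.masks:
            out[m > 0] = m[m > 0]
        return out


@dataclass(frozen=True)
class SceneParams:
    """Knobs of the generator; defaults emulate the moderate-contrast,
    textured-background conditions of real wing photographs."""

    image_size: tuple[int, int] = (256, 256)
    n_elements: tuple[int, int] = (1, 4)  # inclusive range; pass (k, k) for exactly k
    eyespot_outer_radius: tuple[float, float] = (14.0, 26.0)
    spot_radius: tuple[float, float] = (6.0, 14.0)
    background: str = "textured"  # "flat" | "textured"
    contrast: float = 0.7  # element-vs-wing contrast in [0, 1]
    texture_amplitude: float = 0.15
    color_jitter: float = 0.08
    max_eccentricity: float = 0.25
    overlap_allowed: bool = False
    p_eyespot: float = 0.5
    p_marginal: float = 0.88  # fraction of eyespots that are marginal
    noise_sigma: float = 0.01
    px_per_mm: float = DEFAULT_PX_PER_MM
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_size
        if h < 64 or w < 64:
            raise ValueError("image_size must be at least 64x64")
        if not (0.0 <= self.contrast <= 1.0):
            raise ValueError("contrast must lie in [0, 1]")
        for rng_ in (self.eyespot_outer_radius, self.spot_radius):
            if rng_[0] <= 0 or rng_[1] < rng_[0]:
                raise ValueError("radius ranges must be positive and ordered")
        if self.background not in ("flat", "textured"):
            raise ValueError("background must be 'flat' or 'textured'")


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def _ellipse_membership(shape, center, radius, ecc, angle):
    """Boolean mask of pixels whose center lies inside the rotated ellipse
    with semi-axes (radius, radius * (1 - ecc))."""
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    dy = rr - center[0]
    dx = cc - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = dx * ca + dy * sa
    v = -dx * sa + dy * ca
    a = radius
    b = radius * (1.0 - ecc)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def rasterize_element(spec: ElementSpec, shape: tuple[int, int]) -> np.ndarray:
    """Label mask {0,1,2} of one element on an empty canvas of ``shape``."""
    mask = np.zeros(shape, dtype=np.uint8)
    if spec.kind == "spot":
        inside = _ellipse_membership(shape, spec.center, spec.radii[0], spec.eccentricity, spec.angle)
        mask[inside] = RINGS
        return mask
    rc, rb, ro = spec.radii
    outer = _ellipse_membership(shape, spec.center, ro, spec.eccentricity, spec.angle)
    inner = _ellipse_membership(shape, spec.center, rc, spec.eccentricity, spec.angle)
    mask[outer] = RINGS
    mask[inner] = CENTER
    return mask


def _paint_element(image, spec: ElementSpec, mask: np.ndarray, contrast: float) -> None:
    """Blend the element's colors over the background with the given contrast."""
    if spec.kind == "spot":
        regions = [(mask == RINGS, spec.colors[0])]
    else:
        rc, rb, ro = spec.radii
        black = _ellipse_membership(mask.shape, spec.center, rb, spec.eccentricity, spec.angle)
        regions = [
            ((mask == RINGS) & ~black, spec.colors[2]),  # orange outer ring
            ((mask == RINGS) & black, spec.colors[1]),  # black disc
            (mask == CENTER, spec.colors[0]),  # white center
        ]
    for sel, color in regions:
        image[sel] = (1.0 - contrast) * image[sel] + contrast * color


# ---------------------------------------------------------------------------
# Background
# ---------------------------------------------------------------------------

def _make_background(params: SceneParams, rng: np.random.Generator,
                     size: Optional[tuple[int, int]] = None) -> np.ndarray:
    h, w = size if size is not None else params.image_size
    base = _WING_COLOR + rng.uniform(-0.05, 0.05, size=3)
    image = np.ones((h, w, 3)) * base
    if params.background == "textured":
        noise = rng.standard_normal((h, w))
        noise = ndimage.gaussian_filter(noise, sigma=max(h, w) / 32.0)
        span = np.ptp(noise)
        if span > 0:
            noise = (noise - noise.min()) / span - 0.5
        image += params.texture_amplitude * noise[..., None]
        # vein-like dark curves: smooth vertical-ish paths of darkened pixels
        for _ in range(rng.integers(2, 5)):
            col = rng.uniform(0.1 * w, 0.9 * w)
            drift = rng.uniform(-0.3, 0.3)
            amp = rng.uniform(2.0, 8.0)
            rows = np.arange(h)
            cols = col + drift * rows + amp * np.sin(rows / h * np.pi * rng.uniform(1, 3))
            cols = np.clip(np.round(cols).astype(int), 0, w - 1)
            image[rows, cols] *= 1.0 - 0.4 * params.texture_amplitude / 0.15 * 0.5
    return np.clip(image, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Element sampling and placement
# ---------------------------------------------------------------------------

def _jitter(color: np.ndarray, amp: float, rng: np.random.Generator) -> np.ndarray:
    return np.clip(color + rng.uniform(-amp, amp, size=3), 0.0, 1.0)


def _sample_element(params: SceneParams, rng: np.random.Generator,
                    kind: Optional[str] = None) -> ElementSpec:
    """Sample one element spec with a placeholder center at the origin."""
    if kind is None:
        kind = "eyespot" if rng.random() < params.p_eyespot else "spot"
    ecc = rng.uniform(0.0, params.max_eccentricity)
    angle = rng.uniform(0.0, np.pi)
    if kind == "eyespot":
        ro = rng.uniform(*params.eyespot_outer_radius)
        rb = ro * rng.uniform(0.55, 0.75)
        rc = ro * rng.uniform(0.20, 0.34)
        subtype = "marginal" if rng.random() < params.p_marginal else "discal"
        colors = np.stack(
            [
                _jitter(_CENTER_COLOR, params.color_jitter, rng),
                _jitter(_BLACK_COLOR, params.color_jitter, rng),
                _jitter(_ORANGE_COLOR, params.color_jitter, rng),
            ]
        )
        return ElementSpec(kind, subtype, (0.0, 0.0), (rc, rb, ro), colors, ecc, angle)
    r = rng.uniform(*params.spot_radius)
    color = _jitter(_SPOT_COLORS[rng.integers(len(_SPOT_COLORS))], params.color_jitter, rng)
    return ElementSpec("spot", "none", (0.0, 0.0), (r,), color[None, :], ecc, angle)


def _place_elements(specs: list[ElementSpec], params: SceneParams,
                    rng: np.random.Generator, max_tries: int = 200) -> list[ElementSpec]:
    h, w = params.image_size
    placed: list[ElementSpec] = []
    for spec in specs:
        r = spec.outer_radius
        lo_r, hi_r = r + 1.0, h - r - 2.0
        lo_c, hi_c = r + 1.0, w - r - 2.0
        if hi_r <= lo_r or hi_c <= lo_c:
            raise ValueError(
                f"element with outer radius {r:.1f} cannot fit inside a {h}x{w} image"
            )
        for _ in range(max_tries):
            center = (rng.uniform(lo_r, hi_r), rng.uniform(lo_c, hi_c))
            if params.overlap_allowed or all(
                np.hypot(center[0] - p.center[0], center[1] - p.center[1])
                > r + p.outer_radius + 2.0
                for p in placed
            ):
                placed.append(replace(spec, center=center))
                break
        else:
            raise RuntimeError(
                f"could not place element {len(placed)} without overlap after "
                f"{max_tries} tries; lower the density or set overlap_allowed=True"
            )
    return placed


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def generate_scene(params: SceneParams) -> tuple[np.ndarray, SceneGroundTruth]:
    """Render one scene; returns the float RGB image in [0, 1] and its GT."""
    rng = np.random.default_rng(params.seed)
    image = _make_background(params, rng)
    h, w = params.image_size

    lo, hi = params.n_elements
    n = int(rng.integers(lo, hi + 1)) if hi > lo else int(lo)
    specs = _place_elements([_sample_element(params, rng) for _ in range(n)], params, rng)

    # ownership map resolves overlaps: the later element wins a pixel
    owner = np.zeros((h, w), dtype=np.int32)
    labels = np.zeros((h, w), dtype=np.uint8)
    for k, spec in enumerate(specs):
        m = rasterize_element(spec, (h, w))
        sel = m > 0
        owner[sel] = k + 1
        labels[sel] = m[sel]
        _paint_element(image, spec, m, params.contrast)

    if params.noise_sigma > 0:
        image = image + rng.normal(0.0, params.noise_sigma, size=image.shape)
    image = np.clip(image, 0.0, 1.0)

    elements, boxes, masks = [], [], []
    centers, rings = [], []
    for k, spec in enumerate(specs):
        m = np.where(owner == k + 1, labels, 0).astype(np.uint8)
        if not m.any():  # fully occluded under overlap_allowed
            continue
        label = "eyespot" if spec.kind == "eyespot" else "spot"
        elements.append(spec)
        masks.append(m)
        boxes.append(mask_to_box(m, label=label))
        centers.append(int((m == CENTER).sum()))
        rings.append(int((m == RINGS).sum()))
    gt = SceneGroundTruth(
        elements=elements,
        boxes=boxes,
        masks=masks,
        true_center_area_px=np.array(centers, dtype=float),
        true_rings_area_px=np.array(rings, dtype=float),
        px_per_mm=params.px_per_mm,
    )
    return image.astype(np.float32), gt


def generate_eyespot_crop(
    params: SceneParams, margin_factor: float = 1.25
) -> tuple[np.ndarray, np.ndarray, SceneGroundTruth]:
    """Render a square crop holding exactly one centered eyespot.

    The crop side is ``2 * round(margin_factor * r_orange) + 1`` so that with
    ``margin_factor == 1`` the outer ring is tangent to the crop border.
    Returns (crop, three-class mask, ground truth).
    """
    lo, hi = params.n_elements
    if not (lo == hi == 1):
        raise ValueError("generate_eyespot_crop requires n_elements == (1, 1)")
    rng = np.random.default_rng(params.seed)
    spec = _sample_element(params, rng, kind="eyespot")
    side = 2 * int(round(margin_factor * spec.outer_radius)) + 1
    side = max(side, 32)
    mid = float(side // 2)
    spec = replace(spec, center=(mid, mid))

    image = _make_background(params, rng, size=(side, side))
    mask = rasterize_element(spec, (side, side))
    _paint_element(image, spec, mask, params.contrast)
    if params.noise_sigma > 0:
        image = image + rng.normal(0.0, params.noise_sigma, size=image.shape)
    image = np.clip(image, 0.0, 1.0).astype(np.float32)

    gt = SceneGroundTruth(
        elements=[spec],
        boxes=[mask_to_box(mask, label="eyespot")],
        masks=[mask],
        true_center_area_px=np.array([float((mask == CENTER).sum())]),
        true_rings_area_px=np.array([float((mask == RINGS).sum())]),
        px_per_mm=params.px_per_mm,
    )
    return image, mask, gt


def generate_crop_dataset(
    n: int, params: SceneParams, seed: int, margin_factor: float = 1.25
) -> list[tuple[np.ndarray, np.ndarray, SceneGroundTruth]]:
    """Generate ``n`` independent eyespot crops from one master seed."""
    child_seeds = np.random.SeedSequence(seed).generate_state(n) & 0x7FFFFFFF
    out = []
    for s in child_seeds:
        p = replace(params, n_elements=(1, 1), seed=int(s))
        out.append(generate_eyespot_crop(p, margin_factor=margin_factor))
    return out


def generate_scene_dataset(
    n: int, params: SceneParams, seed: int
) -> list[tuple[np.ndarray, SceneGroundTruth]]:
    """Generate ``n`` independent scenes from one master seed."""
    child_seeds = np.random.SeedSequence(seed).generate_state(n) & 0x7FFFFFFF
    return [generate_scene(replace(params, seed=int(s))) for s in child_seeds]


def erase_left_half(
    image: np.ndarray, gt: SceneGroundTruth
) -> tuple[np.ndarray, SceneGroundTruth]:
    """Blank the left half of a scene, as done to un-annotated left wings.

    Columns ``[0, W // 2)`` are replaced by the per-row median of the right
    half (a background estimate).  Elements entirely inside the erased region
    are dropped from the ground truth; straddling boxes are clipped.
    """
    h, w = image.shape[:2]
    if w < 2:
        raise ValueError("image must be at least 2 pixels wide")
    half = w // 2
    out = image.copy()
    fill = np.median(image[:, half:], axis=1)  # (H, 3) per-row background color
    out[:, :half] = fill[:, None, :]

    elements, boxes, masks, centers, rings = [], [], [], [], []
    for spec, mask in zip(gt.elements, gt.masks):
        m = mask.copy()
        m[:, :half] = 0
        if not m.any():
            continue
        elements.append(spec)
        masks.append(m)
        boxes.append(mask_to_box(m, label="eyespot" if spec.kind == "eyespot" else "spot"))
        centers.append(float((m == CENTER).sum()))
        rings.append(float((m == RINGS).sum()))
    gt2 = SceneGroundTruth(
        elements=elements,
        boxes=boxes,
        masks=masks,
        true_center_area_px=np.array(centers, dtype=float),
        true_rings_area_px=np.array(rings, dtype=float),
        px_per_mm=gt.px_per_mm,
    )
    return out, gt2


def split_dataset(
    items: Sequence,
    fractions: Optional[Sequence[float]] = None,
    seed: int = 0,
    counts: Optional[Sequence[int]] = None,
) -> list[list]:
    """Disjoint, exhaustive, seed-reproducible split at the item level.

    With ``fractions`` each split gets ``floor(f * n)`` items except the last,
    which takes the remainder.  ``counts`` gives explicit sizes instead (they
    must sum to ``len(items)``).
    """
    n = len(items)
    if n == 0:
        raise ValueError("cannot split an empty manifest")
    if counts is None:
        if fractions is None:
            raise ValueError("provide fractions or counts")
        if abs(sum(fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        counts = [int(np.floor(f * n)) for f in fractions[:-1]]
        counts.append(n - sum(counts))
    elif sum(counts) != n:
        raise ValueError(f"counts {counts} do not sum to {n}")
    order = np.random.default_rng(seed).permutation(n)
    splits, start = [], 0
    for c in counts:
        splits.append([items[i] for i in order[start : start + c]])
        start += c
    return splits


def write_scene_dataset(out_dir, n: int, params: SceneParams, seed: int,
                        split_fractions: Sequence[float] = (0.9, 0.1)) -> "Path":
    """Render scenes to disk (PNG + VOC XML + mask PNG) with a CSV manifest.

    Returns the manifest path.  Splits are named train/test in order.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scenes = generate_scene_dataset(n, params, seed)
    idx_splits = split_dataset(list(range(n)), fractions=split_fractions, seed=seed)
    split_names = ["train", "test", "val"][: len(idx_splits)]
    split_of = {}
    for name, idxs in zip(split_names, idx_splits):
        for i in idxs:
            split_of[i] = name
    rows = []
    for i, (image, gt) in enumerate(scenes):
        stem = f"scene_{i:04d}"
        img_path = out_dir / f"{stem}.png"
        xml_path = out_dir / f"{stem}.xml"
        mask_path = out_dir / f"{stem}_mask.png"
        anio.write_image_png(img_path, image)
        h, w = image.shape[:2]
        anio.write_voc_xml(xml_path, anio.ImageMeta(img_path.name, w, h), gt.boxes)
        anio.write_mask_png(mask_path, gt.combined_mask((h, w)))
        rows.append(
            {
                "image_path": img_path.name,
                "xml_path": xml_path.name,
                "mask_path": mask_path.name,
                "split": split_of[i],
                "seed": seed,
            }
        )
    manifest = out_dir / "manifest.csv"
    anio.write_manifest(manifest, rows)
    return manifest
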