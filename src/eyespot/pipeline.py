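"""End-to-end orchestration: simulate → train → detect → measure → evaluate.

A single YAML config drives the whole run.  Every stage writes its outputs
under ``out_dir`` (models, VOC XML detections, a measurements CSV, a JSON
report) and derives its random seed from the global seed by a fixed offset,
so stages are individually reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import annotations as anio
from . import detector as det
from . import measurer, metrics, segmenter
from .nn import TrainConfig
from .synthetic import (
    DEFAULT_PX_PER_MM,
    SceneParams,
    generate_crop_dataset,
    generate_scene_dataset,
    split_dataset,
)

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

# per-stage seed offsets fanned out from the global seed
_SEED_SCENES, _SEED_CROPS, _SEED_DET, _SEED_SEG = 11, 23, 37, 53


@dataclass
class PipelineConfig:
    out_dir: str = "eyespot_run"
    mode: str = "full"  # "full" | "simulate-only"
    seed: int = 0
    px_per_mm: float = DEFAULT_PX_PER_MM
    scheme: str = "two_class"
    n_scenes: int = 60
    n_crops: int = 40
    margin_factor: float = 1.25
    resume: bool = False  # reuse existing model checkpoints in out_dir
    logging_level: str = "INFO"
    schema_version: int = SCHEMA_VERSION
    scene: SceneParams = field(default_factory=SceneParams)
    detector: det.DetectorConfig = field(default_factory=det.DetectorConfig)
    segmenter: segmenter.SegmenterConfig = field(default_factory=segmenter.SegmenterConfig)

    def __post_init__(self) -> None:
        if self.mode not in ("full", "simulate-only"):
            raise ValueError("mode must be 'full' or 'simulate-only'")
        det.ClassScheme(self.scheme)  # validates


def _build_nested(cls, data: dict, errors: list, prefix: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in fields:
            errors.append(f"{prefix}{key}")
            continue
        if isinstance(value, dict):
            sub_cls = {
                "scene": SceneParams,
                "detector": det.DetectorConfig,
                "segmenter": segmenter.SegmenterConfig,
                "train": TrainConfig,
            }.get(key)
            if sub_cls is None:
                errors.append(f"{prefix}{key}")
                continue
            kwargs[key] = _build_nested(sub_cls, value, errors, f"{prefix}{key}.")
        elif isinstance(value, list):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    if errors:
        return None
    return cls(**kwargs)


def validate_config(path) -> PipelineConfig:
    """Load and normalize a YAML pipeline config.

    Unknown keys are rejected (all of them reported at once); missing keys
    take the defaults (px_per_mm 28.944, NMS 0.3, Adam 1e-4, batch 8, ...).
    An empty file yields the all-defaults config.
    """
    with open(str(path)) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    errors: list[str] = []
    cfg = _build_nested(PipelineConfig, data, errors, "")
    if errors:
        raise ValueError(f"{path}: unknown config keys: {', '.join(sorted(errors))}")
    logger.info("normalized config: %s", cfg)
    return cfg


def run_all(config: PipelineConfig) -> dict:
    """Run the full pipeline; returns a dict of artifact paths and metrics."""
    logging.basicConfig(level=getattr(logging, config.logging_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scheme = det.ClassScheme(config.scheme)
    report: dict = {"schema_version": config.schema_version, "seed": config.seed}

    # --- stage 1: simulate -------------------------------------------------
    scenes = generate_scene_dataset(config.n_scenes, config.scene, config.seed + _SEED_SCENES)
    crop_params = replace(config.scene, n_elements=(1, 1), px_per_mm=config.px_per_mm)
    crops = generate_crop_dataset(config.n_crops, crop_params, config.seed + _SEED_CROPS)
    scene_splits = split_dataset(scenes, fractions=(0.9, 0.1), seed=config.seed + _SEED_SCENES)
    crop_splits = split_dataset(crops, fractions=(0.8, 0.2), seed=config.seed + _SEED_CROPS)
    report["n_scenes_train"], report["n_scenes_test"] = map(len, scene_splits)
    report["n_crops_train"], report["n_crops_test"] = map(len, crop_splits)
    if config.mode == "simulate-only":
        data_dir = out / "data"
        data_dir.mkdir(exist_ok=True)
        for i, (img, gt) in enumerate(scenes):
            anio.write_image_png(data_dir / f"scene_{i:04d}.png", img)
            h, w = img.shape[:2]
            anio.write_voc_xml(
                data_dir / f"scene_{i:04d}.xml",
                anio.ImageMeta(f"scene_{i:04d}.png", w, h),
                gt.boxes,
            )
            anio.write_mask_png(data_dir / f"scene_{i:04d}_mask.png", gt.combined_mask((h, w)))
        report["data_dir"] = str(data_dir)
        (out / "report.json").write_text(json.dumps(report, indent=2))
        return report

    # --- stage 2: train detector -------------------------------------------
    det_cfg = replace(
        config.detector, train=replace(config.detector.train, seed=config.seed + _SEED_DET)
    )
    train_pairs = [(img, scheme.map_gt_boxes(gt)) for img, gt in scene_splits[0]]
    test_pairs = [(img, scheme.map_gt_boxes(gt)) for img, gt in scene_splits[1]]
    det_ckpt = out / "detector.npz"
    try:
        if config.resume and det_ckpt.exists():
            model_det = det.load_detector(det_ckpt)
            report["detector"] = {"resumed": True, "checkpoint": str(det_ckpt)}
        else:
            model_det, det_log = det.train_detector(train_pairs, test_pairs, scheme, det_cfg)
            det.save_detector(det_ckpt, model_det)
            report["detector"] = {
                "epochs": det_log.n_epochs,
                "stop_reason": det_log.stop_reason,
                "checkpoint": str(det_ckpt),
            }
    except Exception as exc:
        raise RuntimeError(f"stage train-detector failed: {exc}") from exc

    # --- stage 3: train segmenter -------------------------------------------
    seg_cfg = replace(
        config.segmenter, train=replace(config.segmenter.train, seed=config.seed + _SEED_SEG)
    )
    tr_crops = [c for c, _, _ in crop_splits[0]]
    tr_masks = [m for _, m, _ in crop_splits[0]]
    te_crops = [c for c, _, _ in crop_splits[1]]
    te_masks = [m for _, m, _ in crop_splits[1]]
    if seg_cfg.n_classes == 2:
        tr_masks = [segmenter.to_two_class(m) for m in tr_masks]
        te_masks = [segmenter.to_two_class(m) for m in te_masks]
    seg_ckpt = out / "segmenter.npz"
    try:
        if config.resume and seg_ckpt.exists():
            model_seg = segmenter.load_segmenter(seg_ckpt)
            report["segmenter"] = {"resumed": True, "checkpoint": str(seg_ckpt)}
        else:
            model_seg, seg_log = segmenter.train_segmenter(
                tr_crops, tr_masks, seg_cfg, te_crops, te_masks
            )
            segmenter.save_segmenter(seg_ckpt, model_seg)
            report["segmenter"] = {
                "epochs": seg_log.n_epochs,
                "stop_reason": seg_log.stop_reason,
                "checkpoint": str(seg_ckpt),
            }
    except Exception as exc:
        raise RuntimeError(f"stage train-segmenter failed: {exc}") from exc

    # --- stage 4: detect + measure on held-out scenes ------------------------
    det_dir = out / "detections"
    det_dir.mkdir(exist_ok=True)
    all_dets, all_gts, records = [], [], []
    for i, (img, gt) in enumerate(scene_splits[1]):
        dets = det.nms(det.detect(model_det, img), det_cfg.nms_iou_threshold)
        h, w = img.shape[:2]
        anio.write_voc_xml(
            det_dir / f"test_{i:04d}.xml", anio.ImageMeta(f"test_{i:04d}.png", w, h), dets
        )
        all_dets.append(dets)
        all_gts.append(scheme.map_gt_boxes(gt))
        records.extend(
            measurer.run_measurement_pipeline(
                img, dets, model_seg, config.px_per_mm, config.margin_factor,
                image_id=f"test_{i:04d}",
            )
        )
    anio.write_measurements_csv(out / "measurements.csv", records)
    report["n_detections"] = int(sum(len(d) for d in all_dets))
    report["measurements_csv"] = str(out / "measurements.csv")

    # --- stage 5: evaluate ---------------------------------------------------
    ap = metrics.ap_per_class(all_dets, all_gts)
    ap50 = metrics.ap_per_class(all_dets, all_gts, iou_thresholds=[0.5])
    report["detection"] = {
        "ap_per_class": ap,
        "mAP": metrics.mean_ap(ap),
        "ap50_per_class": ap50,
        "mAP50": metrics.mean_ap(ap50),
    }
    accs, f1s, ious = [], [], []
    manual_tot, auto_tot = [], []
    for crop, mask, gt in crop_splits[1]:
        if seg_cfg.n_classes == 2:
            mask = segmenter.to_two_class(mask)
        resized = segmenter.prepare_crops([crop], [mask], seg_cfg.input_size)
        pred = segmenter.segment(model_seg, np.moveaxis(resized[0][0], 0, -1))
        a, f, i_ = metrics.segmentation_metrics(pred, resized[1][0], seg_cfg.n_classes)
        accs.append(a)
        f1s.append(f)
        ious.append(i_)
        recs = measurer.run_measurement_pipeline(
            crop, gt.boxes, model_seg, config.px_per_mm, config.margin_factor
        )
        if recs:
            manual_tot.append(gt.true_total_area_px[0] / config.px_per_mm**2)
            auto_tot.append(recs[0].total_area_mm2)
    report["segmentation"] = {
        "accuracy": float(np.mean(accs)),
        "macro_f1": float(np.mean(f1s)),
        "mean_iou": float(np.mean(ious)),
    }
    if manual_tot:
        report["areas_total"] = metrics.area_error_stats(manual_tot, auto_tot).to_dict()
    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report
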