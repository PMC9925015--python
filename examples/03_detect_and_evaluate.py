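"""Train the mini-detector on synthetic scenes and score it with
COCO-style average precision.

Run:  python examples/03_detect_and_evaluate.py   (~2-3 minutes on CPU)
"""

from eyespot.detector import ClassScheme, DetectorConfig, detect, nms, train_detector
from eyespot.metrics import ap_per_class, average_precision, mean_ap
from eyespot.nn import TrainConfig
from eyespot.synthetic import SceneParams, generate_scene_dataset, split_dataset

params = SceneParams(image_size=(128, 128), n_elements=(1, 2), contrast=0.9,
                     eyespot_outer_radius=(10.0, 16.0), spot_radius=(6.0, 9.0))
scenes = generate_scene_dataset(60, params, seed=3)
train, test = split_dataset(scenes, fractions=(0.9, 0.1), seed=3)

scheme = ClassScheme("one_class_all")
cfg = DetectorConfig(
    input_size=128, anchor_scales=(14.0, 22.0, 32.0),
    train=TrainConfig(lr=2e-3, max_epochs=30, patience=30, seed=0),
)
pairs_tr = [(img, scheme.map_gt_boxes(gt)) for img, gt in train]
pairs_te = [(img, scheme.map_gt_boxes(gt)) for img, gt in test]
model, log = train_detector(pairs_tr, pairs_te, scheme, cfg)
print(f"trained {log.n_epochs} epochs ({log.stop_reason})")

dets = [nms(detect(model, img, score_threshold=0.3), cfg.nms_iou_threshold)
        for img, _ in pairs_te]
gts = [g for _, g in pairs_te]
ap50 = average_precision(dets, gts, label="element", iou_thresholds=[0.5])
per_class = ap_per_class(dets, gts)
print(f"AP@0.5 = {ap50:.3f}   AP@[.5:.95] = {per_class['element']:.3f}   "
      f"mAP = {mean_ap(per_class):.3f}")
print(
    "AP is the area under the precision-recall curve; AP@[.5:.95] averages it\n"
    "over ten IoU thresholds, so it also rewards tight box localization."
)
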