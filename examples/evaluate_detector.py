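"""Scoring a detector with per-class AP at IoU 0.5 and mAP50.

Uses the generator's ground-truth annotations as the reference, and a
degraded copy (some boxes shifted, some dropped, one false positive per
frame) as the "detector output" to show a non-trivial score.
"""

import numpy as np

from gaitcontext import (
    AnnotationRecord,
    BoundingBox,
    SceneConfig,
    evaluate_map50,
    generate_scene_sequence,
    load_taxonomy,
)

tax = load_taxonomy("builtin")
_, _, truth = generate_scene_sequence(SceneConfig(n_frames=40, seed=13), tax)
rng = np.random.default_rng(13)

preds = []
for rec in truth.annotations:
    boxes, confs = [], []
    for name, b in rec.boxes:
        if rng.random() < 0.15:  # miss 15% of objects
            continue
        dx = float(rng.normal(0, 6))
        boxes.append((name, BoundingBox(b.x_min + dx, b.y_min, b.x_max + dx, b.y_max)))
        confs.append(float(rng.uniform(0.5, 1.0)))
    boxes.append(("Chair", BoundingBox(5, 5, 40, 40)))  # spurious detection
    confs.append(float(rng.uniform(0.1, 0.4)))
    preds.append(AnnotationRecord(rec.image_id, boxes, confidences=confs))

result = evaluate_map50(preds, truth.annotations)
for cls, ap in sorted(result.per_class_ap.items()):
    print(f"AP50[{cls:16s}] = {ap:.3f}")
print(f"mAP50 = {result.map50:.3f}")

# A prediction counts as correct when its IoU with an unmatched truth box
# of the same class reaches 0.5; AP integrates precision over recall and
# mAP50 averages over the classes present in the ground truth.
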