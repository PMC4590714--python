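"""Train, calibrate and run the full three-stage detector.

Trains the three SVMs on synthetic scenes, calibrates the two decision
thresholds on a disjoint validation suite, evaluates on held-out
scenes, and prints stage-by-stage metrics.  Takes a few minutes.
"""

from seghog import (
    detect, detection_metrics, generate_scene_suite, match_detections,
    train_all,
)
from seghog.evaluation import DetectionCounts
from seghog.pipeline import calibrate_thresholds

train = generate_scene_suite(16, seed=100)
val = generate_scene_suite(8, seed=150)
test = generate_scene_suite(20, seed=200)

models = train_all([s[0] for s in train], [s[1] for s in train], seed=0)
config = calibrate_thresholds(models, [s[0] for s in val], [s[1] for s in val])
print(f"calibrated thresholds: prescreen {config.prescreen.theta:.2f}, "
      f"classification {config.classification.theta:.2f}")

TP = FP = FN = 0
preTP = preFP = preFN = 0
for image, truth in test:
    dets = detect(image, models, config)
    polys = [g.polygon() for g in truth.glomeruli]
    c = match_detections([d for d in dets if d.accepted], polys)
    cp = match_detections([(d.center, d.prescreen_score) for d in dets], polys)
    TP += c.TPG; FP += c.FPG; FN += c.FNG
    preTP += cp.TPG; preFP += cp.FPG; preFN += cp.FNG

pre = detection_metrics(DetectionCounts(preTP, preFP, preFN))
fin = detection_metrics(DetectionCounts(TP, FP, FN))
print(f"pre-screening : P={pre[0]:.3f} R={pre[1]:.3f} F={pre[2]:.3f} "
      f"({preFP} false positives)")
print(f"classification: P={fin[0]:.3f} R={fin[1]:.3f} F={fin[2]:.3f} "
      f"({FP} false positives)")
# The S-HOG stage removes a sizable fraction of pre-screening false
# positives while keeping (almost) all true glomeruli.
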