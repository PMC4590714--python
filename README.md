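# seghog — glomerulus detection with Segmental HOG

`seghog` detects glomeruli — the kidney's roughly spherical filtration
units — in bright-field microscopy images of immunostained kidney
sections.  Heterogeneous staining, variable size and deformation make
rigid sliding-window descriptors produce many false positives; this
package implements a three-stage detector whose final descriptor adapts
its blocks to each candidate's estimated boundary:

1. **Pre-screening** — a 200×200 sliding window scored by a linear SVM
   on rectangular HOG features (512-dim), thinned by non-maximal
   suppression;
2. **Segmentation** — m = 36 rays are cast from each candidate center,
   a boundary-likeliness SVM scores n = 22 samples per ray, and the
   boundary polygon solves

       max Σᵢ Lᵢ(pᵢ)   s.t.  |pᵢ − pᵢ₊₁| ≤ ς  (cyclically),

   exactly, via a divide & conquer dynamic program (DCDP): a chain
   (Viterbi) DP on the wrap-relaxed problem inside a branch-and-bound
   over endpoint intervals, provably optimal with at most 2n−1 DP calls;
3. **Classification** — the Segmental HOG (S-HOG) descriptor (3 radial
   zones × 8 sectors fitted to the estimated boundary, 216-dim) makes
   the final accept/reject decision.

The package also ships the EDP and brute-force reference solvers, an
MPLP / MPLP+ dual coordinate-descent baseline (the MAP-inference view of
the same problem), a synthetic kidney-section generator with exact
ground truth (so the full pipeline is trainable and verifiable without
real slides), and detection/segmentation metrics (TPG/FPG/FNG and
TPA/FPA/FNA with precision, recall, F-measure).

## Worked example

```python
import numpy as np
from seghog import (
    generate_scene_suite, train_all, detect,
    match_detections, detection_metrics,
)
from seghog.pipeline import calibrate_thresholds
from seghog.evaluation import DetectionCounts

train = generate_scene_suite(16, seed=100)   # synthetic annotated sections
val   = generate_scene_suite(8,  seed=150)
test  = generate_scene_suite(20, seed=200)

models = train_all([s[0] for s in train], [s[1] for s in train], seed=0)
config = calibrate_thresholds(models, [s[0] for s in val], [s[1] for s in val])

TP = FP = FN = 0
for image, truth in test:
    detections = [d for d in detect(image, models, config) if d.accepted]
    c = match_detections(detections, [g.polygon() for g in truth.glomeruli])
    TP, FP, FN = TP + c.TPG, FP + c.FPG, FN + c.FNG
precision, recall, f = detection_metrics(DetectionCounts(TP, FP, FN))
print(f"P={precision:.3f} R={recall:.3f} F={f:.3f}")
```

This prints `P=0.708 R=1.000 F=0.829` — precision, recall and F-measure of
the calibrated detector over 80 synthetic glomeruli in 20 held-out
scenes: every true glomerulus is found, and roughly seven in ten
accepted detections are real (the remainder are vessel-like
distractors).  The classification stage is what earns the precision: on
the same scenes the pre-screening stage alone reaches precision 0.645
at the same recall, and the S-HOG classifier removes a quarter of its
false positives without losing a single true one.

Each `Detection` carries the candidate center, the estimated boundary
polygon (one vertex per ray, smooth by construction), the
classification score, and the accept flag.  `examples/` contains one
short script per capability (solver, descriptors, generator, full
pipeline, benchmark).

A thin CLI wraps the library for shell use:

```bash
seghog simulate --n-scenes 5 --seed 0 --out scenes/
seghog simulate --n-scenes 3 --seed 1 --out val/
seghog train --images scenes/ --val-images val/ --seed 0 --out models.pkl
seghog detect --image scenes/scene_000.png --models models.pkl --out det.json
seghog eval --detections det.json --truth scenes/scene_000.truth.json --out metrics.csv
seghog bench --seed 0 --out bench.csv
```

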