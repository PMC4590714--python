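"""Detection and segmentation scoring.

Object-level counts: a true positive glomerulus (TPG) is a detection
matched one-to-one to an annotated glomerulus, a false positive (FPG) an
unmatched detection, a false negative (FNG) an unmatched annotation.
Pixel-level counts for a single object: TPA is the intersection of true
and estimated areas, FPA the estimated-minus-true area, FNA the
true-minus-estimated area.  In both cases

    precision = TP / (TP + FP),  recall = TP / (TP + FN),
    F = harmonic mean of precision and recall,

with the 0/0 convention that an undefined ratio is 0 (a warning is
logged).

The matching rule is greedy: detections are processed in descending
score order and matched to the first still-unmatched truth object whose
polygon contains the detection center (``criterion='center'``), or whose
center lies within ``max_distance`` (``criterion='distance'``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from matplotlib.path import Path

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectionCounts:
    TPG: int
    FPG: int
    FNG: int


@dataclass(frozen=True)
class PixelCounts:
    TPA: int
    FPA: int
    FNA: int


def _safe_ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        logger.warning("%s undefined (0/0); reporting 0", what)
        return 0.0
    return num / den


def _prf(tp: float, fp: float, fn: float) -> tuple[float, float, float]:
    precision = _safe_ratio(tp, tp + fp, "precision")
    recall = _safe_ratio(tp, tp + fn, "recall")
    f = _safe_ratio(2 * precision * recall, precision + recall, "F-measure")
    return precision, recall, f


def match_detections(
    detections,
    truth_polygons: list[np.ndarray],
    criterion: str = "center",
    max_distance: float = 50.0,
) -> DetectionCounts:
    """Greedily match accepted detections to truth objects, one-to-one.

    Parameters
    ----------
    detections : sequence
        Accepted detections; each needs ``center`` and ``score``
        attributes (or ``(center, score)`` pairs).
    truth_polygons : list of (k, 2) arrays
        One closed boundary polygon per annotated glomerulus.
    criterion : {'center', 'distance'}
        'center': a detection matches a truth object iff its center lies
        inside the truth polygon.  'distance': iff the detection center
        is within ``max_distance`` of the truth polygon centroid.
    """
    items = []
    for d in detections:
        if hasattr(d, "center"):
            center, score = d.center, d.score
        else:
            center, score = d
        items.append((np.asarray(center, dtype=float), float(score)))
    # deterministic order: descending score, then coordinates
    items.sort(key=lambda t: (-t[1], t[0][0], t[0][1]))

    paths = [Path(np.asarray(poly, dtype=float)) for poly in truth_polygons]
    centroids = [np.asarray(poly, dtype=float).mean(axis=0) for poly in truth_polygons]
    matched = [False] * len(truth_polygons)
    tpg = fpg = 0
    for center, _score in items:
        hit = None
        for j in range(len(paths)):
            if matched[j]:
                continue
            if criterion == "center":
                # Path vertices are (row, col); query in the same order
                ok = paths[j].contains_point((center[0], center[1]))
            elif criterion == "distance":
                ok = np.linalg.norm(center - centroids[j]) <= max_distance
            else:
                raise ValueError(f"unknown criterion {criterion!r}")
            if ok:
                hit = j
                break
        if hit is None:
            fpg += 1
        else:
            matched[hit] = True
            tpg += 1
    fng = matched.count(False)
    return DetectionCounts(TPG=tpg, FPG=fpg, FNG=fng)


def detection_metrics(counts: DetectionCounts) -> tuple[float, float, float]:
    """(precision, recall, F-measure) from object-level counts."""
    return _prf(counts.TPG, counts.FPG, counts.FNG)


def segmentation_metrics(
    pred_mask: np.ndarray, true_mask: np.ndarray
) -> tuple[float, float, float, PixelCounts]:
    """(precision, recall, F, pixel counts) for one predicted area."""
    pred = np.asarray(pred_mask, dtype=bool)
    true = np.asarray(true_mask, dtype=bool)
    if pred.shape != true.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {true.shape}")
    tpa = int(np.count_nonzero(pred & true))
    fpa = int(np.count_nonzero(pred & ~true))
    fna = int(np.count_nonzero(~pred & true))
    counts = PixelCounts(TPA=tpa, FPA=fpa, FNA=fna)
    p, r, f = _prf(tpa, fpa, fna)
    return p, r, f, counts
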