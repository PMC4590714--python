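"""The three-stage glomerulus detector.

Stage 1 (pre-screening) slides a 200x200 window over the image, scores
each placement with a linear SVM on R-HOG features, thresholds the score
and applies greedy non-maximal suppression; surviving window centers are
the candidate glomeruli.  Stage 2 (segmentation) casts 36 rays from each
candidate center, scores every ray sample with a linear SVM on the
ray-window descriptor (the boundary likeliness table L), and solves the
cyclic smoothness-constrained maximization exactly with DCDP to obtain
the boundary polygon.  Stage 3 (classification) extracts the S-HOG
descriptor on the estimated boundary and accepts the candidate iff its
linear-SVM score exceeds the classification threshold.

Each stage has its own SVM; all three are trained on examples derived
from annotated images (here: synthetic scenes with exact truth).  All
sampling is driven by explicit seeds, so a fixed input yields identical
detections on every run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import LinearSVC

from .descriptors import (
    RayWindowConfig,
    RHogConfig,
    RhogIntegral,
    ShogConfig,
    ray_window_table,
    shog_descriptor,
)
from .imaging import GradientField, as_gray, compute_gradient_field
from .rays import RayConfig, build_ray_system, polygon_from_solution
from .solver import BoundaryProblem, dcdp
from .synthetic import SceneTruth

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class PrescreenConfig:
    rhog: RHogConfig = field(default_factory=RHogConfig)
    stride: int = 20
    C: float = 10.0
    theta: float = 2.0
    nms_radius: float = 60.0
    neg_exclusion: float = 100.0   # min distance of negative-window centers to truths
    neg_ratio: float = 3.0         # negatives per positive when building training data


@dataclass(frozen=True)
class SegmentationConfig:
    rays: RayConfig = field(default_factory=RayConfig)
    window: RayWindowConfig = field(default_factory=RayWindowConfig)
    C: float = 10.0
    varsigma: int = 1
    scheme: str = "adap"
    neg_margin: int = 2            # negative samples at >= this many steps from truth


@dataclass(frozen=True)
class ClassificationConfig:
    shog: ShogConfig = field(default_factory=ShogConfig)
    C: float = 10.0
    theta: float = -1.5


@dataclass(frozen=True)
class DetectionConfig:
    prescreen: PrescreenConfig = field(default_factory=PrescreenConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    classification: ClassificationConfig = field(default_factory=ClassificationConfig)
    min_diameter: float = 50.0


# --------------------------------------------------------------------------
# linear SVM


@dataclass(frozen=True)
class SvmModel:
    """Linear decision function score(x) = w . x + b."""

    weights: np.ndarray
    bias: float
    C: float

    def score(self, X: np.ndarray) -> np.ndarray | float:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            return float(X @ self.weights + self.bias)
        return X @ self.weights + self.bias


def train_linear_svm(
    features: np.ndarray, labels: np.ndarray, C: float = 10.0, seed: int = 0
) -> SvmModel:
    """Fit an L2-regularized hinge-loss linear SVM (deterministic per seed)."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if features.ndim != 2 or features.shape[0] != labels.shape[0]:
        raise ValueError("features must be (n_samples, n_features) matching labels")
    if len(np.unique(labels)) < 2:
        raise ValueError("training set must contain both classes")
    clf = LinearSVC(C=C, loss="hinge", max_iter=200000, tol=1e-6, random_state=seed)
    clf.fit(features, labels)
    return SvmModel(weights=clf.coef_.ravel().copy(), bias=float(clf.intercept_[0]), C=C)


# --------------------------------------------------------------------------
# training-set construction


def _eligible_glomeruli(truth: SceneTruth, min_diameter: float):
    return [g for g in truth.glomeruli if g.diameter >= min_diameter]


def _window_top(center: np.ndarray, window: int) -> np.ndarray:
    return np.round(np.asarray(center) - window / 2.0).astype(int)


def _random_negative_centers(
    shape: tuple[int, int],
    truth_centers: np.ndarray,
    n: int,
    window: int,
    exclusion: float,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    H, W = shape
    half = window / 2.0
    out: list[np.ndarray] = []
    attempts = 0
    while len(out) < n and attempts < 200 * max(n, 1):
        attempts += 1
        c = rng.uniform([half, half], [H - half, W - half])
        if truth_centers.size and np.min(
            np.linalg.norm(truth_centers - c, axis=1)
        ) <= exclusion:
            continue
        out.append(c)
    return out


def build_prescreen_training_set(
    images: list[np.ndarray],
    truths: list[SceneTruth],
    config: DetectionConfig | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """R-HOG training examples for the pre-screening SVM.

    Positives are windows centered on each annotated glomerulus of
    diameter >= ``min_diameter``; negatives are windows at random
    locations whose centers are farther than the exclusion radius from
    every annotated center.  Returns (features, labels in {-1, +1}).
    """
    config = config or DetectionConfig()
    ps = config.prescreen
    w = ps.rhog.window
    rng = np.random.default_rng(seed)
    feats, labels = [], []
    for image, truth in zip(images, truths):
        gray = as_gray(image)
        if gray.shape[0] < w or gray.shape[1] < w:
            logger.warning("image %s too small for %dx%d window; skipped",
                           gray.shape, w, w)
            continue
        extractor = RhogIntegral(compute_gradient_field(gray), ps.rhog)
        pos_centers = []
        for g in _eligible_glomeruli(truth, config.min_diameter):
            top = _window_top(np.asarray(g.center), w)
            if np.any(top < 0) or top[0] + w > gray.shape[0] or top[1] + w > gray.shape[1]:
                logger.warning("glomerulus at %s too close to border; skipped", g.center)
                continue
            feats.append(extractor.descriptor(tuple(top)))
            labels.append(1)
            pos_centers.append(g.center)
        n_neg = int(round(ps.neg_ratio * len(pos_centers)))
        for c in _random_negative_centers(
            gray.shape, truth.centers, n_neg, w, ps.neg_exclusion, rng
        ):
            feats.append(extractor.descriptor(tuple(_window_top(c, w))))
            labels.append(-1)
    return np.asarray(feats), np.asarray(labels)


def build_boundary_training_set(
    images: list[np.ndarray],
    truths: list[SceneTruth],
    config: DetectionConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Ray-window examples for the boundary-likeliness SVM.

    For each annotated glomerulus, rays are cast from its center; on each
    ray the sample nearest the true boundary crossing is a positive and
    samples at least ``neg_margin`` steps away are negatives.  Rays whose
    true crossing lies outside the sampled radial range are skipped.
    """
    config = config or DetectionConfig()
    seg = config.segmentation
    rc = seg.rays
    r_lo, r_hi = rc.inner_offset, rc.inner_offset + rc.segment_length
    feats, labels = [], []
    for image, truth in zip(images, truths):
        gray = as_gray(image)
        fld = compute_gradient_field(gray)
        for g in _eligible_glomeruli(truth, config.min_diameter):
            rays = build_ray_system(g.center, rc)
            table = ray_window_table(fld, rays, seg.window)
            for i in range(1, rays.m + 1):
                r_true = float(g.radius_at(rays.angle(i)))
                if not (r_lo <= r_true <= r_hi):
                    logger.warning("ray %d of glomerulus at %s: true boundary at "
                                   "%.1f px outside sampled range; skipped",
                                   i, g.center, r_true)
                    continue
                p_pos = 1 + int(round((r_true - rc.inner_offset) / rc.step))
                p_pos = min(max(p_pos, 1), rays.n)
                feats.append(table[i - 1, p_pos - 1])
                labels.append(1)
                for p in range(1, rays.n + 1):
                    if abs(p - p_pos) >= seg.neg_margin:
                        feats.append(table[i - 1, p - 1])
                        labels.append(-1)
    return np.asarray(feats), np.asarray(labels)


def build_classification_training_set(
    images: list[np.ndarray],
    truths: list[SceneTruth],
    boundary_svm: SvmModel,
    config: DetectionConfig | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """S-HOG examples for the classification SVM.

    Windows are the pre-screening positives (annotated centers) and
    seeded random negatives; for *both* classes the boundary is estimated
    by the segmentation stage (not taken from the truth) and the S-HOG
    descriptor is extracted on that estimate.
    """
    config = config or DetectionConfig()
    rng = np.random.default_rng(seed)
    w = config.prescreen.rhog.window
    feats, labels = [], []
    for image, truth in zip(images, truths):
        gray = as_gray(image)
        fld = compute_gradient_field(gray)
        pos_centers = [g.center for g in _eligible_glomeruli(truth, config.min_diameter)]
        n_neg = int(round(config.prescreen.neg_ratio * len(pos_centers)))
        neg_centers = _random_negative_centers(
            gray.shape, truth.centers, n_neg, w,
            config.prescreen.neg_exclusion, rng,
        )
        for center, label in [(c, 1) for c in pos_centers] + [
            (c, -1) for c in neg_centers
        ]:
            polygon, rays = segment_candidate(fld, center, boundary_svm, config)
            feats.append(shog_descriptor(fld, rays, polygon, config.classification.shog))
            labels.append(label)
    return np.asarray(feats), np.asarray(labels)


# --------------------------------------------------------------------------
# detection stages


@dataclass(frozen=True)
class Candidate:
    center: np.ndarray
    score: float


@dataclass(frozen=True)
class Detection:
    """One candidate with its estimated boundary and classification verdict."""

    center: np.ndarray
    polygon: np.ndarray
    score: float
    accepted: bool
    prescreen_score: float = float("nan")


def prescreen(
    image: np.ndarray, svm: SvmModel, config: DetectionConfig | None = None
) -> list[Candidate]:
    """Sliding-window R-HOG scoring + thresholding + greedy NMS.

    Windows are placed on a ``stride`` grid; windows scoring above
    ``theta`` are kept and suppressed greedily: candidates are visited in
    descending score order, each accepted candidate removes all
    not-yet-accepted ones within ``nms_radius`` of its center.
    """
    config = config or DetectionConfig()
    ps = config.prescreen
    w = ps.rhog.window
    gray = as_gray(image)
    if gray.shape[0] < w or gray.shape[1] < w:
        logger.warning("image %s smaller than the %dx%d window", gray.shape, w, w)
        return []
    extractor = RhogIntegral(compute_gradient_field(gray), ps.rhog)
    tops_r = np.arange(0, gray.shape[0] - w + 1, ps.stride)
    tops_c = np.arange(0, gray.shape[1] - w + 1, ps.stride)
    rr, cc = np.meshgrid(tops_r, tops_c, indexing="ij")
    tops = np.stack([rr.ravel(), cc.ravel()], axis=1)
    descs = extractor.descriptors(tops)
    scores = svm.score(descs)
    # a window with no gradient content at all cannot contain an object;
    # its score would be the bare bias, which is meaningless
    keep = (scores > ps.theta) & (np.abs(descs).sum(axis=1) > 0)
    tops, scores = tops[keep], scores[keep]
    centers = tops + w / 2.0
    # greedy NMS, deterministic tie-break by coordinates
    order = np.lexsort((centers[:, 1], centers[:, 0], -scores))
    accepted: list[Candidate] = []
    suppressed = np.zeros(len(order), dtype=bool)
    for a in range(len(order)):
        ia = order[a]
        if suppressed[a]:
            continue
        accepted.append(Candidate(center=centers[ia], score=float(scores[ia])))
        d = np.linalg.norm(centers[order] - centers[ia], axis=1)
        suppressed |= d <= ps.nms_radius
    return accepted


def boundary_likeliness_table(
    fld: GradientField, rays, svm: SvmModel, window: RayWindowConfig
) -> np.ndarray:
    """L[i, p] = SVM score of the ray-window descriptor at sample (i, p)."""
    table = ray_window_table(fld, rays, window)
    return table @ svm.weights + svm.bias


def segment_candidate(
    image: np.ndarray | GradientField,
    center: tuple[float, float],
    boundary_svm: SvmModel,
    config: DetectionConfig | None = None,
):
    """Estimate the boundary polygon of a candidate centered at ``center``.

    Builds the ray system, fills the boundary-likeliness table from the
    segmentation SVM and solves the cyclic problem exactly with DCDP.
    Returns ``(polygon, rays)``; the polygon satisfies every smoothness
    constraint including the wrap-around one.
    """
    config = config or DetectionConfig()
    seg = config.segmentation
    fld = image if isinstance(image, GradientField) else compute_gradient_field(as_gray(image))
    rays = build_ray_system(center, seg.rays)
    table = ray_window_table(fld, rays, seg.window)
    L = table @ boundary_svm.weights + boundary_svm.bias
    prob = BoundaryProblem(L=L, varsigma=seg.varsigma)
    report = dcdp(prob, seg.scheme)
    return polygon_from_solution(rays, report.solution.p), rays


def classify_candidate(
    image: np.ndarray | GradientField,
    center: tuple[float, float],
    polygon: np.ndarray,
    shog_svm: SvmModel,
    config: DetectionConfig | None = None,
) -> Detection:
    """Score the S-HOG descriptor on the estimated boundary; accept iff
    score strictly exceeds the classification threshold."""
    config = config or DetectionConfig()
    fld = image if isinstance(image, GradientField) else compute_gradient_field(as_gray(image))
    rays = build_ray_system(center, config.segmentation.rays)
    feat = shog_descriptor(fld, rays, polygon, config.classification.shog)
    score = float(shog_svm.score(feat))
    return Detection(center=np.asarray(center, dtype=float), polygon=polygon,
                     score=score, accepted=score > config.classification.theta)


@dataclass(frozen=True)
class TrainedModels:
    prescreen: SvmModel
    boundary: SvmModel
    classify: SvmModel


def train_all(
    images: list[np.ndarray],
    truths: list[SceneTruth],
    config: DetectionConfig | None = None,
    seed: int = 0,
) -> TrainedModels:
    """Train all three stage SVMs from annotated images."""
    config = config or DetectionConfig()
    Xp, yp = build_prescreen_training_set(images, truths, config, seed=seed)
    svm_p = train_linear_svm(Xp, yp, C=config.prescreen.C, seed=seed)
    Xb, yb = build_boundary_training_set(images, truths, config)
    svm_b = train_linear_svm(Xb, yb, C=config.segmentation.C, seed=seed)
    Xc, yc = build_classification_training_set(images, truths, svm_b, config, seed=seed)
    svm_c = train_linear_svm(Xc, yc, C=config.classification.C, seed=seed)
    logger.info("trained SVMs on %d/%d/%d examples", len(yp), len(yb), len(yc))
    return TrainedModels(prescreen=svm_p, boundary=svm_b, classify=svm_c)


def calibrate_thresholds(
    models: TrainedModels,
    val_images: list[np.ndarray],
    val_truths: list[SceneTruth],
    config: DetectionConfig | None = None,
    margin: float = 0.25,
) -> DetectionConfig:
    """Select the two decision thresholds on held-out validation images.

    SVM scores are in arbitrary margin units, so the operating thresholds
    are chosen on a validation set (train on one image set, pick the
    operating point on a second, evaluate on the rest).  Both stages are tuned recall-first, because later stages (and
    only they) can remove false positives while a dropped true positive
    is unrecoverable: the pre-screening threshold sits just below the
    weakest best-window score over all validation glomeruli, and the
    classification threshold sits ``margin`` below the weakest validation
    true-candidate score — the highest threshold that keeps every
    validation true positive.  Returns a config with both thetas
    replaced.
    """
    import dataclasses

    from matplotlib.path import Path as MplPath

    config = config or DetectionConfig()
    ps = config.prescreen
    w = ps.rhog.window

    # --- prescreen theta: keep every validation glomerulus reachable
    best_scores = []
    for image, truth in zip(val_images, val_truths):
        gray = as_gray(image)
        if gray.shape[0] < w or gray.shape[1] < w:
            continue
        extractor = RhogIntegral(compute_gradient_field(gray), ps.rhog)
        tops_r = np.arange(0, gray.shape[0] - w + 1, ps.stride)
        tops_c = np.arange(0, gray.shape[1] - w + 1, ps.stride)
        rr, cc = np.meshgrid(tops_r, tops_c, indexing="ij")
        tops = np.stack([rr.ravel(), cc.ravel()], axis=1)
        scores = models.prescreen.score(extractor.descriptors(tops))
        centers = tops + w / 2.0
        for g in _eligible_glomeruli(truth, config.min_diameter):
            near = np.linalg.norm(centers - np.asarray(g.center), axis=1) <= ps.nms_radius / 2
            if near.any():
                best_scores.append(float(np.max(scores[near])))
    if not best_scores:
        raise ValueError("no eligible validation glomeruli for calibration")
    theta_p = min(best_scores) - 0.05
    cfg1 = dataclasses.replace(
        config, prescreen=dataclasses.replace(ps, theta=theta_p)
    )

    # --- classification theta: keep every validation true candidate
    true_scores: list[float] = []
    for image, truth in zip(val_images, val_truths):
        gray = as_gray(image)
        fld = compute_gradient_field(gray)
        paths = [MplPath(g.polygon()) for g in truth.glomeruli]
        matched = [False] * len(paths)
        for cand in prescreen(gray, models.prescreen, cfg1):
            polygon, _ = segment_candidate(fld, tuple(cand.center), models.boundary, cfg1)
            det = classify_candidate(fld, tuple(cand.center), polygon, models.classify, cfg1)
            for j, pth in enumerate(paths):
                if not matched[j] and pth.contains_point((cand.center[0], cand.center[1])):
                    matched[j] = True
                    true_scores.append(det.score)
                    break
    if not true_scores:
        raise ValueError("no validation true candidates for calibration")
    best_theta = min(true_scores) - margin
    logger.info("calibrated thresholds: prescreen %.3f, classification %.3f",
                theta_p, best_theta)
    return dataclasses.replace(
        cfg1,
        classification=dataclasses.replace(cfg1.classification, theta=best_theta),
    )


def detect(
    image: np.ndarray,
    models: TrainedModels,
    config: DetectionConfig | None = None,
) -> list[Detection]:
    """Run the full three-stage detector.

    Returns *all* candidates that passed pre-screening, each with its
    estimated boundary, classification score and accept flag (rejected
    candidates are retained).
    """
    config = config or DetectionConfig()
    gray = as_gray(image)
    fld = compute_gradient_field(gray)
    detections: list[Detection] = []
    for cand in prescreen(gray, models.prescreen, config):
        polygon, _rays = segment_candidate(fld, tuple(cand.center), models.boundary, config)
        det = classify_candidate(fld, tuple(cand.center), polygon, models.classify, config)
        detections.append(Detection(center=det.center, polygon=det.polygon,
                                    score=det.score, accepted=det.accepted,
                                    prescreen_score=cand.score))
    logger.info("detect: %d candidates, %d accepted",
                len(detections), sum(d.accepted for d in detections))
    return detections
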