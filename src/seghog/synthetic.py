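"""Synthetic kidney-section scenes and random solver instances.

Real inputs to the detector are bright-field microscopy images of
desmin-immunostained kidney sections: roughly circular glomeruli of
varying diameter with densely textured interiors (tightly packed cells
give high gradient magnitudes), an optional darker Bowman's-capsule ring
along the boundary, strongly heterogeneous per-object staining, and
elongated stained blood vessels acting as distractors, all on a gently
textured background.  :func:`generate_scene` emulates these features in
grayscale with exact ground truth (centers and boundary polygons), so
every pipeline stage can be trained and scored without real slides.

Glomerulus boundaries are deformed circles

    r(theta) = r0 * (1 + sum_{k=1..4} a_k * cos(k*theta + phi_k)),

with bounded harmonic amplitudes, matching the mostly-spherical but
somewhat deformed shapes of real glomeruli while keeping exactly one
boundary crossing per ray.

:func:`generate_boundary_problem` draws random integer likeliness tables
for the solvers (integer scores make cross-solver equality exact), with
an optional planted path whose bonus makes it the unique optimum.

Both generators are pure functions of their parameters (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import distance_transform_edt, gaussian_filter

from .solver import BoundaryProblem, is_feasible


@dataclass(frozen=True)
class SceneParams:
    """Parameters of one synthetic scene (defaults: see methods note)."""

    shape: tuple[int, int] = (600, 600)
    n_glomeruli: int = 4
    radius_range: tuple[float, float] = (30.0, 90.0)
    deform_amplitude: float = 0.05     # per-harmonic |a_k| upper bound (<= 0.15)
    capsule_prob: float = 0.7
    capsule_thickness: float = 4.0
    capsule_contrast: float = 0.25
    stain_range: tuple[float, float] = (0.35, 1.0)  # per-object stain level
    texture_contrast: float = 0.12     # interior speckle sd at stain = 1
    n_vessels: int = 5
    vessel_width_range: tuple[float, float] = (10.0, 24.0)
    vessel_contrast: float = 0.25
    vessel_texture: float = 0.10       # speckle sd inside vessels (stained walls)
    background_level: float = 0.85
    background_amplitude: float = 0.04
    noise_sd: float = 0.02
    border_margin: float = 110.0       # keeps a 200x200 window around each center
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radius_range[0] < 1:
            raise ValueError("radii must be >= 1")
        if not 0 <= self.capsule_prob <= 1:
            raise ValueError("capsule_prob must be in [0, 1]")
        if not 0 <= self.deform_amplitude <= 0.15:
            raise ValueError("deform_amplitude must be in [0, 0.15]")


@dataclass(frozen=True)
class GlomerulusTruth:
    """Ground truth for one rendered glomerulus."""

    center: tuple[float, float]
    r0: float
    harmonics: np.ndarray = field(repr=False)   # (4,) amplitudes a_k
    phases: np.ndarray = field(repr=False)      # (4,) phases phi_k
    stain: float = 1.0
    has_capsule: bool = False
    is_glomerulus: bool = True

    def radius_at(self, theta: np.ndarray | float) -> np.ndarray | float:
        """Analytic boundary radius r(theta)."""
        theta = np.asarray(theta, dtype=float)
        k = np.arange(1, len(self.harmonics) + 1)
        r = self.r0 * (
            1.0
            + (self.harmonics[None, :] * np.cos(np.outer(theta, k) + self.phases)).sum(-1)
        )
        return r if r.size > 1 else float(r[0])

    def polygon(self, n_vertices: int = 72) -> np.ndarray:
        """Boundary polygon as an (n_vertices, 2) array of (row, col)."""
        theta = 2.0 * np.pi * np.arange(n_vertices) / n_vertices
        r = np.asarray(self.radius_at(theta), dtype=float).reshape(-1)
        cr, cc = self.center
        return np.stack([cr - r * np.sin(theta), cc + r * np.cos(theta)], axis=1)

    @property
    def diameter(self) -> float:
        return 2.0 * self.r0


@dataclass(frozen=True)
class SceneTruth:
    """Everything the generator knows about a scene."""

    glomeruli: list[GlomerulusTruth]
    vessel_paths: list[np.ndarray]     # each (k, 2) polyline of (row, col)

    @property
    def centers(self) -> np.ndarray:
        if not self.glomeruli:
            return np.zeros((0, 2))
        return np.array([g.center for g in self.glomeruli])


class PlacementError(RuntimeError):
    """Raised when the requested object count cannot be placed."""


def _place_centers(params: SceneParams, radii: np.ndarray, rng: np.random.Generator
                   ) -> np.ndarray:
    H, W = params.shape
    centers: list[np.ndarray] = []
    for k, r in enumerate(radii):
        margin = max(params.border_margin, r + 10.0)
        if H - 2 * margin <= 0 or W - 2 * margin <= 0:
            raise PlacementError("image too small for the requested radii/margins")
        for _ in range(2000):
            c = rng.uniform([margin, margin], [H - margin, W - margin])
            ok = all(
                np.linalg.norm(c - c2) > r + r2 + 15.0
                for c2, r2 in zip(centers, radii[: len(centers)])
            )
            if ok:
                centers.append(c)
                break
        else:
            raise PlacementError(f"could not place object {k + 1}/{len(radii)}")
    return np.array(centers)


def _vessel_path(params: SceneParams, glom_centers: np.ndarray,
                 glom_radii: np.ndarray, rng: np.random.Generator) -> np.ndarray | None:
    """Random smooth polyline that stays clear of every glomerulus."""
    H, W = params.shape
    start = rng.uniform([10, 10], [H - 10, W - 10])
    heading = rng.uniform(0, 2 * np.pi)
    pts = [start]
    pos = start.copy()
    length = rng.uniform(150, 350)
    for _ in range(int(length)):
        heading += rng.normal(0, 0.06)
        pos = pos + np.array([np.sin(heading), np.cos(heading)])
        if not (5 <= pos[0] < H - 5 and 5 <= pos[1] < W - 5):
            break
        if glom_centers.size and np.any(
            np.linalg.norm(glom_centers - pos, axis=1) < glom_radii + 25.0
        ):
            break
        pts.append(pos.copy())
    if len(pts) < 40:
        return None
    return np.array(pts)


def generate_scene(params: SceneParams | None = None) -> tuple[np.ndarray, SceneTruth]:
    """Render one scene; returns (image in [0, 1], truth)."""
    params = params or SceneParams()
    rng = np.random.default_rng(params.seed)
    H, W = params.shape

    texture = gaussian_filter(rng.standard_normal((H, W)), 15.0)
    texture /= max(texture.std(), 1e-9)   # unit-sd smooth undulation
    image = params.background_level + params.background_amplitude * texture

    radii = rng.uniform(*params.radius_range, size=params.n_glomeruli)
    centers = (
        _place_centers(params, radii, rng)
        if params.n_glomeruli
        else np.zeros((0, 2))
    )

    # vessels first: glomeruli are drawn on top
    vessel_paths: list[np.ndarray] = []
    for _ in range(params.n_vessels):
        path = _vessel_path(params, centers, radii, rng)
        if path is None:
            continue
        vessel_paths.append(path)
        canvas = np.ones((H, W), dtype=bool)
        ij = np.round(path).astype(int)
        canvas[ij[:, 0], ij[:, 1]] = False
        dist = distance_transform_edt(canvas)
        width = rng.uniform(*params.vessel_width_range)
        mask = dist < width / 2.0
        image[mask] -= params.vessel_contrast * rng.uniform(0.6, 1.2)
        # stained-wall speckle: vessels carry cell-scale texture too
        speck = gaussian_filter(rng.standard_normal((H, W)), 1.4)
        speck /= max(speck.std(), 1e-9)
        image[mask] += params.vessel_texture * speck[mask]

    glomeruli: list[GlomerulusTruth] = []
    rows, cols = np.indices((H, W))
    for k in range(params.n_glomeruli):
        r0 = radii[k]
        a = rng.uniform(-params.deform_amplitude, params.deform_amplitude, size=4)
        phi = rng.uniform(0, 2 * np.pi, size=4)
        stain = rng.uniform(*params.stain_range)
        has_capsule = bool(rng.uniform() < params.capsule_prob)
        g = GlomerulusTruth(center=tuple(centers[k]), r0=float(r0), harmonics=a,
                            phases=phi, stain=float(stain), has_capsule=has_capsule)
        glomeruli.append(g)

        cr, cc = g.center
        pad = int(np.ceil(r0 * 1.3 + params.capsule_thickness + 3))
        r0i, r1i = max(0, int(cr) - pad), min(H, int(cr) + pad + 1)
        c0i, c1i = max(0, int(cc) - pad), min(W, int(cc) + pad + 1)
        dy = rows[r0i:r1i, c0i:c1i] - cr
        dx = cols[r0i:r1i, c0i:c1i] - cc
        rad = np.hypot(dy, dx)
        theta = np.mod(np.arctan2(-dy, dx), 2 * np.pi)
        rb = np.asarray(g.radius_at(theta.ravel())).reshape(theta.shape)
        interior = rad < rb
        # speckled interior: dense cell-scale texture scaled by stain level
        speckle = gaussian_filter(rng.standard_normal(interior.shape), 1.2)
        speckle /= max(speckle.std(), 1e-9)   # unit sd
        level = image[r0i:r1i, c0i:c1i]
        level[interior] -= 0.10 + 0.15 * stain
        level[interior] += params.texture_contrast * stain * speckle[interior]
        if has_capsule:
            ring = np.abs(rad - rb) < params.capsule_thickness / 2.0
            level[ring] -= params.capsule_contrast * stain

    image += rng.normal(0.0, params.noise_sd, size=(H, W))
    np.clip(image, 0.0, 1.0, out=image)
    return image, SceneTruth(glomeruli=glomeruli, vessel_paths=vessel_paths)


def generate_scene_suite(
    n_scenes: int, base: SceneParams | None = None, seed: int = 0
) -> list[tuple[np.ndarray, SceneTruth]]:
    """Render ``n_scenes`` scenes with per-scene seeds derived from ``seed``."""
    base = base or SceneParams()
    rng = np.random.default_rng(seed)
    scenes = []
    for _ in range(n_scenes):
        params = replace(base, seed=int(rng.integers(0, 2**31 - 1)))
        scenes.append(generate_scene(params))
    return scenes


def generate_boundary_problem(
    m: int,
    n: int,
    varsigma: int = 1,
    seed: int = 0,
    planted: np.ndarray | None = None,
    low: int = 0,
    high: int = 100,
    bonus: int = 1000,
) -> BoundaryProblem:
    """Random integer likeliness table, optionally with a planted optimum.

    Scores are drawn uniformly from the integers ``low..high``; if
    ``planted`` is given (a cyclically feasible index vector) a bonus is
    added along it, making it the unique optimal solution.
    """
    rng = np.random.default_rng(seed)
    L = rng.integers(low, high + 1, size=(m, n)).astype(float)
    prob = BoundaryProblem(L=L, varsigma=varsigma)
    if planted is not None:
        planted = np.asarray(planted, dtype=int)
        if planted.shape != (m,) or planted.min() < 1 or planted.max() > n:
            raise ValueError("planted path must be an m-vector with entries in 1..n")
        if not is_feasible(planted, prob):
            raise ValueError("planted path violates the smoothness constraints")
        L[np.arange(m), planted - 1] += bonus
        prob = BoundaryProblem(L=L, varsigma=varsigma)
    return prob


def random_feasible_path(
    m: int, n: int, varsigma: int, rng: np.random.Generator
) -> np.ndarray:
    """Random index vector satisfying all cyclic smoothness constraints.

    Built as a bounded random walk that is blended back to its start so
    the wrap constraint holds.
    """
    if varsigma == 0:
        return np.full(m, int(rng.integers(1, n + 1)))
    for _ in range(200):
        p = np.empty(m, dtype=int)
        p[0] = int(rng.integers(1, n + 1))
        for i in range(1, m):
            lo = max(1, p[i - 1] - varsigma)
            hi = min(n, p[i - 1] + varsigma)
            # drift back toward p[0] near the end so the cycle can close
            remaining = m - i
            lo = max(lo, p[0] - remaining * varsigma)
            hi = min(hi, p[0] + remaining * varsigma)
            p[i] = int(rng.integers(lo, hi + 1))
        if abs(p[-1] - p[0]) <= varsigma:
            return p
    raise RuntimeError("failed to sample a feasible path")
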