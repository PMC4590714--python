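"""Radial ray geometry around a candidate object center.

The boundary of a candidate glomerulus is modelled as an ``m``-sided
polygon whose *i*-th vertex is restricted to one of ``n`` evenly spaced
sample locations on the *i*-th of ``m`` radial line segments (rays) cast
from the candidate center.  With the defaults (36 rays, first sample 17 px
from the center, 63 px long segments sampled every 3 px) each ray carries
n = 22 samples, i.e. 36 x 22 = 792 candidate boundary locations.

Angle convention: ray 1 points along the +col axis (angle 0) and angles
increase counter-clockwise in the conventional display orientation, i.e.
the direction of ray *i* is ``(drow, dcol) = (-sin(theta_i), cos(theta_i))``
with ``theta_i = 2*pi*(i-1)/m``.  Ray and sample indices are 1-based to
match the polygon model; sub-pixel locations are kept as floats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import logging

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RayConfig:
    """Geometry of the ray system.

    Attributes
    ----------
    m : int
        Number of rays (default 36).
    inner_offset : float
        Distance in px from the center to the first sample (default 17).
    segment_length : float
        Length of each ray segment in px (default 63).
    step : float
        Spacing between consecutive samples in px (default 3).
    """

    m: int = 36
    inner_offset: float = 17.0
    segment_length: float = 63.0
    step: float = 3.0

    def __post_init__(self) -> None:
        if self.m < 3:
            raise ValueError("m must be >= 3")
        if self.inner_offset <= 0 or self.segment_length <= 0 or self.step <= 0:
            raise ValueError("inner_offset, segment_length and step must be > 0")
        ratio = self.segment_length / self.step
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                "segment_length must be an integer multiple of step "
                f"(got {self.segment_length}/{self.step})"
            )

    @property
    def n(self) -> int:
        """Samples per ray: segment_length/step + 1."""
        return int(round(self.segment_length / self.step)) + 1

    def radius(self, p: int | np.ndarray) -> float | np.ndarray:
        """Distance from the center to sample index ``p`` (1-based)."""
        return self.inner_offset + (np.asarray(p) - 1) * self.step


@dataclass(frozen=True)
class RaySystem:
    """Ray sample locations around one candidate center."""

    center: tuple[float, float]
    config: RayConfig
    #: (m, n, 2) array of (row, col) sample locations; entry [i-1, p-1]
    #: is sample p on ray i.
    locations: np.ndarray = field(repr=False, default=None)

    @property
    def m(self) -> int:
        return self.config.m

    @property
    def n(self) -> int:
        return self.config.n

    def angle(self, i: int) -> float:
        """Direction angle of ray ``i`` (1-based)."""
        return 2.0 * np.pi * (i - 1) / self.m

    def location(self, i: int, p: int) -> tuple[float, float]:
        """Pixel location (row, col) of sample ``p`` on ray ``i`` (1-based)."""
        if not (1 <= i <= self.m and 1 <= p <= self.n):
            raise IndexError(f"(i, p) = ({i}, {p}) outside 1..{self.m} x 1..{self.n}")
        return tuple(self.locations[i - 1, p - 1])


def ray_direction(theta: float | np.ndarray) -> np.ndarray:
    """Unit (drow, dcol) direction for angle ``theta`` (CCW, 0 = +col)."""
    return np.stack([-np.sin(theta), np.cos(theta)], axis=-1)


def build_ray_system(center: tuple[float, float], config: RayConfig | None = None) -> RaySystem:
    """Place ``config.m`` uniformly spaced rays around ``center``."""
    config = config or RayConfig()
    thetas = 2.0 * np.pi * np.arange(config.m) / config.m
    dirs = ray_direction(thetas)                       # (m, 2)
    radii = config.inner_offset + config.step * np.arange(config.n)  # (n,)
    locs = np.asarray(center, dtype=float) + radii[None, :, None] * dirs[:, None, :]
    return RaySystem(center=tuple(np.asarray(center, dtype=float)), config=config,
                     locations=locs)


def polygon_from_solution(rays: RaySystem, p: np.ndarray) -> np.ndarray:
    """Map an index vector to the (m, 2) vertex array of its polygon.

    ``p`` must have one entry per ray, each in ``1..n``; vertex *i* is the
    ``p[i]``-th sample on ray *i*.  The polygon is implicitly closed.
    """
    p = np.asarray(p, dtype=int)
    if p.shape != (rays.m,):
        raise ValueError(f"index vector must have length m={rays.m}, got {p.shape}")
    if np.any(p < 1) or np.any(p > rays.n):
        raise ValueError(f"index values must lie in 1..{rays.n}")
    return rays.locations[np.arange(rays.m), p - 1].copy()


def polygon_radii(rays: RaySystem, polygon: np.ndarray) -> np.ndarray:
    """Per-vertex distance from the ray-system center."""
    return np.linalg.norm(polygon - np.asarray(rays.center), axis=1)


def polygon_mask(polygon: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a closed polygon into a boolean mask.

    A pixel belongs to the mask iff its center lies inside the polygon
    (crossing test; centers exactly on an edge follow the path library's
    convention); the mask is clipped to ``shape``.  A polygon entirely
    outside the image yields an empty mask.  Degenerate self-intersecting
    polygons are still rasterized, with a warning.
    """
    from matplotlib.path import Path

    polygon = np.asarray(polygon, dtype=float)
    if polygon.ndim != 2 or polygon.shape[1] != 2 or polygon.shape[0] < 3:
        raise ValueError("polygon must be an (k>=3, 2) array of (row, col) vertices")
    if shape[0] < 1 or shape[1] < 1:
        raise ValueError("mask shape must be positive")
    if _is_self_intersecting(polygon):
        logger.warning("rasterizing a self-intersecting polygon")
    r0 = max(0, int(np.floor(polygon[:, 0].min())))
    r1 = min(shape[0], int(np.ceil(polygon[:, 0].max())) + 1)
    c0 = max(0, int(np.floor(polygon[:, 1].min())))
    c1 = min(shape[1], int(np.ceil(polygon[:, 1].max())) + 1)
    mask = np.zeros(shape, dtype=bool)
    if r0 >= r1 or c0 >= c1:
        return mask
    rows, cols = np.mgrid[r0:r1, c0:c1]
    pts = np.stack([rows.ravel(), cols.ravel()], axis=1)
    inside = Path(polygon).contains_points(pts).reshape(rows.shape)
    mask[r0:r1, c0:c1] = inside
    return mask


def _is_self_intersecting(polygon: np.ndarray) -> bool:
    """Cheap segment-pair check for non-adjacent edge crossings."""
    k = len(polygon)
    if k > 64:  # O(k^2) check not worth it for dense polygons
        return False
    segs = [(polygon[i], polygon[(i + 1) % k]) for i in range(k)]

    def crosses(a, b, c, d):
        def orient(p, q, r):
            return np.sign((q[1] - p[1]) * (r[0] - p[0]) - (q[0] - p[0]) * (r[1] - p[1]))

        return (orient(a, b, c) * orient(a, b, d) < 0
                and orient(c, d, a) * orient(c, d, b) < 0)

    for i in range(k):
        for j in range(i + 2, k):
            if i == 0 and j == k - 1:
                continue
            if crosses(*segs[i], *segs[j]):
                return True
    return False
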