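"""The three HOG-family descriptors used by the detection pipeline.

* **R-HOG** — rigid-grid HOG over a 200x200 window (8x8 cells of 25x25 px,
  8 unsigned orientation bins, 512 dimensions); used for sliding-window
  pre-screening.
* **Ray-window descriptor** — a 30x15 px window aligned with a ray and
  centered on one of its sample locations, split into three consecutive
  10x15 radial blocks with 9 orientation bins each (27 dimensions); its
  linear-SVM score is the boundary likeliness of that location.  The
  window is resampled bilinearly in ray-aligned coordinates and pixel
  orientations are expressed relative to the ray direction, so a single
  SVM serves every ray direction.
* **S-HOG** — blocks adapted to an estimated boundary polygon: three
  radial zones (inner/middle/outer, bounded by 0.7, 1.1 and 1.4 times the
  per-direction boundary radius) intersected with eight 45-degree
  sectors, giving 24 disjoint blocks of 9 bins each (216 dimensions).

Every block histogram is L2-normalized independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .imaging import GradientField, bin_orientations, l2_normalize
from .rays import RaySystem, polygon_radii


# --------------------------------------------------------------------------
# R-HOG


@dataclass(frozen=True)
class RHogConfig:
    """Rigid-grid HOG: ``grid x grid`` cells of ``cell`` px, ``bins`` bins."""

    window: int = 200
    cell: int = 25
    bins: int = 8

    def __post_init__(self) -> None:
        if self.window % self.cell != 0:
            raise ValueError("cells must tile the window exactly")

    @property
    def grid(self) -> int:
        return self.window // self.cell

    @property
    def length(self) -> int:
        return self.grid * self.grid * self.bins


def rhog_descriptor(
    field: GradientField, top_left: tuple[int, int], config: RHogConfig | None = None
) -> np.ndarray:
    """R-HOG of the window whose top-left pixel is ``top_left``.

    Concatenates the per-cell L2-normalized histograms in row-major cell
    order; length ``grid**2 * bins`` (512 with defaults).  The window
    must lie fully inside the image.
    """
    config = config or RHogConfig()
    r0, c0 = int(top_left[0]), int(top_left[1])
    H, W = field.shape
    w = config.window
    if r0 < 0 or c0 < 0 or r0 + w > H or c0 + w > W:
        raise ValueError(f"window at {top_left} not inside image of shape {field.shape}")
    out = np.empty(config.length)
    k = 0
    for gr in range(config.grid):
        for gc in range(config.grid):
            rs = slice(r0 + gr * config.cell, r0 + (gr + 1) * config.cell)
            cs = slice(c0 + gc * config.cell, c0 + (gc + 1) * config.cell)
            hist = bin_orientations(
                field.orientation[rs, cs], field.magnitude[rs, cs], config.bins
            )
            out[k : k + config.bins] = l2_normalize(hist)
            k += config.bins
    return out


class RhogIntegral:
    """Integral-histogram accelerator for sliding-window R-HOG.

    Precomputes per-bin cumulative magnitude images once per input so
    that each cell histogram is four lookups; produces descriptors
    identical to :func:`rhog_descriptor`.
    """

    def __init__(self, field: GradientField, config: RHogConfig | None = None):
        self.config = config or RHogConfig()
        self.shape = field.shape
        H, W = field.shape
        b = self.config.bins
        idx = np.floor(field.orientation / (np.pi / b) + 1e-7).astype(int) % b
        planes = np.zeros((H, W, b))
        rows, cols = np.indices(field.shape)
        planes[rows, cols, idx] = field.magnitude
        self._integral = np.zeros((H + 1, W + 1, b))
        np.cumsum(np.cumsum(planes, axis=0), axis=1, out=self._integral[1:, 1:])

    def _cell_hist(self, r0: np.ndarray, c0: np.ndarray, size: int) -> np.ndarray:
        I = self._integral
        return (I[r0 + size, c0 + size] - I[r0, c0 + size]
                - I[r0 + size, c0] + I[r0, c0])

    def descriptors(self, tops: np.ndarray) -> np.ndarray:
        """R-HOG descriptors for windows at the given (k, 2) top-left corners."""
        cfg = self.config
        tops = np.atleast_2d(np.asarray(tops, dtype=int))
        H, W = self.shape
        if np.any(tops < 0) or np.any(tops[:, 0] + cfg.window > H) or np.any(
            tops[:, 1] + cfg.window > W
        ):
            raise ValueError("window not inside image")
        offs = np.arange(cfg.grid) * cfg.cell
        gr, gc = np.meshgrid(offs, offs, indexing="ij")
        r0 = tops[:, 0, None, None] + gr[None]          # (k, grid, grid)
        c0 = tops[:, 1, None, None] + gc[None]
        hists = self._cell_hist(r0, c0, cfg.cell)        # (k, grid, grid, bins)
        norms = np.linalg.norm(hists, axis=-1, keepdims=True)
        hists = np.where(norms > 1e-12, hists / np.maximum(norms, 1e-300), 0.0)
        return hists.reshape(tops.shape[0], cfg.length)

    def descriptor(self, top_left: tuple[int, int]) -> np.ndarray:
        return self.descriptors(np.asarray([top_left]))[0]


# --------------------------------------------------------------------------
# Ray-window descriptor (boundary likeliness features)


@dataclass(frozen=True)
class RayWindowConfig:
    """Ray-aligned window: ``radial x tangential`` px, 3 radial blocks."""

    radial: int = 30
    tangential: int = 15
    blocks: int = 3
    bins: int = 9

    def __post_init__(self) -> None:
        if self.radial % self.blocks != 0:
            raise ValueError("radial extent must split evenly into blocks")

    @property
    def length(self) -> int:
        return self.blocks * self.bins


def _ray_window_features(
    field: GradientField,
    locations: np.ndarray,
    thetas: np.ndarray,
    config: RayWindowConfig,
) -> np.ndarray:
    """Descriptors for ``k`` ray-aligned windows.

    ``locations`` is (k, 2) window centers, ``thetas`` (k,) ray angles.
    Samples gx/gy bilinearly on a rotated unit grid (out-of-image samples
    contribute zero magnitude), folds orientations relative to the ray,
    and histograms three consecutive radial blocks (inner -> outer).
    """
    k = locations.shape[0]
    R, T, B, nb = config.radial, config.tangential, config.blocks, config.bins
    u = np.arange(R) - (R - 1) / 2.0        # radial offsets, inner -> outer
    v = np.arange(T) - (T - 1) / 2.0        # tangential offsets
    drow = np.stack([-np.sin(thetas), np.cos(thetas)], axis=-1)   # radial unit
    dtan = np.stack([-np.cos(thetas), -np.sin(thetas)], axis=-1)  # tangential unit
    # (k, R, T, 2) sample coordinates
    coords = (
        locations[:, None, None, :]
        + u[None, :, None, None] * drow[:, None, None, :]
        + v[None, None, :, None] * dtan[:, None, None, :]
    )
    flat = coords.reshape(-1, 2).T
    gx = map_coordinates(field.gx, flat, order=1, mode="constant", cval=0.0)
    gy = map_coordinates(field.gy, flat, order=1, mode="constant", cval=0.0)
    mag = np.hypot(gx, gy).reshape(k, R, T)
    # ray angle in (gx, gy) space is atan2(drow_row, drow_col) = -theta
    rel = np.mod(np.arctan2(gy, gx).reshape(k, R, T) + thetas[:, None, None], np.pi)
    # tolerance-aware hard binning (see imaging.bin_orientations): angles on
    # a bin edge to within rounding always land in the same bin
    bidx = np.floor(rel / (np.pi / nb) + 1e-7).astype(int) % nb

    rows = R // B
    out = np.empty((k, B * nb))
    for b in range(B):
        sl = slice(b * rows, (b + 1) * rows)
        hists = np.zeros((k, nb))
        flat_idx = (np.arange(k)[:, None, None] * nb + bidx[:, sl, :]).ravel()
        np.add.at(hists.ravel(), flat_idx, mag[:, sl, :].ravel())
        norms = np.linalg.norm(hists, axis=1, keepdims=True)
        hists = np.where(norms > 1e-12, hists / np.maximum(norms, 1e-300), 0.0)
        out[:, b * nb : (b + 1) * nb] = hists
    return out


def ray_window_descriptor(
    field: GradientField,
    rays: RaySystem,
    i: int,
    p: int,
    config: RayWindowConfig | None = None,
) -> np.ndarray:
    """27-dim boundary-likeliness descriptor at sample ``p`` of ray ``i``."""
    config = config or RayWindowConfig()
    loc = np.asarray(rays.location(i, p), dtype=float)[None, :]
    theta = np.asarray([rays.angle(i)])
    return _ray_window_features(field, loc, theta, config)[0]


def ray_window_table(
    field: GradientField, rays: RaySystem, config: RayWindowConfig | None = None
) -> np.ndarray:
    """Descriptors at every ray sample: array of shape (m, n, length)."""
    config = config or RayWindowConfig()
    m, n = rays.m, rays.n
    locs = rays.locations.reshape(m * n, 2)
    thetas = np.repeat(2.0 * np.pi * np.arange(m) / m, n)
    feats = _ray_window_features(field, locs, thetas, config)
    return feats.reshape(m, n, config.length)


# --------------------------------------------------------------------------
# S-HOG


@dataclass(frozen=True)
class ShogConfig:
    """Boundary-adapted blocks: 3 radial zones x 8 sectors, 9 bins each.

    ``zone_fracs`` are the zone boundaries as multiples of the
    per-direction boundary radius: inner [0, 0.7), middle [0.7, 1.1),
    outer [1.1, 1.4].
    """

    sectors: int = 8
    zone_fracs: tuple[float, float, float] = (0.7, 1.1, 1.4)
    bins: int = 9

    @property
    def zones(self) -> int:
        return len(self.zone_fracs)

    @property
    def n_blocks(self) -> int:
        return self.zones * self.sectors

    @property
    def length(self) -> int:
        return self.n_blocks * self.bins


def shog_blocks(
    rays: RaySystem,
    polygon: np.ndarray,
    shape: tuple[int, int],
    config: ShogConfig | None = None,
) -> list[np.ndarray]:
    """The 24 disjoint block masks induced by a boundary polygon.

    The boundary radius ``r_b(theta)`` is linearly interpolated between
    the radii of the two adjacent polygon vertices.  Each pixel belongs
    to at most one (sector, zone) block, determined by its angle and its
    radius relative to ``r_b``.  Ordering is sector-major (sector 1
    starts at angle 0, counter-clockwise), zones inner -> outer.
    """
    config = config or ShogConfig()
    cr, cc = rays.center
    radii = polygon_radii(rays, polygon)
    m = rays.m
    H, W = shape

    rmax = config.zone_fracs[-1] * radii.max() + 1.0
    r0, r1 = max(0, int(np.floor(cr - rmax))), min(H, int(np.ceil(cr + rmax)) + 1)
    c0, c1 = max(0, int(np.floor(cc - rmax))), min(W, int(np.ceil(cc + rmax)) + 1)
    blocks = [np.zeros(shape, dtype=bool) for _ in range(config.n_blocks)]
    if r0 >= r1 or c0 >= c1:
        return blocks

    rows, cols = np.mgrid[r0:r1, c0:c1]
    dy = rows - cr
    dx = cols - cc
    radius = np.hypot(dy, dx)
    theta = np.mod(np.arctan2(-dy, dx), 2.0 * np.pi)

    # interpolate r_b between adjacent vertices (vertex i at angle 2pi(i-1)/m)
    t = theta / (2.0 * np.pi / m)
    i0 = np.floor(t).astype(int) % m
    frac = t - np.floor(t)
    rb = (1.0 - frac) * radii[i0] + frac * radii[(i0 + 1) % m]

    ratio = np.divide(radius, rb, out=np.full_like(radius, np.inf), where=rb > 0)
    f = config.zone_fracs
    zone = np.full(ratio.shape, -1)
    zone[ratio < f[0]] = 0
    zone[(ratio >= f[0]) & (ratio < f[1])] = 1
    zone[(ratio >= f[1]) & (ratio <= f[2])] = 2
    sector = np.floor(theta / (2.0 * np.pi / config.sectors)).astype(int)
    np.clip(sector, 0, config.sectors - 1, out=sector)

    inside = zone >= 0
    block_idx = sector * config.zones + zone
    for b in range(config.n_blocks):
        sub = inside & (block_idx == b)
        if sub.any():
            blocks[b][r0:r1, c0:c1] = sub
    return blocks


def shog_descriptor(
    field: GradientField,
    rays: RaySystem,
    polygon: np.ndarray,
    config: ShogConfig | None = None,
) -> np.ndarray:
    """216-dim S-HOG: concatenated per-block L2-normalized histograms."""
    config = config or ShogConfig()
    masks = shog_blocks(rays, polygon, field.shape, config)
    out = np.empty(config.length)
    nb = config.bins
    for k, mask in enumerate(masks):
        if mask.any():
            hist = bin_orientations(field.orientation[mask], field.magnitude[mask], nb)
            out[k * nb : (k + 1) * nb] = l2_normalize(hist)
        else:
            out[k * nb : (k + 1) * nb] = 0.0
    return out
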