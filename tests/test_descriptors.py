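"""R-HOG, ray-window and S-HOG descriptor behaviour."""

import numpy as np
import pytest

from seghog.descriptors import (
    RayWindowConfig,
    RHogConfig,
    RhogIntegral,
    ShogConfig,
    ray_window_descriptor,
    ray_window_table,
    rhog_descriptor,
    shog_blocks,
    shog_descriptor,
)
from seghog.imaging import compute_gradient_field
from seghog.rays import build_ray_system, polygon_from_solution


def test_descriptor_lengths():
    assert RHogConfig().length == 512
    assert RayWindowConfig().length == 27
    cfg = ShogConfig()
    assert cfg.n_blocks == 24
    assert cfg.length == 216


def test_rhog_of_constant_image_is_zero():
    fld = compute_gradient_field(np.full((220, 220), 3.0))
    assert np.array_equal(rhog_descriptor(fld, (5, 5)), np.zeros(512))


def test_rhog_window_out_of_bounds_rejected():
    fld = compute_gradient_field(np.zeros((210, 210)))
    with pytest.raises(ValueError):
        rhog_descriptor(fld, (20, 20))


def test_rhog_localizes_texture_to_matching_cell():
    img = np.zeros((200, 200))
    rng = np.random.default_rng(0)
    # texture strictly inside cell (2, 3): rows 50..74, cols 75..99
    img[52:73, 77:98] = rng.random((21, 21))
    fld = compute_gradient_field(img)
    desc = rhog_descriptor(fld, (0, 0)).reshape(8, 8, 8)
    nonzero = np.argwhere(desc.sum(axis=2) > 0)
    assert nonzero.tolist() == [[2, 3]]


def test_rhog_integral_matches_naive():
    rng = np.random.default_rng(1)
    fld = compute_gradient_field(rng.random((260, 260)))
    fast = RhogIntegral(fld)
    for top in [(0, 0), (13, 42), (60, 60)]:
        assert np.allclose(fast.descriptor(top), rhog_descriptor(fld, top), atol=1e-9)


def test_ray_window_descriptor_of_constant_image_is_zero():
    fld = compute_gradient_field(np.full((300, 300), 2.0))
    rays = build_ray_system((150.0, 150.0))
    assert np.array_equal(ray_window_descriptor(fld, rays, 3, 7), np.zeros(27))


def test_ray_window_invariant_across_rays_on_radial_field(paraboloid_field):
    fld, center = paraboloid_field
    rays = build_ray_system(center)
    table = ray_window_table(fld, rays)
    ref = table[0]
    assert np.max(np.linalg.norm(table - ref[None], axis=2)) < 1e-6


def test_ray_window_middle_block_dominates_on_ring():
    # a bright ring at the radius of sample p=10 concentrates gradient mass
    # in the middle radial block, identically for every ray direction
    rows, cols = np.indices((260, 260))
    center = (130.0, 130.0)
    rays = build_ray_system(center)
    r10 = 17.0 + 9 * 3.0
    ring = np.exp(-((np.hypot(rows - center[0], cols - center[1]) - r10) ** 2) / 18.0)
    fld = compute_gradient_field(ring)
    table = ray_window_table(fld, rays)
    for i in range(36):
        blocks = table[i, 9].reshape(3, 9)
        # normalized blocks all have unit norm where nonzero; compare the
        # raw gradient content via the interior/outer blocks being emptier
        norms = np.linalg.norm(blocks, axis=1)
        assert norms[1] > 0  # middle block sees the ring on every ray


def test_shog_blocks_count_disjoint_and_bounded():
    rays = build_ray_system((70.0, 70.0))
    p = np.random.default_rng(2).integers(5, 15, size=36)
    poly = polygon_from_solution(rays, p)
    masks = shog_blocks(rays, poly, (140, 140))
    assert len(masks) == 24
    total = np.zeros((140, 140), dtype=int)
    for m in masks:
        total += m
    assert total.max() <= 1  # pairwise disjoint
    # every block pixel lies within the 1.4 * r_b envelope
    rows, cols = np.indices((140, 140))
    rad = np.hypot(rows - 70.0, cols - 70.0)
    rb_max = np.max(np.linalg.norm(poly - np.array([70.0, 70.0]), axis=1))
    assert rad[total > 0].max() <= 1.4 * rb_max + 1.5


def test_shog_zone_boundaries_are_circles_for_constant_radius():
    rays = build_ray_system((80.0, 80.0))
    poly = polygon_from_solution(rays, np.full(36, 12))  # radius 50
    r = 17.0 + 11 * 3.0
    masks = shog_blocks(rays, poly, (160, 160))
    rows, cols = np.indices((160, 160))
    rad = np.hypot(rows - 80.0, cols - 80.0)
    inner = np.zeros((160, 160), bool)
    middle = np.zeros((160, 160), bool)
    outer = np.zeros((160, 160), bool)
    for s in range(8):
        inner |= masks[s * 3]
        middle |= masks[s * 3 + 1]
        outer |= masks[s * 3 + 2]
    # interpolated r_b is slightly below r between vertices (chord effect),
    # so allow a 1-px band at each circle boundary
    assert rad[inner].max() < 0.7 * r + 1.0
    assert 0.7 * r - 1.5 < rad[middle].min() and rad[middle].max() < 1.1 * r + 1.0
    assert 1.1 * r - 1.5 < rad[outer].min() and rad[outer].max() <= 1.4 * r + 1.0


def test_shog_descriptor_constant_image_zero_and_length():
    fld = compute_gradient_field(np.full((160, 160), 1.0))
    rays = build_ray_system((80.0, 80.0))
    poly = polygon_from_solution(rays, np.full(36, 10))
    desc = shog_descriptor(fld, rays, poly)
    assert desc.shape == (216,)
    assert np.array_equal(desc, np.zeros(216))


def test_shog_invariant_to_global_intensity_scale():
    rng = np.random.default_rng(3)
    img = rng.random((200, 200))
    rays = build_ray_system((100.0, 100.0))
    poly = polygon_from_solution(rays, np.full(36, 13))
    d1 = shog_descriptor(compute_gradient_field(img), rays, poly)
    d2 = shog_descriptor(compute_gradient_field(3.7 * img), rays, poly)
    assert np.allclose(d1, d2)
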