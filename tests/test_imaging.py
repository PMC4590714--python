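"""Gradient field and orientation histogram primitives."""

import numpy as np
import pytest

from seghog.imaging import (
    as_gray,
    bin_orientations,
    compute_gradient_field,
    l2_normalize,
    orientation_histogram,
)


def test_constant_image_has_zero_gradient():
    fld = compute_gradient_field(np.full((20, 30), 7.0))
    assert np.all(fld.magnitude == 0)
    assert fld.shape == (20, 30)


def test_vertical_step_edge_hand_computed():
    # left half 0, right half 1: central differences give 0.5 at the two
    # columns adjacent to the step, orientation = horizontal-gradient angle 0
    img = np.zeros((10, 10))
    img[:, 5:] = 1.0
    fld = compute_gradient_field(img)
    assert np.allclose(fld.magnitude[:, 4], 0.5)
    assert np.allclose(fld.magnitude[:, 5], 0.5)
    assert np.allclose(fld.magnitude[:, [0, 1, 2, 3, 7, 8, 9]], 0.0)
    edge = fld.magnitude > 0
    assert np.allclose(fld.orientation[edge], 0.0)


def test_output_shape_matches_input():
    fld = compute_gradient_field(np.random.default_rng(0).random((200, 200)))
    assert fld.magnitude.shape == (200, 200)
    assert fld.orientation.shape == (200, 200)
    assert np.all(fld.magnitude >= 0)
    assert np.all((fld.orientation >= 0) & (fld.orientation < np.pi))


@pytest.mark.parametrize("bad", [np.zeros((0, 5)), np.zeros(5), np.array([[np.nan]])])
def test_invalid_images_rejected(bad):
    with pytest.raises(ValueError):
        compute_gradient_field(bad)


def test_rgb_luminance_reduction():
    rgb = np.zeros((4, 4, 3))
    rgb[..., 1] = 1.0
    assert np.allclose(as_gray(rgb), 0.587)


def test_zero_field_gives_zero_histogram():
    fld = compute_gradient_field(np.zeros((8, 8)))
    hist = orientation_histogram(fld, np.ones((8, 8), dtype=bool))
    assert np.array_equal(hist, np.zeros(9))


def test_single_orientation_gives_unit_basis_vector():
    img = np.tile(np.arange(8.0), (8, 1))  # pure horizontal gradient
    fld = compute_gradient_field(img)
    hist = orientation_histogram(fld, np.ones((8, 8), dtype=bool))
    expected = np.zeros(9)
    expected[0] = 1.0
    assert np.allclose(hist, expected)


def test_equal_bins_normalize_to_one_third():
    # nine bins with equal mass -> every entry 1/sqrt(9) = 1/3 exactly
    hist = l2_normalize(np.full(9, 5.0))
    assert np.allclose(hist, 1.0 / 3.0)


def test_empty_mask_returns_zero_vector():
    fld = compute_gradient_field(np.random.default_rng(1).random((6, 6)))
    assert np.array_equal(orientation_histogram(fld, np.zeros((6, 6), bool)), np.zeros(9))


def test_mask_shape_mismatch_rejected():
    fld = compute_gradient_field(np.ones((6, 6)))
    with pytest.raises(ValueError):
        orientation_histogram(fld, np.ones((5, 6), dtype=bool))


def test_histogram_invariant_to_intensity_offset():
    rng = np.random.default_rng(2)
    img = rng.random((30, 30))
    mask = rng.random((30, 30)) > 0.5
    h1 = orientation_histogram(compute_gradient_field(img), mask)
    h2 = orientation_histogram(compute_gradient_field(img + 11.5), mask)
    assert np.allclose(h1, h2)


def test_pattern_rotated_half_turn_same_unsigned_histogram():
    rng = np.random.default_rng(3)
    img = rng.random((21, 21))
    rot = np.rot90(img, 2)  # 180-degree rotation negates both gradients
    h1 = orientation_histogram(compute_gradient_field(img), np.ones((21, 21), bool))
    h2 = orientation_histogram(compute_gradient_field(rot), np.ones((21, 21), bool))
    assert np.allclose(np.sort(h1), np.sort(h2))
    assert np.allclose(h1, h2)


def test_unnormalized_mass_equals_magnitude_sum():
    rng = np.random.default_rng(4)
    img = rng.random((25, 25))
    fld = compute_gradient_field(img)
    mask = rng.random((25, 25)) > 0.3
    hist = bin_orientations(fld.orientation[mask], fld.magnitude[mask], 9)
    assert np.isclose(hist.sum(), fld.magnitude[mask].sum())
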