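"""Gradient computation and oriented-gradient histogramming.

All HOG-family descriptors in this package are built from the same two
primitives: a dense gradient field of an intensity image, and a
magnitude-weighted histogram of unsigned gradient orientations over an
arbitrary pixel mask.

Conventions
-----------
* Pixel coordinates are 0-based ``(row, col)``, origin at the top-left.
* Gradients are central differences in the interior and one-sided
  differences on the border (``numpy.gradient``).
* Orientations are *unsigned*: angles are folded into ``[0, pi)`` so that
  a gradient and its negation land in the same bin.  Histogramming uses
  hard assignment into ``n_bins`` equal bins of width ``pi / n_bins``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Luminance weights applied to RGB input before gradient computation.
RGB_LUMINANCE = (0.299, 0.587, 0.114)

#: Guard used when L2-normalizing histograms: a histogram whose norm does
#: not exceed this value is returned as the zero vector.
NORM_EPS = 1e-12


@dataclass(frozen=True)
class GradientField:
    """Dense image gradients.

    Attributes
    ----------
    gx, gy : ndarray
        Horizontal (+col) and vertical (+row) derivative components.
    magnitude : ndarray
        ``sqrt(gx**2 + gy**2)``, non-negative.
    orientation : ndarray
        Unsigned gradient angle in ``[0, pi)`` radians.
    """

    gx: np.ndarray
    gy: np.ndarray
    magnitude: np.ndarray
    orientation: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.magnitude.shape


def as_gray(image: np.ndarray) -> np.ndarray:
    """Return a float 2-D intensity image; RGB(A) is reduced to luminance."""
    arr = np.asarray(image, dtype=float)
    if arr.ndim == 3:
        if arr.shape[2] not in (3, 4):
            raise ValueError(f"expected an RGB(A) image, got shape {arr.shape}")
        arr = arr[..., :3] @ np.array(RGB_LUMINANCE)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {arr.shape}")
    return arr


def compute_gradient_field(image: np.ndarray) -> GradientField:
    """Compute the gradient field of a grayscale image.

    Parameters
    ----------
    image : ndarray
        2-D intensity array (RGB input must be converted with
        :func:`as_gray` first).  Must be non-empty and finite.
    """
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image intensities must be finite")
    if arr.shape[0] >= 2:
        gy = np.gradient(arr, axis=0)
    else:
        gy = np.zeros_like(arr)
    if arr.shape[1] >= 2:
        gx = np.gradient(arr, axis=1)
    else:
        gx = np.zeros_like(arr)
    magnitude = np.hypot(gx, gy)
    orientation = np.mod(np.arctan2(gy, gx), np.pi)
    # atan2 can return exactly pi for (-x, +0.0); fold that onto 0.
    orientation[orientation >= np.pi] = 0.0
    return GradientField(gx=gx, gy=gy, magnitude=magnitude, orientation=orientation)


def l2_normalize(vec: np.ndarray, eps: float = NORM_EPS) -> np.ndarray:
    """L2-normalize ``vec``; vectors with norm <= eps come back as zeros."""
    vec = np.asarray(vec, dtype=float)
    norm = float(np.linalg.norm(vec))
    if norm <= eps:
        return np.zeros_like(vec)
    return vec / norm


def bin_orientations(
    orientation: np.ndarray, magnitude: np.ndarray, n_bins: int
) -> np.ndarray:
    """Histogram orientations (hard assignment) weighted by magnitude.

    Bin ``k`` covers ``[k*pi/n_bins, (k+1)*pi/n_bins)``.  Works on arrays
    of any (matching) shape; returns an unnormalized length-``n_bins``
    vector.  A tiny tolerance snaps angles sitting within float rounding
    of a bin edge upward (and across the 0/pi wrap), so orientations that
    are analytically equal always land in the same bin.
    """
    idx = np.floor(orientation / (np.pi / n_bins) + 1e-7).astype(int) % n_bins
    hist = np.zeros(n_bins)
    np.add.at(hist, idx.ravel(), np.asarray(magnitude, dtype=float).ravel())
    return hist


def orientation_histogram(
    field: GradientField, mask: np.ndarray, n_bins: int = 9
) -> np.ndarray:
    """Magnitude-weighted orientation histogram over a pixel mask.

    Parameters
    ----------
    field : GradientField
    mask : ndarray
        Boolean mask of the same shape as the field.  An all-false mask
        yields the zero vector (no error).
    n_bins : int
        Number of unsigned orientation bins (default 9, bin width pi/9).

    Returns
    -------
    ndarray
        Length-``n_bins`` L2-normalized histogram.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != field.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match field shape {field.shape}"
        )
    if not mask.any():
        return np.zeros(n_bins)
    hist = bin_orientations(field.orientation[mask], field.magnitude[mask], n_bins)
    return l2_normalize(hist)
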