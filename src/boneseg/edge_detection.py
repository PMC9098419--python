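"""Per-slice Canny edge detection with a normalized hysteresis threshold.

The detector exposes a single threshold on a normalized 0–1 scale: the
hysteresis high threshold is the given fraction of the slice's maximum
Gaussian-smoothed gradient magnitude, and the low threshold is 0.4 × high
(the conventional hysteresis ratio).  Per-slice normalization lets one
threshold range work across slices of varying brightness; typical useful
ranges are 0.02–0.07 for MRI and 0.15–0.25 for CT.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import feature

from .volume_io import ImageVolume

logger = logging.getLogger(__name__)

#: hysteresis low / high threshold ratio
LOW_HIGH_RATIO = 0.4

#: Gaussian smoothing SD (pixels) recommended for the phantom volumes.
#: A historical GUI default of 0.10 px is accepted but performs almost no
#: smoothing; see docs/methods.md.
DEFAULT_SIGMA = 1.0


@dataclass
class EdgeMap:
    """Per-slice binary edge grids aligned to a source volume, with the
    detection parameters recorded for provenance."""

    edges: np.ndarray  # bool, same shape as the source voxel grid
    high_threshold: float
    low_threshold: float
    sigma: float

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=bool)
        if not 0 < self.low_threshold < self.high_threshold:
            raise ValueError("require 0 < low_threshold < high_threshold")

    def slice_pixels(self, slice_idx: int) -> set[tuple[int, int]]:
        """Edge pixels of one slice as a set of (row, col) tuples."""
        rr, cc = np.nonzero(self.edges[slice_idx])
        return set(zip(rr.tolist(), cc.tolist()))


def _smoothed_gradient_max(image: np.ndarray, sigma: float) -> float:
    """Maximum interior Sobel gradient magnitude of the Gaussian-smoothed
    slice; defines the 1.0 point of the normalized threshold scale.

    The smoothing (constant-padded Gaussian with bleed-over renormalization)
    and the Sobel operator replicate the pipeline inside skimage's Canny, so
    the fraction-of-max thresholds land on the same magnitude scale the
    hysteresis sees.
    """
    img = image.astype(float)
    sm = ndimage.gaussian_filter(img, sigma, mode="constant")
    bleed = ndimage.gaussian_filter(np.ones_like(img), sigma, mode="constant")
    sm = sm / (bleed + np.finfo(float).eps)
    gr = ndimage.sobel(sm, axis=0)
    gc = ndimage.sobel(sm, axis=1)
    mag = np.hypot(gr, gc)
    return float(mag[1:-1, 1:-1].max()) if min(img.shape) > 2 else float(mag.max())


def canny_slice(image: np.ndarray, high_threshold: float,
                sigma: float = DEFAULT_SIGMA) -> np.ndarray:
    """Canny edges of one 2D slice.

    ``high_threshold`` is a fraction of the slice's maximum smoothed
    gradient magnitude (normalized 0–1 scale); hysteresis low threshold is
    ``0.4 × high``.  A constant slice has no gradient and yields an empty
    edge grid (with a logged warning).

    Returns
    -------
    bool ndarray of the image's shape.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or min(img.shape) < 5:
        raise ValueError(f"image must be 2D and at least 5x5, got shape {img.shape}")
    if not 0 < high_threshold < 1:
        raise ValueError(f"high_threshold must lie in (0, 1), got {high_threshold}")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    gmax = _smoothed_gradient_max(img, sigma)
    scale = max(1.0, float(np.abs(img).max()))
    if gmax <= 1e-9 * scale:  # constant up to floating-point rounding
        logger.warning("constant slice: no gradients, returning empty edge grid")
        return np.zeros(img.shape, dtype=bool)
    high = high_threshold * gmax
    return feature.canny(img, sigma=sigma,
                         low_threshold=LOW_HIGH_RATIO * high,
                         high_threshold=high,
                         use_quantiles=False)


def detect_edges(volume: ImageVolume, high_threshold: float,
                 sigma: float = DEFAULT_SIGMA) -> EdgeMap:
    """Slice-wise Canny edge detection over a whole volume."""
    edges = np.zeros(volume.shape, dtype=bool)
    for k in range(volume.shape[0]):
        edges[k] = canny_slice(volume.voxels[k], high_threshold, sigma)
    return EdgeMap(edges=edges, high_threshold=high_threshold,
                   low_threshold=LOW_HIGH_RATIO * high_threshold, sigma=sigma)
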