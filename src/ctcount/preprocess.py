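"""Filtering chain applied before object separation.

The contrast agent makes pollen and ovules the brightest structures in
the scan, so the pipeline is: greyscale thresholding (drop voxels darker
than a chosen value), a 3×3×3 3D median filter against reconstruction
noise, then a 9×9×9 3D Gaussian smoothing filter.  Greyscale is retained
inside the mask (sub-threshold voxels are zeroed, not binarised) because
the subsequent iterative-threshold split operates on intensities.

Boundary handling for both filters is mirror (reflect) padding, which
avoids darkening object fragments at scan edges and so avoids biasing
volume estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .volume_io import Volume3D

__all__ = ["BinaryMask", "threshold_grey", "median3d", "gaussian3d", "apply_mask", "resolve_threshold"]

log = logging.getLogger(__name__)

DEFAULT_MEDIAN_KERNEL = 3
DEFAULT_GAUSSIAN_KERNEL = 9
#: sigma for the 9-wide truncated Gaussian (support ~ 6 sigma)
DEFAULT_GAUSSIAN_SIGMA = 1.5


@dataclass
class BinaryMask:
    """Boolean foreground mask aligned to a parent :class:`Volume3D`."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)

    @property
    def shape(self):
        return self.data.shape

    def count(self) -> int:
        return int(self.data.sum())


def resolve_threshold(vol: Volume3D, threshold) -> float:
    """Resolve a config threshold: a number, or ``"otsu"`` for automatic choice."""
    if isinstance(threshold, str):
        if threshold.lower() != "otsu":
            raise ValueError(f"unknown threshold mode {threshold!r}")
        t = float(threshold_otsu(np.asarray(vol.data)))
        log.info("Otsu threshold: %g", t)
        return t
    return float(threshold)


def threshold_grey(vol: Volume3D, t: float) -> BinaryMask:
    """Mask of voxels at least as bright as ``t`` (the stained structures)."""
    mask = np.asarray(vol.data) >= t
    n = int(mask.sum())
    if n == 0 or n == mask.size:
        log.warning("threshold %g yields a %s mask", t, "full" if n else "empty")
    return BinaryMask(mask, vol.spacing)


def apply_mask(vol: Volume3D, mask: BinaryMask) -> Volume3D:
    """Zero voxels outside the mask, keeping greyscale inside it."""
    if mask.shape != vol.shape:
        raise ValueError(f"mask shape {mask.shape} != volume shape {vol.shape}")
    return vol.with_data(np.where(mask.data, vol.data, 0))


def median3d(vol: Volume3D, kernel: int = DEFAULT_MEDIAN_KERNEL) -> Volume3D:
    """3D median filter with a cubic ``kernel³`` neighbourhood (mirror boundary)."""
    kernel = int(kernel)
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError(f"median kernel must be odd and >= 1, got {kernel}")
    if kernel == 1:
        return vol.with_data(vol.data.copy())
    out = ndimage.median_filter(vol.data, size=kernel, mode="mirror")
    return vol.with_data(out)


def gaussian3d(
    vol: Volume3D,
    kernel: int = DEFAULT_GAUSSIAN_KERNEL,
    sigma: float = DEFAULT_GAUSSIAN_SIGMA,
) -> Volume3D:
    """Separable 3D Gaussian smoothing truncated to ``kernel³`` support.

    The truncated 1D kernel is renormalised to sum to 1, so constant
    volumes are preserved exactly and total intensity of interior
    structures is conserved.
    """
    kernel = int(kernel)
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError(f"gaussian kernel must be odd and >= 1, got {kernel}")
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    radius = kernel // 2
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    k1d = np.exp(-0.5 * (x / sigma) ** 2)
    k1d /= k1d.sum()
    out = np.asarray(vol.data, dtype=np.float64)
    for axis in range(3):
        out = ndimage.correlate1d(out, k1d, axis=axis, mode="mirror")
    return vol.with_data(out)
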