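"""Reading, writing and cropping of 3D greyscale stacks.

Volumes are kept in (z, y, x) axis order with z the page index of the
multi-page TIFF, and carry their voxel spacing in µm so that every
volume measurement downstream can be expressed in µm³.  All ROIs are
half-open ``[lo, hi)`` boxes in 0-based voxel coordinates.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from typing import Tuple

import numpy as np
import tifffile

__all__ = ["Volume3D", "SubsetROI", "read_volume", "write_volume", "crop"]

#: allowed calibration states of a volume
CALIBRATION_STATES = ("raw", "byte_scaled", "ct_scaled")


@dataclass
class Volume3D:
    """A 3D greyscale image with physical voxel spacing.

    Parameters
    ----------
    data
        Scalar grid of shape ``(nz, ny, nx)``.
    spacing
        µm per voxel along (z, y, x); anisotropic spacing is supported
        and enters every µm³ conversion.
    calibration_state
        ``"raw"`` for reconstructed greys, ``"byte_scaled"`` or
        ``"ct_scaled"`` after the respective normalisation.  A volume is
        calibrated at most once.
    provenance
        Free-text scan identifier.
    """

    data: np.ndarray
    spacing: Tuple[float, float, float]
    calibration_state: str = "raw"
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError(f"volume must have >=1 voxel per axis, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3:
            raise ValueError("spacing must be a (z, y, x) triple")
        if not all(np.isfinite(s) and s > 0 for s in self.spacing):
            raise ValueError(f"spacing entries must be finite and > 0, got {self.spacing}")
        if self.calibration_state not in CALIBRATION_STATES:
            raise ValueError(f"unknown calibration_state {self.calibration_state!r}")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_um3(self) -> float:
        """Physical volume of one voxel in µm³."""
        sz, sy, sx = self.spacing
        return sz * sy * sx

    def with_data(self, data: np.ndarray, calibration_state: str | None = None) -> "Volume3D":
        """Copy of this volume with new voxel data (same spacing/provenance)."""
        return replace(
            self,
            data=data,
            calibration_state=calibration_state or self.calibration_state,
        )


@dataclass(frozen=True)
class SubsetROI:
    """Half-open axis-aligned box ``[lo, hi)`` in voxel coordinates (z, y, x)."""

    lo: Tuple[int, int, int]
    hi: Tuple[int, int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "lo", tuple(int(v) for v in self.lo))
        object.__setattr__(self, "hi", tuple(int(v) for v in self.hi))
        if len(self.lo) != 3 or len(self.hi) != 3:
            raise ValueError("lo and hi must be (z, y, x) triples")
        if any(l < 0 for l in self.lo) or any(h <= l for l, h in zip(self.lo, self.hi)):
            raise ValueError(f"invalid ROI: lo={self.lo}, hi={self.hi} (need 0 <= lo < hi)")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return tuple(h - l for l, h in zip(self.lo, self.hi))

    @property
    def slices(self) -> Tuple[slice, slice, slice]:
        return tuple(slice(l, h) for l, h in zip(self.lo, self.hi))

    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def check_within(self, shape: Tuple[int, int, int]) -> None:
        if any(h > s for h, s in zip(self.hi, shape)):
            raise ValueError(f"ROI {self.lo}-{self.hi} exceeds volume shape {shape}")

    @classmethod
    def full(cls, shape: Tuple[int, int, int]) -> "SubsetROI":
        """ROI covering the whole of a volume of the given shape."""
        return cls((0, 0, 0), tuple(int(s) for s in shape))


def read_volume(path: str | os.PathLike, spacing: Tuple[float, float, float],
                provenance: str | None = None) -> Volume3D:
    """Read a multi-page TIFF stack as a :class:`Volume3D`.

    The grid shape is ``(n_pages, page_height, page_width)``; ``spacing``
    (µm per voxel along z, y, x) is attached verbatim — scan metadata is
    not stored in the image files and must be supplied by the caller.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"volume file not found: {path}")
    with tifffile.TiffFile(path) as tf:
        pages = tf.pages
        n = len(pages)
        if n == 0:
            raise ValueError(f"{path}: TIFF contains no pages")
        shape0, dtype0 = pages[0].shape, pages[0].dtype
        if dtype0 is None:
            raise ValueError(f"{path}: unsupported sample format on page 0")
        for i, p in enumerate(pages):
            if p.shape != shape0 or p.dtype != dtype0:
                raise ValueError(
                    f"{path}: ragged TIFF — page {i} has shape {p.shape}/{p.dtype}, "
                    f"page 0 has {shape0}/{dtype0}"
                )
        data = tf.asarray()
    if data.ndim == 2:  # single-page stack
        data = data[None, ...]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected greyscale pages, got array of ndim {data.ndim}")
    return Volume3D(data, spacing, provenance=provenance or os.path.basename(path))


def write_volume(vol: Volume3D, path: str | os.PathLike) -> None:
    """Write a volume as a multi-page TIFF, one page per z slice.

    Integer data (including 32-bit label maps) and float data round-trip
    losslessly through :func:`read_volume`.
    """
    path = os.fspath(path)
    parent = os.path.dirname(path) or "."
    if not os.path.isdir(parent):
        raise IOError(f"parent directory does not exist: {parent}")
    data = np.asarray(vol.data)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    tifffile.imwrite(path, data, photometric="minisblack")


def crop(vol: Volume3D, roi: SubsetROI) -> Volume3D:
    """Extract the sub-volume covered by ``roi``; spacing is unchanged."""
    roi.check_within(vol.shape)
    sub = vol.data[roi.slices].copy()
    return replace(vol, data=sub, provenance=f"{vol.provenance}[{roi.lo}:{roi.hi}]")
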