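"""Greyscale normalisation: byte scaling and two-point CT scaling.

Reconstructed micro-CT greys are only comparable across scans after
normalisation.  Two schemes are provided:

* **byte scaling** — a global linear rescale of a chosen grey window to
  the 8-bit range 0–255 (used for the gynoecium scans);
* **CT scaling** — a two-point linear calibration against the measured
  mean greys of two reference materials on a dedicated "dummy" scan:
  air, and the 1% PTA/FAA fixative/contrast solution (measured density
  0.937 g ml⁻¹, recorded as metadata only).  Calibrated volumes carry
  float greys; quantisation happens only at file export.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .volume_io import SubsetROI, Volume3D

__all__ = [
    "CalibrationModel",
    "byte_scale",
    "fit_ct_scaling",
    "measure_dummy",
    "apply_ct_scaling",
]

log = logging.getLogger(__name__)

#: default calibrated values assigned to the two reference materials
DEFAULT_AIR_TARGET = 0.0
DEFAULT_REF_TARGET = 1000.0

#: measured density of the 1% PTA/FAA reference solution, g per 100 ml
REF_DENSITY_G_PER_100ML = 93.7


@dataclass(frozen=True)
class CalibrationModel:
    """Linear grey map fixed by two reference materials.

    ``slope`` and ``intercept`` are the unique solution of the 2x2 system
    mapping ``air_grey -> air_target`` and ``ref_grey -> ref_target``.
    """

    air_grey: float
    ref_grey: float
    air_target: float = DEFAULT_AIR_TARGET
    ref_target: float = DEFAULT_REF_TARGET
    slope: float = field(init=False)
    intercept: float = field(init=False)

    def __post_init__(self) -> None:
        if self.air_grey == self.ref_grey:
            raise ValueError("air and reference greys coincide; the linear map is undefined")
        slope = (self.ref_target - self.air_target) / (self.ref_grey - self.air_grey)
        object.__setattr__(self, "slope", slope)
        object.__setattr__(self, "intercept", self.air_target - slope * self.air_grey)

    def __call__(self, v):
        return self.slope * np.asarray(v, dtype=np.float64) + self.intercept


def byte_scale(vol: Volume3D, gmin: float, gmax: float) -> Volume3D:
    """Linearly rescale the grey window ``[gmin, gmax]`` to 0–255.

    Values are clamped to the window, mapped with
    ``(v - gmin) / (gmax - gmin) * 255`` and rounded half-up to integers;
    the result is an 8-bit volume in the ``byte_scaled`` state.
    """
    if gmin >= gmax:
        raise ValueError(f"need gmin < gmax, got gmin={gmin}, gmax={gmax}")
    if vol.calibration_state != "raw":
        raise ValueError(f"volume is already {vol.calibration_state}; byte scaling needs raw greys")
    v = vol.data.astype(np.float64)
    scaled = np.clip((v - gmin) / (gmax - gmin), 0.0, 1.0) * 255.0
    rounded = np.floor(scaled + 0.5).astype(np.uint8)  # round half up
    return vol.with_data(rounded, calibration_state="byte_scaled")


def fit_ct_scaling(
    air_grey: float,
    ref_grey: float,
    air_target: float = DEFAULT_AIR_TARGET,
    ref_target: float = DEFAULT_REF_TARGET,
) -> CalibrationModel:
    """Fit the unique linear grey map through the two reference points."""
    return CalibrationModel(float(air_grey), float(ref_grey), float(air_target), float(ref_target))


def measure_dummy(dummy: Volume3D, air_roi: SubsetROI, ref_roi: SubsetROI) -> tuple[float, float]:
    """Mean grey of the air and reference-liquid compartments of a dummy scan.

    Returns ``(air_grey, ref_grey)`` as arithmetic means over the two
    ROIs.  Overlapping ROIs are permitted (a warning is logged); empty
    ROIs cannot be constructed.
    """
    air_roi.check_within(dummy.shape)
    ref_roi.check_within(dummy.shape)
    if all(al < rh and rl < ah for al, ah, rl, rh in
           zip(air_roi.lo, air_roi.hi, ref_roi.lo, ref_roi.hi)):
        log.warning("air and reference ROIs overlap: %s vs %s", air_roi, ref_roi)
    air_grey = float(np.mean(dummy.data[air_roi.slices], dtype=np.float64))
    ref_grey = float(np.mean(dummy.data[ref_roi.slices], dtype=np.float64))
    return air_grey, ref_grey


def apply_ct_scaling(vol: Volume3D, model: CalibrationModel) -> Volume3D:
    """Apply a fitted CT-scaling model voxelwise (``v -> slope*v + intercept``)."""
    if vol.calibration_state != "raw":
        raise ValueError(f"volume is already {vol.calibration_state}; refusing to re-calibrate")
    return vol.with_data(model(vol.data), calibration_state="ct_scaled")
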