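"""Subset-to-whole counting workflows and the pollen:ovule ratio.

The central estimator is stereological: count objects in a subset where
they are individually resolvable, derive the mean object volume
``v_bar = V_subset / n_subset`` from the segmented foreground volume of
that subset, and extrapolate ``N_total = V_total / v_bar`` to the whole
structure.  Three workflows use it:

* **pollen** — grains are not resolvable on the overview scan of the
  whole pollinium, so the subset count comes from a separate
  high-resolution scan while both volumes are measured on the overview
  scan;
* **ovule** — ovules are resolvable on a single scan of the whole
  ovary, so count and volumes come from the same segmentation (the
  subset count may be supplied manually, mirroring landmark counting);
* **massulae** — the pollinium sub-aggregates are resolvable whole, so
  they are counted directly with massula-scale volume bounds and no
  extrapolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from . import preprocess, segmentation
from .segmentation import LabelMap
from .volume_io import SubsetROI, Volume3D

__all__ = [
    "CountingConfig",
    "CountEstimate",
    "subset_count",
    "mean_object_volume",
    "extrapolate_total",
    "pollen_workflow",
    "ovule_workflow",
    "massulae_workflow",
    "pollen_ovule_ratio",
]

log = logging.getLogger(__name__)

EDGE_RULES = ("centroid", "counting_frame", "all")

#: FlowerRecord column order used in count tables
FLOWER_COLUMNS = ["species", "individual", "position", "strategy",
                  "pollen", "ovules", "massulae", "po"]


@dataclass
class CountingConfig:
    """Pipeline settings shared by the counting workflows.

    ``threshold`` may be a grey value or ``"otsu"``.  ``vmin_um3`` and
    ``vmax_um3`` are the physical object-volume bounds of the
    iterative-threshold split and of object filtering; they are
    specimen-specific and mandatory for real data.
    """

    threshold: float | str = "otsu"
    overview_threshold: float | str | None = None  # defaults to `threshold`
    median_kernel: int = preprocess.DEFAULT_MEDIAN_KERNEL
    gaussian_kernel: int = preprocess.DEFAULT_GAUSSIAN_KERNEL
    gaussian_sigma: float = preprocess.DEFAULT_GAUSSIAN_SIGMA
    connectivity: int = segmentation.DEFAULT_CONNECTIVITY
    vmin_um3: float = 0.0
    vmax_um3: float = np.inf
    step: Optional[float] = None
    criterion: str = segmentation.DEFAULT_CRITERION
    split: str = "iterative"  # "iterative" | "none"
    edge_rule: str = "centroid"
    #: edge rule at the border of a pre-cropped subset scan; fragments of
    #: cut objects lie wholly inside such a scan, which biases the
    #: centroid rule upward, so the unbiased counting frame is the default
    subset_scan_edge_rule: str = "counting_frame"
    #: guard-zone width (µm) for the two-scan pollen workflow: centroids
    #: are counted only at least this far from the subset-scan border and
    #: the subset volume is measured on the matching shrunk window.  With
    #: a guard of at least one maximum object radius the centroid rule is
    #: unbiased; 0 falls back to `subset_scan_edge_rule` on the full frame.
    guard_um: float = 0.0

    @classmethod
    def from_dict(cls, d: dict) -> "CountingConfig":
        """Build from a (possibly nested) config mapping."""
        flat: dict = {}
        for key, val in d.items():
            if key in ("preprocess", "segmentation", "quantify") and isinstance(val, dict):
                flat.update(val)
            else:
                flat[key] = val
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(flat) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**flat)


@dataclass
class CountEstimate:
    """Record of one subset-to-whole extrapolation."""

    workflow: str
    n_subset: int
    v_subset_um3: float
    v_total_um3: float
    v_bar_um3: float
    n_total_raw: float
    n_total: int

    def as_dict(self) -> dict:
        return asdict(self)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def subset_count(lm: LabelMap, roi: SubsetROI, edge_rule: str = "centroid") -> int:
    """Count labelled objects attributed to ``roi`` under an edge rule.

    * ``centroid`` — objects whose centre of mass lies inside the
      half-open box (unbiased under stationary object placement);
    * ``counting_frame`` — objects intersecting the box except those
      touching its three exclusion faces (low-z, low-y, low-x), the
      classical unbiased counting-frame rule;
    * ``all`` — every object intersecting the box.
    """
    if edge_rule not in EDGE_RULES:
        raise ValueError(f"edge_rule must be one of {EDGE_RULES}, got {edge_rule!r}")
    roi.check_within(lm.shape)
    if lm.n_labels == 0:
        return 0
    if edge_rule == "centroid":
        idx = np.arange(1, lm.n_labels + 1)
        from scipy import ndimage
        com = np.asarray(ndimage.center_of_mass(np.ones(lm.shape), lm.labels, idx)).reshape(-1, 3)
        centre = com + 0.5  # continuous voxel coordinate
        lo = np.asarray(roi.lo)
        hi = np.asarray(roi.hi)
        inside = np.all((centre >= lo) & (centre < hi), axis=1)
        return int(inside.sum())

    sub = lm.labels[roi.slices]
    present = np.unique(sub)
    present = present[present > 0]
    if edge_rule == "all":
        return int(present.size)

    # counting_frame: drop objects touching the low-z/low-y/low-x faces of
    # the roi or extending beyond them
    excluded = set()
    for axis in range(3):
        face = [slice(l, h) for l, h in zip(roi.lo, roi.hi)]
        face[axis] = slice(roi.lo[axis], roi.lo[axis] + 1)
        excluded.update(np.unique(lm.labels[tuple(face)]).tolist())
    from scipy import ndimage
    objects = ndimage.find_objects(lm.labels, max_label=lm.n_labels)
    for lab in present:
        sl = objects[int(lab) - 1]
        if sl is None:
            continue
        if any(sl[a].start < roi.lo[a] for a in range(3)):
            excluded.add(int(lab))
    return int(sum(1 for lab in present if int(lab) not in excluded))


def mean_object_volume(v_subset_um3: float, n_subset: int) -> float:
    """Mean object volume ``v_bar = V_subset / n_subset`` in µm³."""
    if n_subset < 1:
        raise ValueError("subset contains no counted objects; the subset is unusable")
    if v_subset_um3 <= 0:
        raise ValueError(f"subset segmented volume must be > 0, got {v_subset_um3}")
    return float(v_subset_um3) / int(n_subset)


def extrapolate_total(v_total_um3: float, v_bar_um3: float) -> tuple[float, int]:
    """Total object number ``V_total / v_bar`` (raw float, half-up integer)."""
    if v_bar_um3 <= 0:
        raise ValueError(f"mean object volume must be > 0, got {v_bar_um3}")
    raw = float(v_total_um3) / float(v_bar_um3)
    return raw, _round_half_up(raw)


# ---------------------------------------------------------------------------
# shared pipeline pieces
# ---------------------------------------------------------------------------

def _preprocess(vol: Volume3D, cfg: CountingConfig, threshold=None):
    """Threshold -> mask -> median -> Gaussian, in the fixed pipeline order."""
    t = preprocess.resolve_threshold(vol, cfg.threshold if threshold is None else threshold)
    mask = preprocess.threshold_grey(vol, t)
    work = preprocess.apply_mask(vol, mask)
    work = preprocess.median3d(work, cfg.median_kernel)
    work = preprocess.gaussian3d(work, cfg.gaussian_kernel, cfg.gaussian_sigma)
    return work, mask


def _segment(vol: Volume3D, cfg: CountingConfig) -> LabelMap:
    work, mask = _preprocess(vol, cfg)
    if cfg.split == "iterative":
        return segmentation.iterative_threshold_split(
            work, cfg.vmin_um3, cfg.vmax_um3, step=cfg.step,
            criterion=cfg.criterion, connectivity=cfg.connectivity, mask=mask.data)
    lm = segmentation.label_components(mask, cfg.connectivity)
    # apply volume bounds by discarding out-of-range components
    tbl = segmentation.object_stats(lm)
    v = tbl["volume_um3"].to_numpy()
    keep = np.flatnonzero((v >= cfg.vmin_um3) & (v <= cfg.vmax_um3)) + 1
    lut = np.zeros(lm.n_labels + 1, dtype=np.int32)
    lut[keep] = np.arange(1, keep.size + 1, dtype=np.int32)
    return LabelMap(lut[lm.labels], lm.spacing, int(keep.size))


def _foreground_volume(vol: Volume3D, cfg: CountingConfig, roi: SubsetROI | None,
                       threshold=None) -> float:
    """Thresholded foreground volume (µm³), optionally restricted to a roi."""
    t = preprocess.resolve_threshold(vol, cfg.threshold if threshold is None else threshold)
    data = vol.data if roi is None else vol.data[roi.slices]
    return float((np.asarray(data) >= t).sum()) * vol.voxel_volume_um3


def _guarded_centroid_count(lm: LabelMap, roi_ov: SubsetROI,
                            spacing_ov, guard_um: float) -> tuple[int, SubsetROI]:
    """Centroid count inside a guard-shrunk window of a subset scan.

    The guarded window is first snapped to whole overview voxels (so the
    matching subset-volume measurement uses exactly the same physical
    box) and then expressed in µm in the subset scan's frame.
    """
    spacing_ov = np.asarray(spacing_ov, dtype=float)
    shrink = np.ceil(guard_um / spacing_ov).astype(int)
    lo = np.asarray(roi_ov.lo) + shrink
    hi = np.asarray(roi_ov.hi) - shrink
    if np.any(lo >= hi):
        raise ValueError(f"guard of {guard_um} µm leaves an empty subset window")
    roi_inner = SubsetROI(tuple(lo), tuple(hi))
    lo_um = (lo - np.asarray(roi_ov.lo)) * spacing_ov
    hi_um = (hi - np.asarray(roi_ov.lo)) * spacing_ov
    tbl = segmentation.object_stats(lm)
    if len(tbl) == 0:
        return 0, roi_inner
    cent = tbl[["centroid_z_um", "centroid_y_um", "centroid_x_um"]].to_numpy()
    inside = np.all((cent >= lo_um) & (cent < hi_um), axis=1)
    return int(inside.sum()), roi_inner


# ---------------------------------------------------------------------------
# workflows
# ---------------------------------------------------------------------------

def pollen_workflow(highres: Volume3D, overview: Volume3D,
                    roi_in_overview: SubsetROI, cfg: CountingConfig) -> CountEstimate:
    """Two-scan counting when objects are unresolvable on the overview scan.

    The grain count comes from the high-resolution scan of the subset;
    both the subset's and the whole pollinium's segmented pollen volume
    are measured on the overview scan, so the mean grain volume and the
    extrapolation share one volumetric frame.
    """
    roi_in_overview.check_within(overview.shape)
    lm = _segment(highres, cfg)
    ov_t = cfg.overview_threshold if cfg.overview_threshold is not None else cfg.threshold
    v_total = _foreground_volume(overview, cfg, None, threshold=ov_t)
    if v_total <= 0:
        raise ValueError("overview scan has zero segmented foreground")
    if cfg.guard_um > 0:
        n_subset, roi_inner = _guarded_centroid_count(lm, roi_in_overview,
                                                      overview.spacing, cfg.guard_um)
        v_subset = _foreground_volume(overview, cfg, roi_inner, threshold=ov_t)
    else:
        n_subset = subset_count(lm, SubsetROI.full(lm.shape), cfg.subset_scan_edge_rule)
        v_subset = _foreground_volume(overview, cfg, roi_in_overview, threshold=ov_t)
    v_bar = mean_object_volume(v_subset, n_subset)
    raw, rounded = extrapolate_total(v_total, v_bar)
    log.info("pollen workflow: n_subset=%d v_subset=%.4g v_total=%.4g -> N=%d",
             n_subset, v_subset, v_total, rounded)
    return CountEstimate("pollen", n_subset, v_subset, v_total, v_bar, raw, rounded)


def ovule_workflow(vol: Volume3D, roi: SubsetROI, cfg: CountingConfig,
                   manual_n_subset: Optional[int] = None) -> CountEstimate:
    """Single-scan counting when objects are resolvable on the whole scan.

    ``manual_n_subset`` replaces the automatic subset count with an
    operator-supplied landmark count of the same subset.
    """
    roi.check_within(vol.shape)
    lm = _segment(vol, cfg)
    n_subset = (int(manual_n_subset) if manual_n_subset is not None
                else subset_count(lm, roi, cfg.edge_rule))
    seg_fg = lm.labels > 0
    voxvol = vol.voxel_volume_um3
    v_total = float(seg_fg.sum()) * voxvol
    v_subset = float(seg_fg[roi.slices].sum()) * voxvol
    v_bar = mean_object_volume(v_subset, n_subset)
    raw, rounded = extrapolate_total(v_total, v_bar)
    return CountEstimate("ovule", n_subset, v_subset, v_total, v_bar, raw, rounded)


def massulae_workflow(vol: Volume3D, cfg: CountingConfig) -> int:
    """Direct count of massula-scale components (no extrapolation)."""
    lm = _segment(vol, cfg)
    tbl = segmentation.object_stats(lm)
    return segmentation.count_objects(tbl, cfg.vmin_um3, cfg.vmax_um3)


def pollen_ovule_ratio(pollen: float, ovule: float) -> float:
    """Per-flower P:O; defined only for a positive ovule count."""
    if ovule <= 0:
        raise ValueError("P:O is undefined for a zero ovule count")
    if pollen < 0:
        raise ValueError("pollen count must be >= 0")
    return float(pollen) / float(ovule)
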