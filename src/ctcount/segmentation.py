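"""Object separation and counting in 3D.

Two complementary counters:

* :func:`label_components` — plain 3D connected-component labelling, for
  objects that are already spatially separate (ovules, massulae).
* :func:`iterative_threshold_split` — separation of mutually touching
  objects (pollen grains in a pollinium) by a descending threshold
  sweep.  Bright object cores appear as separate components at high
  thresholds and merge as the threshold drops; the sweep maintains the
  component merge-tree and validates each object on its branch at the
  threshold where its volume lies inside configured physical bounds
  ``[vmin, vmax]`` (µm³) and is most stable between consecutive
  thresholds (MSER-style).  When a merged component and the components
  it swallowed both validate, the children win, splitting fused objects.

Per-object statistics (voxel count, µm³ volume, centroid, bounding box,
mean intensity) are collected in an :class:`ObjectTable`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume_io import Volume3D

__all__ = [
    "LabelMap",
    "connectivity_structure",
    "label_components",
    "iterative_threshold_split",
    "object_stats",
    "count_objects",
]

log = logging.getLogger(__name__)

DEFAULT_CONNECTIVITY = 26
DEFAULT_CRITERION = "volume_stability"


@dataclass
class LabelMap:
    """Integer-labelled volume; 0 is background, objects are 1..n_labels."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    n_labels: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label map must be integer typed")

    @property
    def shape(self):
        return self.labels.shape

    @property
    def voxel_volume_um3(self) -> float:
        sz, sy, sx = self.spacing
        return sz * sy * sx


def connectivity_structure(connectivity: int) -> np.ndarray:
    """3D adjacency footprint: 6 (faces) or 26 (faces+edges+vertices)."""
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")


def label_components(mask, connectivity: int = DEFAULT_CONNECTIVITY,
                     spacing: tuple[float, float, float] | None = None) -> LabelMap:
    """Label connected foreground components (raster-scan label order)."""
    data = np.asarray(getattr(mask, "data", mask), dtype=bool)
    if spacing is None:
        spacing = getattr(mask, "spacing", (1.0, 1.0, 1.0))
    labels, n = ndimage.label(data, structure=connectivity_structure(connectivity))
    return LabelMap(labels.astype(np.int32), tuple(spacing), int(n))


# ---------------------------------------------------------------------------
# iterative-threshold split
# ---------------------------------------------------------------------------

@dataclass
class _Branch:
    """One region track of the merge-tree across the threshold sweep."""

    bid: int
    seed: tuple  # voxel (z, y, x) of the region's brightest voxel
    children: List[int] = field(default_factory=list)
    merged_into: Optional[int] = None
    thresholds: List[float] = field(default_factory=list)
    counts: List[int] = field(default_factory=list)
    #: voxel count of the merged children at the last threshold before this
    #: branch was created by a merge (None for branches born from nothing)
    merge_base: Optional[int] = None
    sel_threshold: Optional[float] = None
    sel_count: Optional[int] = None


def _sweep_thresholds(data: np.ndarray, fg: np.ndarray, step: Optional[float]) -> np.ndarray:
    vals = data[fg]
    vmax_g = float(vals.max())
    vmin_g = float(vals.min())
    if step is None:
        step = 1.0 if np.issubdtype(data.dtype, np.integer) else max((vmax_g - vmin_g) / 255.0, 1e-12)
    if step <= 0:
        raise ValueError(f"threshold step must be > 0, got {step}")
    if vmax_g == vmin_g:
        return np.array([vmin_g])
    ts = np.arange(vmax_g, vmin_g, -step)
    if ts[-1] > vmin_g:
        ts = np.append(ts, vmin_g)
    return ts


def _select_stable_level(br: _Branch, valid: np.ndarray) -> None:
    """Pick the validated level with the smallest relative volume change.

    The change at level i compares to the previous (higher) threshold;
    at a merge node the previous volume is the children's combined
    volume.  Ties resolve to the higher threshold (favours splitting).
    """
    counts = np.asarray(br.counts, dtype=np.float64)
    prev = np.empty_like(counts)
    prev[1:] = counts[:-1]
    prev[0] = br.merge_base if br.merge_base is not None else np.nan
    with np.errstate(invalid="ignore"):
        stability = (counts - prev) / counts
    stability[np.isnan(stability)] = np.inf  # appearance level: no reference
    if valid.sum() == 1:
        idx = int(np.flatnonzero(valid)[0])
    else:
        cand = np.flatnonzero(valid)
        idx = int(cand[np.argmin(stability[cand])])  # argmin keeps first=highest t
    br.sel_threshold = br.thresholds[idx]
    br.sel_count = br.counts[idx]


def iterative_threshold_split(
    vol: Volume3D,
    vmin: float,
    vmax: float,
    step: Optional[float] = None,
    criterion: str = DEFAULT_CRITERION,
    connectivity: int = DEFAULT_CONNECTIVITY,
    mask: Optional[np.ndarray] = None,
) -> LabelMap:
    """Separate touching bright objects by a descending threshold sweep.

    Parameters
    ----------
    vol
        Masked greyscale volume (background already zeroed by the
        preprocessing threshold).
    vmin, vmax
        Physical volume bounds in µm³; an object validates only while
        its component volume lies inside ``[vmin, vmax]``.
    step
        Threshold decrement; default 1 grey level for integer volumes,
        (max-min)/255 for float volumes.
    criterion
        ``"volume_stability"`` — per-branch MSER-style selection of the
        most volume-stable threshold; ``"max_count"`` — single global
        threshold maximising the number of in-range components.
    mask
        Foreground restriction; defaults to ``vol.data > 0``.
    """
    if vmin >= vmax:
        raise ValueError(f"need vmin < vmax, got vmin={vmin}, vmax={vmax}")
    if criterion not in ("volume_stability", "max_count"):
        raise ValueError(f"unknown criterion {criterion!r}")
    data = np.asarray(vol.data)
    fg = (data > 0) if mask is None else (np.asarray(mask, dtype=bool) & np.isfinite(data))
    if not fg.any():
        raise ValueError("empty foreground: nothing to separate")
    structure = connectivity_structure(connectivity)
    voxvol = vol.voxel_volume_um3
    cmin = vmin / voxvol  # volume bounds in voxel counts
    cmax = vmax / voxvol
    thresholds = _sweep_thresholds(data, fg, step)

    if criterion == "max_count":
        return _split_max_count(vol, data, fg, structure, thresholds, cmin, cmax)

    branches: List[_Branch] = []
    prev_branch_of_label: np.ndarray = np.empty(0, dtype=np.int64)  # prev label -> branch id
    prev_nlab = 0
    seeds_z = np.empty(0, dtype=np.int64)
    seeds_y = np.empty(0, dtype=np.int64)
    seeds_x = np.empty(0, dtype=np.int64)

    for t in thresholds:
        cur_mask = fg & (data >= t)
        labels, nlab = ndimage.label(cur_mask, structure=structure)
        if nlab == 0:
            continue
        counts = np.bincount(labels.ravel(), minlength=nlab + 1)

        # map every live branch (all of them: components only grow) to its
        # current component via its seed voxel
        if prev_nlab:
            cur_of_prev = labels[seeds_z, seeds_y, seeds_x]
        else:
            cur_of_prev = np.empty(0, dtype=np.int64)

        # group prev branches by current label
        groups: dict[int, list[int]] = {}
        for b_idx, L in zip(prev_branch_of_label, cur_of_prev):
            groups.setdefault(int(L), []).append(int(b_idx))

        branch_of_label = np.zeros(nlab + 1, dtype=np.int64)
        new_labels = [L for L in range(1, nlab + 1) if L not in groups]
        if new_labels:
            # deterministic seed: first (raster-order) voxel of the component
            flat = labels.ravel()
            idx = np.flatnonzero(flat)
            first = np.zeros(nlab + 1, dtype=np.int64)
            first[flat[idx[::-1]]] = idx[::-1]
        for L in new_labels:
            bid = len(branches)
            seed = tuple(int(c) for c in np.unravel_index(first[L], labels.shape))
            branches.append(_Branch(bid, seed,
                                    thresholds=[t], counts=[int(counts[L])]))
            branch_of_label[L] = bid
        for L, members in groups.items():
            if len(members) == 1:
                bid = members[0]
                br = branches[bid]
                br.thresholds.append(t)
                br.counts.append(int(counts[L]))
            else:
                bid = len(branches)
                base = sum(branches[m].counts[-1] for m in members)
                br = _Branch(bid, branches[members[0]].seed, children=list(members),
                             thresholds=[t], counts=[int(counts[L])], merge_base=base)
                branches.append(br)
                for m in members:
                    branches[m].merged_into = bid
            branch_of_label[L] = bid

        live = np.unique(branch_of_label[1:])
        prev_branch_of_label = live
        sz = np.array([branches[b].seed for b in live], dtype=np.int64).reshape(-1, 3)
        seeds_z, seeds_y, seeds_x = sz[:, 0], sz[:, 1], sz[:, 2]
        prev_nlab = nlab

    # validate branches against the physical volume bounds
    for br in branches:
        valid = (np.asarray(br.counts) >= cmin) & (np.asarray(br.counts) <= cmax)
        if valid.any():
            _select_stable_level(br, valid)

    # children win over a validated parent: collect the deepest validated
    # branches of each root's subtree
    selected: List[_Branch] = []

    def collect(bid: int) -> List[_Branch]:
        br = branches[bid]
        got: List[_Branch] = []
        for c in br.children:
            got.extend(collect(c))
        if got:
            return got
        return [br] if br.sel_threshold is not None else []

    import sys
    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, len(branches) + 100))
    try:
        for br in branches:
            if br.merged_into is None:
                selected.extend(collect(br.bid))
    finally:
        sys.setrecursionlimit(old_limit)

    return _render_selection(vol, data, fg, structure, selected)


def _render_selection(vol, data, fg, structure, selected: Sequence[_Branch]) -> LabelMap:
    """Rasterise the selected branches at their selected thresholds."""
    out = np.zeros(data.shape, dtype=np.int32)
    if not selected:
        return LabelMap(out, vol.spacing, 0)
    # deterministic output ids: by seed raster position
    order = sorted(selected, key=lambda b: b.seed)
    ids = {b.bid: i + 1 for i, b in enumerate(order)}
    by_t: dict[float, list[_Branch]] = {}
    for b in order:
        by_t.setdefault(b.sel_threshold, []).append(b)
    for t, group in sorted(by_t.items(), reverse=True):
        labels, nlab = ndimage.label(fg & (data >= t), structure=structure)
        lut = np.zeros(nlab + 1, dtype=np.int32)
        for b in group:
            lut[labels[b.seed]] = ids[b.bid]
        sel = lut[labels]
        np.copyto(out, sel, where=sel > 0)
    return LabelMap(out, vol.spacing, len(order))


def _split_max_count(vol, data, fg, structure, thresholds, cmin, cmax) -> LabelMap:
    """Global threshold maximising the number of in-range components."""
    best_t, best_n = None, -1
    for t in thresholds:
        labels, nlab = ndimage.label(fg & (data >= t), structure=structure)
        if nlab == 0:
            continue
        counts = np.bincount(labels.ravel(), minlength=nlab + 1)[1:]
        n_ok = int(((counts >= cmin) & (counts <= cmax)).sum())
        if n_ok > best_n:  # strict: ties keep the higher threshold
            best_t, best_n = t, n_ok
    out = np.zeros(data.shape, dtype=np.int32)
    if best_t is None or best_n <= 0:
        return LabelMap(out, vol.spacing, 0)
    labels, nlab = ndimage.label(fg & (data >= best_t), structure=structure)
    counts = np.bincount(labels.ravel(), minlength=nlab + 1)
    keep = np.flatnonzero((counts >= cmin) & (counts <= cmax))
    keep = keep[keep > 0]
    lut = np.zeros(nlab + 1, dtype=np.int32)
    lut[keep] = np.arange(1, keep.size + 1, dtype=np.int32)
    out = lut[labels]
    return LabelMap(out, vol.spacing, int(keep.size))


# ---------------------------------------------------------------------------
# per-object statistics
# ---------------------------------------------------------------------------

def object_stats(lm: LabelMap, vol: Optional[Volume3D] = None) -> pd.DataFrame:
    """Per-object statistics table (one row per label).

    Columns: ``label``, ``voxel_count``, ``volume_um3`` (voxel count x
    voxel volume), centroid in µm (physical centre of mass of the voxel
    centres, volume frame), voxel bounding box (half-open), and
    ``mean_intensity`` (NaN when no greyscale volume is supplied).
    """
    if vol is not None and vol.shape != lm.shape:
        raise ValueError(f"volume shape {vol.shape} != label shape {lm.shape}")
    n = lm.n_labels
    cols = ["label", "voxel_count", "volume_um3",
            "centroid_z_um", "centroid_y_um", "centroid_x_um",
            "bbox_z0", "bbox_y0", "bbox_x0", "bbox_z1", "bbox_y1", "bbox_x1",
            "mean_intensity"]
    if n == 0:
        return pd.DataFrame(columns=cols)
    idx = np.arange(1, n + 1)
    counts = np.bincount(lm.labels.ravel(), minlength=n + 1)[1:]
    voxvol = lm.voxel_volume_um3
    com = np.asarray(ndimage.center_of_mass(np.ones(lm.shape), lm.labels, idx))
    spacing = np.asarray(lm.spacing)
    cent = (com + 0.5) * spacing  # voxel centres in µm
    objects = ndimage.find_objects(lm.labels, max_label=n)
    bbox = np.array([
        [sl[0].start, sl[1].start, sl[2].start, sl[0].stop, sl[1].stop, sl[2].stop]
        if sl is not None else [0, 0, 0, 0, 0, 0]
        for sl in objects
    ])
    if vol is not None:
        mean_int = np.asarray(ndimage.mean(vol.data, lm.labels, idx), dtype=np.float64)
    else:
        mean_int = np.full(n, np.nan)
    return pd.DataFrame({
        "label": idx,
        "voxel_count": counts,
        "volume_um3": counts * voxvol,
        "centroid_z_um": cent[:, 0], "centroid_y_um": cent[:, 1], "centroid_x_um": cent[:, 2],
        "bbox_z0": bbox[:, 0], "bbox_y0": bbox[:, 1], "bbox_x0": bbox[:, 2],
        "bbox_z1": bbox[:, 3], "bbox_y1": bbox[:, 4], "bbox_x1": bbox[:, 5],
        "mean_intensity": mean_int,
    })


def count_objects(tbl: pd.DataFrame, vmin: float = 0.0, vmax: float = np.inf) -> int:
    """Number of objects whose µm³ volume lies in ``[vmin, vmax]``."""
    if vmin > vmax:
        raise ValueError(f"need vmin <= vmax, got {vmin} > {vmax}")
    if len(tbl) == 0:
        return 0
    v = tbl["volume_um3"].to_numpy()
    return int(((v >= vmin) & (v <= vmax)).sum())
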