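"""Phantom generators with exact ground truth.

The real specimens behind the counting method are not reproducible, so
validation rests on CT-like phantoms: pollinium-like packings of
thousands of touching quasi-spherical grains (optionally clustered into
unequal massulae — a few large and many small), ovary-like volumes with
ovules strung along a cylindrical placenta (optionally with a contiguous
spatial gap), and two-compartment calibration dummies.  Rendering
mimics a reconstructed scan: solid spheres at a foreground grey,
Gaussian point-spread blur, additive Gaussian noise (CT reconstruction
noise is approximately Gaussian after filtering) and optional linear
shading.  Every generator is a pure function of its spec and seed, and
ground-truth counts are exact by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume_io import Volume3D

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "generate_pollinium",
    "generate_ovary",
    "generate_dummy",
    "generate_flower_table",
    "DEFAULT_SPECIES_PARAMS",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a rendered sphere-packing phantom.

    Distances are physical (µm); the grid is ``shape`` voxels at
    ``spacing`` µm per voxel (z, y, x).
    """

    n_objects: int = 500
    radius_mean_um: float = 4.0
    radius_cv: float = 0.15
    mode: str = "touching"  # loose | touching | massulae
    n_massulae: int = 12
    massula_sigma_log: float = 0.8  # lognormal shape: few large + many small
    shape: tuple[int, int, int] = (128, 128, 128)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    psf_sigma_um: float = 1.0
    noise_sd: float = 18.0
    foreground_grey: float = 200.0
    background_grey: float = 20.0
    gradient: float = 0.0  # relative linear shading along z (+/- fraction)
    max_overlap_frac: float = 0.05  # allowed centre-distance shortfall
    packing_fraction: float = 0.30  # target solid fraction of the container
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_objects < 1:
            raise ValueError("n_objects must be >= 1")
        for name in ("radius_mean_um", "psf_sigma_um"):
            if getattr(self, name) < 0 or (name == "radius_mean_um" and getattr(self, name) <= 0):
                raise ValueError(f"{name} must be positive")
        if self.mode not in ("loose", "touching", "massulae"):
            raise ValueError(f"unknown aggregation mode {self.mode!r}")
        if not 0 < self.packing_fraction < 0.5:
            raise ValueError("packing_fraction must lie in (0, 0.5)")


@dataclass
class GroundTruth:
    """Exact description of the generated objects."""

    centres_um: np.ndarray  # (n, 3), z/y/x in µm
    radii_um: np.ndarray
    massula_id: np.ndarray  # cluster membership (0-based; -1 when unclustered)

    @property
    def count(self) -> int:
        return int(len(self.radii_um))

    @property
    def total_volume_um3(self) -> float:
        return float(np.sum(4.0 / 3.0 * np.pi * self.radii_um ** 3))


# ---------------------------------------------------------------------------
# sphere packing
# ---------------------------------------------------------------------------

class _CellGrid:
    """Uniform-grid neighbour lookup for sequential sphere packing."""

    def __init__(self, cell: float):
        self.cell = float(cell)
        self.cells: dict[tuple[int, int, int], list[int]] = {}
        self.centres: list[np.ndarray] = []
        self.radii: list[float] = []

    def _key(self, p):
        return tuple(int(np.floor(c / self.cell)) for c in p)

    def ok(self, p: np.ndarray, r: float, min_gap_frac: float) -> bool:
        kz, ky, kx = self._key(p)
        for dz in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    for i in self.cells.get((kz + dz, ky + dy, kx + dx), ()):
                        d = np.linalg.norm(p - self.centres[i])
                        if d < (r + self.radii[i]) * min_gap_frac:
                            return False
        return True

    def add(self, p: np.ndarray, r: float) -> None:
        self.cells.setdefault(self._key(p), []).append(len(self.centres))
        self.centres.append(p)
        self.radii.append(r)


def _sample_radii(rng: np.random.Generator, n: int, mean: float, cv: float) -> np.ndarray:
    r = rng.normal(mean, cv * mean, size=n)
    return np.clip(r, 0.2 * mean, None)


def _pack_in_ball(rng, n, radii, centre, container_r, min_dist_frac,
                  grid: Optional[_CellGrid] = None, tries_per_obj: int = 4000):
    """Random sequential addition of spheres inside a spherical container.

    Spheres are placed largest-first, which markedly raises the density
    random sequential addition can reach.
    """
    if grid is None:
        grid = _CellGrid(cell=2.2 * float(np.max(radii)))
    placed = []
    # fixed margin for every sphere: a radius-dependent margin would
    # enrich the wall layer in small objects and break the stationarity
    # that subset extrapolation relies on
    rmax = float(np.max(radii[:n]))
    for r in sorted((float(r) for r in radii[:n]), reverse=True):
        for _ in range(tries_per_obj):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            rad = max(container_r - rmax, 0.0) * rng.random() ** (1.0 / 3.0)
            p = centre + u * rad
            if grid.ok(p, r, min_dist_frac):
                grid.add(p, r)
                placed.append((p, r))
                break
        else:
            break  # retry budget exhausted
    return placed, grid


def _pack_in_box(rng, n, radii, lo, hi, min_dist_frac, tries_per_obj: int = 4000):
    """Largest-first random sequential addition inside an axis-aligned box."""
    grid = _CellGrid(cell=2.2 * float(np.max(radii)))
    placed = []
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    rmax = float(np.max(radii[:n]))  # fixed margin: keeps placement stationary
    for r in sorted((float(r) for r in radii[:n]), reverse=True):
        for _ in range(tries_per_obj):
            p = lo + rmax + rng.random(3) * (hi - lo - 2 * rmax)
            if grid.ok(p, r, min_dist_frac):
                grid.add(p, r)
                placed.append((p, r))
                break
        else:
            break
    return placed, grid


def _container_radius(radii: np.ndarray, packing_fraction: float) -> float:
    total = np.sum(4.0 / 3.0 * np.pi * radii ** 3)
    return float((total / packing_fraction * 3.0 / (4.0 * np.pi)) ** (1.0 / 3.0))


def _render(spec: PhantomSpec, centres: np.ndarray, radii: np.ndarray,
            rng: np.random.Generator, provenance: str) -> Volume3D:
    """Rasterise spheres, blur with the PSF, shade, add noise."""
    shape = tuple(int(s) for s in spec.shape)
    spacing = np.asarray(spec.spacing, dtype=np.float64)
    img = np.full(shape, float(spec.background_grey), dtype=np.float32)
    fg = float(spec.foreground_grey)
    for p, r in zip(centres, radii):
        lo = np.maximum(np.floor((p - r) / spacing).astype(int), 0)
        hi = np.minimum(np.ceil((p + r) / spacing).astype(int) + 1, shape)
        if np.any(lo >= hi):
            continue
        zz, yy, xx = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        d2 = (((zz + 0.5) * spacing[0] - p[0]) ** 2
              + ((yy + 0.5) * spacing[1] - p[1]) ** 2
              + ((xx + 0.5) * spacing[2] - p[2]) ** 2)
        box = img[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        box[d2 <= r * r] = fg
    if spec.psf_sigma_um > 0:
        sigma_vox = spec.psf_sigma_um / spacing
        img = ndimage.gaussian_filter(img, sigma=sigma_vox, mode="nearest")
    if spec.gradient:
        shade = 1.0 + spec.gradient * (np.arange(shape[0]) / max(shape[0] - 1, 1) - 0.5)
        img = img * shade[:, None, None].astype(np.float32)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=shape).astype(np.float32)
    return Volume3D(img.astype(np.float32), tuple(spec.spacing), provenance=provenance)


def _finish(spec: PhantomSpec, placed, rng, provenance, massula_id=None):
    centres = np.array([p for p, _ in placed]).reshape(-1, 3)
    radii = np.array([r for _, r in placed])
    n = len(placed)
    if n < spec.n_objects:
        log.warning("packing budget exhausted: placed %d of %d objects", n, spec.n_objects)
    if massula_id is None:
        massula_id = np.full(n, -1, dtype=int)
    vol = _render(spec, centres, radii, rng, provenance)
    return vol, GroundTruth(centres, radii, np.asarray(massula_id[:n]))


def generate_pollinium(spec: PhantomSpec) -> tuple[Volume3D, GroundTruth]:
    """Pollinium-like phantom: many mutually touching grains in one mass.

    ``loose`` mode keeps grains clearly separated (low packing
    fraction, enforced gap); ``touching`` packs them densely, allowing
    tangency and at most ``max_overlap_frac`` centre-distance overlap;
    ``massulae`` first samples cluster centres with lognormal sizes
    (a few large and many small sub-aggregates) and then packs grains
    within each cluster.
    """
    rng = np.random.default_rng(spec.seed)
    shape_um = np.asarray(spec.shape) * np.asarray(spec.spacing)
    centre = shape_um / 2.0
    radii = _sample_radii(rng, spec.n_objects, spec.radius_mean_um, spec.radius_cv)

    if spec.mode == "loose":
        # separated grains spread through the whole volume (enforced gap)
        margin = spec.radius_mean_um + 3 * spec.psf_sigma_um
        placed, _ = _pack_in_box(rng, spec.n_objects, radii,
                                 lo=np.full(3, margin), hi=shape_um - margin,
                                 min_dist_frac=1.25)
        return _finish(spec, placed, rng, f"pollinium-loose-seed{spec.seed}")
    min_frac, packing = 1.0 - spec.max_overlap_frac, spec.packing_fraction

    if spec.mode == "massulae":
        weights = rng.lognormal(mean=0.0, sigma=spec.massula_sigma_log, size=spec.n_massulae)
        counts = np.maximum(np.round(weights / weights.sum() * spec.n_objects).astype(int), 1)
        while counts.sum() > spec.n_objects:
            counts[np.argmax(counts)] -= 1
        counts[np.argmax(counts)] += spec.n_objects - counts.sum()
        cluster_r = np.array([
            _container_radius(radii[:c], packing) for c in counts
        ])
        placed_all, massula_id = [], []
        grid = _CellGrid(cell=2.2 * float(np.max(radii)))
        order = np.argsort(-cluster_r)  # large clusters first
        big = _container_radius(radii, packing * 0.45)
        starts = np.concatenate([[0], np.cumsum(counts)])
        accepted: list[tuple[np.ndarray, float]] = []
        for k in order:
            # rejection-sample a cluster centre keeping clusters mostly
            # disjoint (massulae touch, so mild interpenetration is allowed)
            best, best_score = centre, -np.inf
            for _ in range(500):
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                c = centre + u * max(big - cluster_r[k], 0.0) * rng.random() ** (1 / 3)
                score = min((np.linalg.norm(c - c2) - 0.85 * (cluster_r[k] + r2)
                             for c2, r2 in accepted), default=np.inf)
                if score >= 0:
                    best = c
                    break
                if score > best_score:
                    best_score, best = score, c
            accepted.append((best, cluster_r[k]))
            sub_radii = radii[starts[k]:starts[k] + counts[k]]
            placed, grid = _pack_in_ball(rng, counts[k], sub_radii, best,
                                         cluster_r[k], min_frac, grid=grid)
            placed_all.extend(placed)
            massula_id.extend([int(k)] * len(placed))
        return _finish(spec, placed_all, rng, f"pollinium-massulae-seed{spec.seed}",
                       np.asarray(massula_id))

    container_r = _container_radius(radii, packing)
    max_r = float(shape_um.min()) / 2.0 - spec.radius_mean_um - 3 * spec.psf_sigma_um
    if container_r > max_r:
        raise ValueError(
            f"objects do not fit: container radius {container_r:.1f} µm exceeds "
            f"available {max_r:.1f} µm — reduce n_objects or radius")
    placed, _ = _pack_in_ball(rng, spec.n_objects, radii, centre, container_r, min_frac)
    return _finish(spec, placed, rng, f"pollinium-{spec.mode}-seed{spec.seed}")


def generate_ovary(spec: PhantomSpec, gap_fraction: float = 0.0) -> tuple[Volume3D, GroundTruth]:
    """Ovary-like phantom: ovules along a cylindrical placenta.

    Ovule centres are uniform along the cylinder axis except inside one
    contiguous gap covering ``gap_fraction`` of its length (emulating
    the patchy ovule distributions seen in gynoecia of top flowers).
    """
    if not 0 <= gap_fraction < 1:
        raise ValueError("gap_fraction must lie in [0, 1)")
    rng = np.random.default_rng(spec.seed)
    shape_um = np.asarray(spec.shape) * np.asarray(spec.spacing)
    radii = _sample_radii(rng, spec.n_objects, spec.radius_mean_um, spec.radius_cv)
    margin = spec.radius_mean_um * 2.0 + 3 * spec.psf_sigma_um
    z0, z1 = margin, shape_um[0] - margin
    if z1 <= z0:
        raise ValueError("volume too small for the placenta model")
    gap_len = gap_fraction * (z1 - z0)
    gap_start = z0 + rng.random() * ((z1 - z0) - gap_len) if gap_fraction > 0 else z0
    placenta_r = min(shape_um[1], shape_um[2]) / 2.0 - margin
    grid = _CellGrid(cell=2.2 * float(np.max(radii)))
    placed = []
    for i in range(spec.n_objects):
        r = float(radii[i])
        for _ in range(4000):
            z = z0 + rng.random() * (z1 - z0)
            if gap_fraction > 0 and gap_start <= z < gap_start + gap_len:
                continue
            ang = rng.random() * 2 * np.pi
            rad = placenta_r * np.sqrt(rng.random())
            p = np.array([z, shape_um[1] / 2 + rad * np.cos(ang),
                          shape_um[2] / 2 + rad * np.sin(ang)])
            # ovules are resolvable by premise: enforce the same clear
            # separation as loose grain packing
            if grid.ok(p, r, 1.25):
                grid.add(p, r)
                placed.append((p, r))
                break
        else:
            break
    return _finish(spec, placed, rng, f"ovary-seed{spec.seed}")


def generate_dummy(air_grey: float, ref_grey: float, noise: float = 0.0,
                   shape: tuple[int, int, int] = (32, 64, 64),
                   seed: int = 0) -> Volume3D:
    """Calibration dummy: a cylinder of reference liquid surrounded by air."""
    if air_grey == ref_grey:
        raise ValueError("air and reference greys must be distinct")
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    r = 0.30 * min(ny, nx)
    inside = ((yy - ny / 2.0 + 0.5) ** 2 + (xx - nx / 2.0 + 0.5) ** 2) <= r * r
    img = np.where(inside, float(ref_grey), float(air_grey))[None, :, :]
    img = np.repeat(img, nz, axis=0)
    if noise > 0:
        img = img + rng.normal(0.0, noise, size=img.shape)
    return Volume3D(img.astype(np.float64), (1.0, 1.0, 1.0), provenance=f"dummy-seed{seed}")


# ---------------------------------------------------------------------------
# per-flower count tables
# ---------------------------------------------------------------------------

#: per-species generating parameters emulating the eight-species study:
#: species means and group sizes follow the published per-species summary
#: table (five deceptive, three rewarding Orchidinae; two to four
#: inflorescences x three flower positions per species).
DEFAULT_SPECIES_PARAMS = [
    dict(species="Anacamptis_morio", strategy="deceptive", pollen_mean=104817, pollen_sd=7856, ovule_mean=7347, ovule_sd=2856, n_inflorescences=3),
    dict(species="Anacamptis_pyramidalis", strategy="deceptive", pollen_mean=74013, pollen_sd=6808, ovule_mean=3435, ovule_sd=769, n_inflorescences=4),
    dict(species="Dactylorhiza_fuchsii", strategy="rewarding", pollen_mean=51917, pollen_sd=9982, ovule_mean=2659, ovule_sd=925, n_inflorescences=3),
    dict(species="Dactylorhiza_incarnata", strategy="deceptive", pollen_mean=79113, pollen_sd=7809, ovule_mean=6715, ovule_sd=2806, n_inflorescences=4),
    dict(species="Dactylorhiza_majalis", strategy="deceptive", pollen_mean=72050, pollen_sd=7659, ovule_mean=4528, ovule_sd=1576, n_inflorescences=4),
    dict(species="Dactylorhiza_viridis", strategy="rewarding", pollen_mean=35588, pollen_sd=7985, ovule_mean=1413, ovule_sd=464, n_inflorescences=4),
    dict(species="Orchis_militaris", strategy="deceptive", pollen_mean=176417, pollen_sd=63838, ovule_mean=12616, ovule_sd=3429, n_inflorescences=3),
    dict(species="Platanthera_bifolia", strategy="rewarding", pollen_mean=215978, pollen_sd=62919, ovule_mean=3779, ovule_sd=1259, n_inflorescences=2),
]

POSITIONS = ("bottom", "middle", "top")

#: multiplicative position effects (bottom, middle, top); ovule numbers
#: decline towards the top of the inflorescence, pollen does not.
DEFAULT_OVULE_POSITION_EFFECT = (1.30, 1.0, 0.70)
DEFAULT_POLLEN_POSITION_EFFECT = (1.0, 1.0, 1.0)


def generate_flower_table(
    species_params=None,
    ovule_position_effect=DEFAULT_OVULE_POSITION_EFFECT,
    pollen_position_effect=DEFAULT_POLLEN_POSITION_EFFECT,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic per-flower count table (FlowerRecord rows).

    Per-flower pollen and ovule counts are drawn from per-species normal
    distributions (truncated at 1) whose means are modulated by the
    position multipliers; each inflorescence contributes one flower per
    position.  The generating parameters are the ground-truth effect
    sizes for statistical calibration tests.
    """
    if species_params is None:
        species_params = DEFAULT_SPECIES_PARAMS
    rng = np.random.default_rng(seed)
    rows = []
    for sp in species_params:
        for ind in range(int(sp.get("n_inflorescences", 3))):
            for pos, oveff, poeff in zip(POSITIONS, ovule_position_effect,
                                         pollen_position_effect):
                pollen = max(1, int(round(rng.normal(sp["pollen_mean"] * poeff,
                                                     sp["pollen_sd"]))))
                ovules = max(1, int(round(rng.normal(sp["ovule_mean"] * oveff,
                                                     sp["ovule_sd"]))))
                rows.append(dict(
                    species=sp["species"], individual=f"{sp['species']}_{ind + 1}",
                    position=pos, strategy=sp["strategy"],
                    pollen=pollen, ovules=ovules, massulae=np.nan,
                    po=pollen / ovules,
                ))
    return pd.DataFrame(rows)
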