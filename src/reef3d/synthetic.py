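"""Two-epoch synthetic reef scenes with known growth and mortality.

No public benthic dataset pairs millimetre orthomosaics with DSMs and
three-class labels, so this module builds one: a sandy substrate with
rocky outcrops, non-overlapping hemispherical coral colonies (live or
dead) carrying fine branch-ridge relief, an illumination gradient over
the RGB rendering, and a prescribed epoch-to-epoch delta (uniform
vertical growth of surviving live colonies, relabeling of a fraction
to dead with the skeleton left standing, removal of a fraction back to
substrate). Every quantity the downstream analyses estimate — growth
medians, class footprints, rugosity contrasts — is therefore known by
construction.

All randomness flows from explicit seeds; a fixed seed reproduces a
scene bit for bit. Colonies are placed by rejection sampling with a
minimum gap so label components and truth-table rows correspond 1:1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, map_coordinates

from .classes import BACKGROUND, DEAD, LABEL_NODATA, LIVE
from .errors import GenerationError, MeshError, ParameterError
from .mesh import TriMesh
from .raster_io import FLOAT_NODATA, GridTransform, Raster
from .roughness import LabeledCloud

__all__ = ["SceneParams", "EpochDelta", "SceneBundle", "generate_scene",
           "evolve_scene", "sample_point_cloud", "build_mesh"]

# base colors (RGB 0-255)
SAND_RGB = (205, 185, 150)
ROCK_RGB = (120, 118, 115)
LIVE_RGB = (185, 55, 120)
DEAD_RGB = (230, 212, 205)   # pale pink / white skeleton

_MIN_GAP_PX = 4
_MAX_PLACEMENT_TRIES = 2000


@dataclass(frozen=True)
class SceneParams:
    """Parameters of one synthetic reef scene.

    Defaults emulate a ~1 m^2 fore-reef quadrat at 1 mm grid spacing
    dominated by decimetre-scale branching colonies: gentle sandy
    substrate (mm-scale smoothed noise), ~10% rocky cover, colonies of
    4-9 cm radius and 5-15 cm height with ~8 mm branch-ridge relief.
    """

    extent_px: tuple[int, int] = (1024, 1024)
    cell_size: float = 0.001
    n_colonies: int = 12
    colony_radius_range: tuple[float, float] = (0.04, 0.09)
    colony_height_range: tuple[float, float] = (0.05, 0.15)
    branch_ridge_amplitude: float = 0.008
    rock_fraction: float = 0.10
    sand_noise_sd: float = 0.002
    illumination_gradient_amplitude: float = 0.25
    rgb_noise_sd: float = 6.0
    dead_fraction: float = 0.25
    dead_rgb: tuple[int, int, int] = DEAD_RGB
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.colony_radius_range) <= 0 or min(self.colony_height_range) <= 0:
            raise ParameterError("colony radii and heights must be positive")
        for name in ("rock_fraction", "dead_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name} must be in [0, 1], got {v}")
        if self.n_colonies < 0:
            raise ParameterError("n_colonies must be non-negative")


@dataclass(frozen=True)
class EpochDelta:
    """Prescribed change between two survey epochs.

    ``growth_mm`` raises the surviving live colonies uniformly;
    ``mortality_fraction`` of the live colonies is relabeled dead with
    the DSM untouched (intact skeleton); ``removal_fraction`` of all
    colonies is erased back to the substrate. ``renoise_sd`` /
    ``redraw_illumination`` optionally re-perturb the second epoch
    (off by default: the noise-free evolve downstream tests rely on).
    """

    growth_mm: float = 0.0
    mortality_fraction: float = 0.0
    removal_fraction: float = 0.0
    renoise_sd: float = 0.0
    redraw_illumination: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mortality_fraction", "removal_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name} must be in [0, 1], got {v}")
        if not math.isfinite(self.growth_mm):
            raise ParameterError("growth_mm must be finite")


@dataclass
class SceneBundle:
    """One epoch of a synthetic scene: co-registered rasters + truth.

    ``truth`` has one row per colony: colony_id, row/col center,
    radius_m, height_m, class_id (live/dead), removed flag, color
    jitter. ``background_dsm`` is the DSM without colonies (used when
    colonies are removed); ``illum`` the multiplicative illumination
    field.
    """

    ortho: Raster
    dsm: Raster
    labels: Raster
    truth: pd.DataFrame
    params: SceneParams
    background_dsm: np.ndarray
    rock_mask: np.ndarray
    illum: np.ndarray

    def save(self, out_dir) -> None:
        from pathlib import Path
        from .raster_io import save_raster
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_raster(self.ortho, out / "ortho.tif")
        save_raster(self.dsm, out / "dsm.tif")
        save_raster(self.labels, out / "labels.tif")
        self.truth.to_csv(out / "truth.csv", index=False)


def _smooth_noise(rng, shape, sigma, sd):
    """Gaussian-smoothed noise renormalised to the requested sd."""
    n = gaussian_filter(rng.standard_normal(shape), sigma)
    s = n.std()
    return n * (sd / s) if s > 0 else n


def _colony_masks(rows, cols, truth):
    """Per-colony boolean footprint masks (d <= r), as a list."""
    yy, xx = np.mgrid[0:rows, 0:cols]
    masks = []
    for t in truth.itertuples():
        r_px = t.radius_m / t.cell_size
        d2 = (yy - t.row) ** 2 + (xx - t.col) ** 2
        masks.append(d2 <= r_px * r_px)
    return masks


def _render_rgb(params, labels, rock_mask, illum, truth, masks, rng):
    rows, cols = labels.shape
    base = np.empty((rows, cols, 3), dtype=np.float64)
    base[:] = SAND_RGB
    base[rock_mask] = ROCK_RGB
    class_rgb = {LIVE: LIVE_RGB, DEAD: params.dead_rgb}
    for t, m in zip(truth.itertuples(), masks):
        if t.removed:
            continue
        jitter = np.array([t.jr, t.jg, t.jb])
        base[m] = np.array(class_rgb[t.class_id]) + jitter
    rgb = base * illum[:, :, None]
    rgb += rng.standard_normal(rgb.shape) * params.rgb_noise_sd
    return np.clip(np.round(rgb), 0, 255).astype(np.uint8)


def _colony_relief(params, truth, masks, rows, cols, rng_ridge):
    """Sum of colony caps + branch-ridge relief for non-removed colonies."""
    yy, xx = np.mgrid[0:rows, 0:cols]
    relief = np.zeros((rows, cols), dtype=np.float64)
    ridge_field = _smooth_noise(rng_ridge, (rows, cols), 1.5,
                                params.branch_ridge_amplitude)
    for t, m in zip(truth.itertuples(), masks):
        if t.removed:
            continue
        r_px = t.radius_m / t.cell_size
        d2 = (yy[m] - t.row) ** 2 + (xx[m] - t.col) ** 2
        cap_frac = np.sqrt(np.clip(1.0 - d2 / (r_px * r_px), 0.0, 1.0))
        relief[m] += t.height_m * cap_frac + ridge_field[m] * cap_frac
    return relief


def generate_scene(p: SceneParams) -> SceneBundle:
    """Build one epoch: ortho + DSM + labels + per-colony truth table.

    Raises :class:`GenerationError` if the requested colonies cannot be
    placed without overlap within the extent.
    """
    rows, cols = p.extent_px
    rng = np.random.default_rng(p.seed)
    transform = GridTransform(0.0, rows * p.cell_size, p.cell_size)

    # substrate: gentle undulation + rocks + smoothed sand noise
    substrate = _smooth_noise(rng, (rows, cols), min(rows, cols) / 8, 0.01)
    rock_field = gaussian_filter(rng.standard_normal((rows, cols)), 12)
    if p.rock_fraction > 0:
        thresh = np.quantile(rock_field, 1.0 - p.rock_fraction)
        rock_mask = rock_field > thresh
        substrate += np.clip(rock_field - thresh, 0, None) * 0.4
    else:
        rock_mask = np.zeros((rows, cols), dtype=bool)
    substrate += _smooth_noise(rng, (rows, cols), 1.0, p.sand_noise_sd)

    # place colonies by rejection sampling (non-overlapping, min gap)
    r_lo, r_hi = p.colony_radius_range
    h_lo, h_hi = p.colony_height_range
    placed = []   # (row, col, r_px)
    records = []
    for cid in range(p.n_colonies):
        radius_m = rng.uniform(r_lo, r_hi)
        height_m = rng.uniform(h_lo, h_hi)
        r_px = radius_m / p.cell_size
        margin = r_px + 2
        if 2 * margin >= min(rows, cols):
            raise GenerationError(
                f"colony radius {radius_m:.3f} m does not fit extent {p.extent_px}")
        ok = False
        for _ in range(_MAX_PLACEMENT_TRIES):
            cr = rng.uniform(margin, rows - margin)
            cc = rng.uniform(margin, cols - margin)
            if all((cr - pr) ** 2 + (cc - pc) ** 2
                   >= (r_px + pr_px + _MIN_GAP_PX) ** 2
                   for pr, pc, pr_px in placed):
                ok = True
                break
        if not ok:
            raise GenerationError(
                f"could not place colony {cid} after {_MAX_PLACEMENT_TRIES} tries")
        placed.append((cr, cc, r_px))
        records.append({"colony_id": cid, "row": cr, "col": cc,
                        "radius_m": radius_m, "height_m": height_m,
                        "cell_size": p.cell_size})
    truth = pd.DataFrame(records, columns=["colony_id", "row", "col",
                                           "radius_m", "height_m", "cell_size"])

    # classes: a fixed count of colonies starts dead
    n_dead = int(round(p.dead_fraction * p.n_colonies))
    class_ids = np.full(p.n_colonies, LIVE, dtype=np.int64)
    if p.n_colonies:
        dead_idx = rng.choice(p.n_colonies, size=n_dead, replace=False)
        class_ids[dead_idx] = DEAD
    truth["class_id"] = class_ids
    truth["removed"] = False
    jit = rng.uniform(-10, 10, size=(p.n_colonies, 3))
    truth["jr"], truth["jg"], truth["jb"] = jit.T if p.n_colonies else ([], [], [])

    masks = _colony_masks(rows, cols, truth)
    relief = _colony_relief(p, truth, masks, rows, cols, rng)
    dsm = substrate + relief

    labels = np.zeros((rows, cols), dtype=np.uint8)
    for t, m in zip(truth.itertuples(), masks):
        labels[m] = t.class_id

    # illumination: linear gradient with a random direction
    theta = rng.uniform(0, 2 * np.pi)
    yy, xx = np.mgrid[0:rows, 0:cols]
    g = (np.cos(theta) * (xx / max(cols - 1, 1) - 0.5)
         + np.sin(theta) * (yy / max(rows - 1, 1) - 0.5)) * 2.0
    illum = 1.0 + p.illumination_gradient_amplitude * g

    rgb = _render_rgb(p, labels, rock_mask, illum, truth, masks, rng)

    mk = lambda d, meaning, nod: Raster(data=d, transform=transform,
                                        nodata=nod, band_meaning=meaning)
    return SceneBundle(
        ortho=mk(rgb, "rgb", 0.0),
        dsm=mk(dsm, "height", FLOAT_NODATA),
        labels=mk(labels, "label", float(LABEL_NODATA)),
        truth=truth, params=p, background_dsm=substrate,
        rock_mask=rock_mask, illum=illum)


def evolve_scene(s: SceneBundle, d: EpochDelta) -> SceneBundle:
    """Apply a prescribed epoch delta and re-render the second epoch.

    Background cells (outside every colony footprint) keep DSM and
    labels bit-equal to the first epoch. Removal is drawn over all
    colonies; mortality over the remaining live ones (floor counts);
    growth applies to colonies that stay live.
    """
    rng = np.random.default_rng(d.seed)
    rows, cols = s.dsm.shape
    truth = s.truth.copy()
    dsm = np.asarray(s.dsm.data, dtype=np.float64).copy()
    labels = np.asarray(s.labels.data).copy()
    masks = _colony_masks(rows, cols, truth)

    present = truth.index[~truth["removed"]].to_numpy()
    n_rm = int(math.floor(d.removal_fraction * len(present)))
    removed_idx = rng.choice(present, size=n_rm, replace=False) if n_rm else []
    truth.loc[removed_idx, "removed"] = True

    live_idx = truth.index[(truth["class_id"] == LIVE)
                           & (~truth["removed"])].to_numpy()
    n_mort = int(math.floor(d.mortality_fraction * len(live_idx)))
    dead_idx = rng.choice(live_idx, size=n_mort, replace=False) if n_mort else []
    truth.loc[dead_idx, "class_id"] = DEAD

    surviving_live = truth.index[(truth["class_id"] == LIVE)
                                 & (~truth["removed"])].to_numpy()

    for i, m in enumerate(masks):
        if i in set(np.atleast_1d(removed_idx).tolist()):
            dsm[m] = s.background_dsm[m]
            labels[m] = BACKGROUND
        elif i in set(np.atleast_1d(dead_idx).tolist()):
            labels[m] = DEAD            # DSM unchanged: skeleton intact
        elif i in set(surviving_live.tolist()):
            dsm[m] += d.growth_mm / 1000.0

    if d.renoise_sd > 0:
        dsm = dsm + _smooth_noise(rng, (rows, cols), 1.0, d.renoise_sd)

    illum = s.illum
    if d.redraw_illumination:
        theta = rng.uniform(0, 2 * np.pi)
        yy, xx = np.mgrid[0:rows, 0:cols]
        g = (np.cos(theta) * (xx / max(cols - 1, 1) - 0.5)
             + np.sin(theta) * (yy / max(rows - 1, 1) - 0.5)) * 2.0
        illum = 1.0 + s.params.illumination_gradient_amplitude * g

    rgb = _render_rgb(s.params, labels, s.rock_mask, illum, truth, masks, rng)

    mk = lambda data, tmpl: Raster(data=data, transform=tmpl.transform,
                                   nodata=tmpl.nodata,
                                   band_meaning=tmpl.band_meaning)
    return SceneBundle(
        ortho=mk(rgb, s.ortho), dsm=mk(dsm, s.dsm), labels=mk(labels, s.labels),
        truth=truth, params=s.params, background_dsm=s.background_dsm,
        rock_mask=s.rock_mask, illum=illum)


def sample_point_cloud(s: SceneBundle, points_per_cell: float = 1.0,
                       jitter: float = 0.5, seed: int = 0) -> LabeledCloud:
    """Sample a labeled point cloud on the DSM surface.

    Each valid cell yields ``floor(points_per_cell)`` points (plus a
    random subset for the fractional part), with (x, y) jittered
    uniformly within ``+-jitter`` cells of the cell center and z from
    bilinear interpolation of the DSM. ``jitter=0`` puts points exactly
    on cell centers with exact cell heights. Each point carries the
    class of its source cell.
    """
    if points_per_cell <= 0:
        raise ParameterError("points_per_cell must be positive")
    if not (0.0 <= jitter <= 0.5):
        raise ParameterError("jitter must be in [0, 0.5] cells")
    rng = np.random.default_rng(seed)
    z, labels = np.asarray(s.dsm.data, dtype=np.float64), np.asarray(s.labels.data)
    valid = z != s.dsm.nodata
    vr, vc = np.nonzero(valid)

    n_base = int(math.floor(points_per_cell))
    rows_idx = np.tile(vr, n_base)
    cols_idx = np.tile(vc, n_base)
    frac = points_per_cell - n_base
    if frac > 0:
        n_extra = int(round(frac * len(vr)))
        pick = rng.choice(len(vr), size=n_extra, replace=True)
        rows_idx = np.concatenate([rows_idx, vr[pick]])
        cols_idx = np.concatenate([cols_idx, vc[pick]])

    fr = rows_idx.astype(np.float64)
    fc = cols_idx.astype(np.float64)
    if jitter > 0:
        fr = fr + rng.uniform(-jitter, jitter, size=len(fr))
        fc = fc + rng.uniform(-jitter, jitter, size=len(fc))
        fr = np.clip(fr, 0, z.shape[0] - 1)
        fc = np.clip(fc, 0, z.shape[1] - 1)
        zs = map_coordinates(z, [fr, fc], order=1)
    else:
        zs = z[rows_idx, cols_idx]
    x, y = s.dsm.transform.cell_center(fr, fc)
    cls = labels[rows_idx, cols_idx]
    return LabeledCloud(xyz=np.column_stack([x, y, zs]), class_id=cls)


def build_mesh(s: SceneBundle) -> TriMesh:
    """Height-field triangulation: one vertex per valid DSM cell, two
    triangles per fully valid cell quad; deterministic vertex order
    (row-major over valid cells); all face normals point up (+z)."""
    z = np.asarray(s.dsm.data, dtype=np.float64)
    valid = z != s.dsm.nodata
    rows, cols = z.shape
    if valid.sum() < 4:
        raise MeshError("fewer than 4 valid DSM cells")
    index = np.full((rows, cols), -1, dtype=np.int64)
    vr, vc = np.nonzero(valid)
    index[vr, vc] = np.arange(len(vr))
    x, y = s.dsm.transform.cell_center(vr, vc)
    vertices = np.column_stack([x, y, z[vr, vc]])

    quad = (valid[:-1, :-1] & valid[1:, :-1] & valid[:-1, 1:] & valid[1:, 1:])
    qr, qc = np.nonzero(quad)
    if len(qr) == 0:
        raise MeshError("no complete 2x2 quad of valid cells")
    a = index[qr, qc]          # (r, c)
    b = index[qr + 1, qc]      # (r+1, c)
    c_ = index[qr, qc + 1]     # (r, c+1)
    d_ = index[qr + 1, qc + 1]
    faces = np.concatenate([np.column_stack([a, b, c_]),
                            np.column_stack([b, d_, c_])])
    mesh = TriMesh(vertices=vertices, faces=faces)
    mesh.vertex_attrs["class_id"] = np.asarray(s.labels.data)[vr, vc]
    return mesh
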