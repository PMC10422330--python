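"""DSM-based structural analyses: slope/aspect, multi-scale vector
ruggedness, height-change mapping and class-stratified statistics.

The Vector Ruggedness Measure (VRM) of a cell is ``1 - |R| / n`` where
``R`` is the resultant of the unit surface normals over an odd
``w x w`` neighborhood and ``n = w**2``: 0 on any plane (all normals
parallel, including tilted planes), approaching 1 for maximally
dispersed normals. Slope and aspect come from Horn's 3x3 weighted
finite differences (the convention of common GIS terrain tools);
normals are decomposed as ``(sin s * sin a, sin s * cos a, cos s)``
with aspect measured clockwise from grid north and flat-cell aspect 0
(immaterial, since ``sin s = 0`` there).

Height change between epochs is the pixel-wise DSM difference,
reported in millimetres; its distribution is summarised by the median
(robust to the skew typical of growth/mortality mixtures), optionally
restricted to one semantic class through a segmentation mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classes import LABEL_NODATA
from .errors import StatsError, TerrainError
from .raster_io import FLOAT_NODATA, Raster, assert_coregistered

__all__ = ["slope_aspect", "normals_from_slope_aspect", "NormalField",
           "vrm", "VrmResult", "dsm_difference", "change_summary",
           "stratify_by_class"]


@dataclass
class NormalField:
    """Unit surface normal components on the grid (nodata = NaN)."""

    nx: np.ndarray
    ny: np.ndarray
    nz: np.ndarray
    valid: np.ndarray


@dataclass
class VrmResult:
    vrm: Raster
    window_px: int


def _dsm_array(dsm: Raster):
    z = np.asarray(dsm.data, dtype=np.float64)
    valid = z != dsm.nodata
    return z, valid


def slope_aspect(dsm: Raster):
    """Horn 3x3 slope and aspect (radians) as scalar rasters.

    Border cells and cells with any nodata neighbor are nodata.
    Aspect is the downslope azimuth clockwise from grid north; flat
    cells get aspect 0.
    """
    rows, cols = dsm.shape
    if rows < 3 or cols < 3:
        raise TerrainError(f"grid {rows}x{cols} too small for a 3x3 stencil")
    z, valid = _dsm_array(dsm)
    c = dsm.transform.cell_size

    zp = np.pad(z, 1, mode="edge")
    vp = np.pad(valid, 1, mode="constant", constant_values=False)

    def sh(dr, dc):
        return zp[1 + dr:1 + dr + rows, 1 + dc:1 + dc + cols]

    def vsh(dr, dc):
        return vp[1 + dr:1 + dr + rows, 1 + dc:1 + dc + cols]

    # Horn weights; row -1 is north (y increases), col +1 is east
    p = ((sh(-1, 1) + 2 * sh(0, 1) + sh(1, 1))
         - (sh(-1, -1) + 2 * sh(0, -1) + sh(1, -1))) / (8 * c)   # dz/dx
    q = ((sh(-1, -1) + 2 * sh(-1, 0) + sh(-1, 1))
         - (sh(1, -1) + 2 * sh(1, 0) + sh(1, 1))) / (8 * c)      # dz/dy

    ok = np.ones((rows, cols), dtype=bool)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            ok &= vsh(dr, dc)

    slope = np.arctan(np.hypot(p, q))
    flat = (p == 0) & (q == 0)
    aspect = np.where(flat, 0.0, np.arctan2(-p, -q) % (2 * np.pi))
    slope = np.where(ok, slope, FLOAT_NODATA)
    aspect = np.where(ok, aspect, FLOAT_NODATA)
    mk = lambda d: Raster(data=d, transform=dsm.transform,
                          nodata=FLOAT_NODATA, band_meaning="scalar")
    return mk(slope), mk(aspect)


def normals_from_slope_aspect(slope: Raster, aspect: Raster) -> NormalField:
    """Decompose slope/aspect into unit normal components."""
    assert_coregistered(slope, aspect)
    s = np.asarray(slope.data, dtype=np.float64)
    a = np.asarray(aspect.data, dtype=np.float64)
    valid = (s != slope.nodata) & (a != aspect.nodata)
    sin_s = np.where(valid, np.sin(s), np.nan)
    nx = sin_s * np.where(valid, np.sin(a), np.nan)
    ny = sin_s * np.where(valid, np.cos(a), np.nan)
    nz = np.where(valid, np.cos(s), np.nan)
    return NormalField(nx=nx, ny=ny, nz=nz, valid=valid)


def _window_sum(x: np.ndarray, w: int) -> np.ndarray:
    """Exact moving-window sum over w x w via a summed-area table.

    Output has shape (rows - w + 1, cols - w + 1)."""
    s = np.zeros((x.shape[0] + 1, x.shape[1] + 1), dtype=np.float64)
    np.cumsum(np.cumsum(x, axis=0), axis=1, out=s[1:, 1:])
    return s[w:, w:] - s[:-w, w:] - s[w:, :-w] + s[:-w, :-w]


def vrm(dsm: Raster, window_px: int) -> VrmResult:
    """Vector Ruggedness Measure over an odd square window.

    ``vrm = 1 - |sum of unit normals| / window_px**2``; any window that
    contains a nodata normal (including the slope/aspect border) is
    nodata. Values lie in [0, 1]: exactly 0 on constant-gradient
    planes.
    """
    if window_px < 3 or window_px % 2 == 0:
        raise TerrainError(f"window must be odd and >= 3, got {window_px}")
    rows, cols = dsm.shape
    if window_px > min(rows, cols):
        raise TerrainError(f"window {window_px} exceeds grid {rows}x{cols}")
    slope, aspect = slope_aspect(dsm)
    nf = normals_from_slope_aspect(slope, aspect)

    half = window_px // 2
    out = np.full((rows, cols), FLOAT_NODATA, dtype=np.float64)
    fill = lambda a: np.where(nf.valid, a, 0.0)
    sx = _window_sum(fill(nf.nx), window_px)
    sy = _window_sum(fill(nf.ny), window_px)
    sz = _window_sum(fill(nf.nz), window_px)
    n_invalid = _window_sum((~nf.valid).astype(np.float64), window_px)

    n = float(window_px * window_px)
    mag = np.sqrt(sx * sx + sy * sy + sz * sz)
    val = np.clip(1.0 - mag / n, 0.0, 1.0)
    val = np.where(n_invalid > 0.5, FLOAT_NODATA, val)
    out[half:rows - half, half:cols - half] = val
    r = Raster(data=out, transform=dsm.transform, nodata=FLOAT_NODATA,
               band_meaning="scalar")
    return VrmResult(vrm=r, window_px=window_px)


def dsm_difference(dsm_t2: Raster, dsm_t1: Raster) -> Raster:
    """Pixel-wise height change (t2 - t1) in millimetres.

    Nodata in either epoch propagates. Antisymmetric by construction.
    """
    assert_coregistered(dsm_t2, dsm_t1)
    z2, v2 = _dsm_array(dsm_t2)
    z1, v1 = _dsm_array(dsm_t1)
    valid = v1 & v2
    diff = np.where(valid, (z2 - z1) * 1000.0, FLOAT_NODATA)
    return Raster(data=diff, transform=dsm_t2.transform,
                  nodata=FLOAT_NODATA, band_meaning="scalar")


def _stats_row(values: np.ndarray, class_id=None, scale=None) -> dict:
    if values.size == 0:
        return {"class": class_id, "scale": scale, "n": 0,
                "min": np.nan, "q1": np.nan, "median": np.nan,
                "q3": np.nan, "max": np.nan, "mean": np.nan, "sd": np.nan}
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return {"class": class_id, "scale": scale, "n": int(values.size),
            "min": float(values.min()), "q1": float(q1),
            "median": float(med), "q3": float(q3),
            "max": float(values.max()), "mean": float(values.mean()),
            "sd": float(values.std(ddof=1)) if values.size > 1 else 0.0}


def change_summary(change: Raster, mask: Raster | None = None,
                   class_id: int | None = None, bin_width: float = 1.0,
                   hist_range: tuple[float, float] = (-50.0, 50.0)):
    """Distribution summary of a change (or any scalar) raster.

    Returns ``(row, (hist_counts, bin_edges))`` where ``row`` holds n,
    min/quartiles/max, mean, sd over valid cells, optionally restricted
    to one class of a co-registered semantic mask. The histogram covers
    ``hist_range`` (a display truncation — the statistics always use
    all valid values).
    """
    vals, valid = _dsm_array(change)
    sel = valid
    if class_id is not None:
        if mask is None:
            raise StatsError("class_id selection requires a mask")
        assert_coregistered(change, mask)
        sel = sel & (mask.data == class_id)
    v = vals[sel]
    if v.size == 0:
        raise StatsError("no valid cells in selection")
    n_bins = int(round((hist_range[1] - hist_range[0]) / bin_width))
    counts, edges = np.histogram(v, bins=n_bins, range=hist_range)
    return _stats_row(v, class_id=class_id), (counts, edges)


def stratify_by_class(values, mask: Raster | None = None,
                      scale=None, scalar_name: str | None = None,
                      scheme_ids=(0, 1, 2)) -> pd.DataFrame:
    """Per-class distribution summary of a scalar raster or labeled cloud.

    ``values`` is either a scalar :class:`Raster` (then ``mask`` must be
    a co-registered label raster) or a :class:`~reef3d.roughness.LabeledCloud`
    carrying ``class_id`` and the scalar named ``scalar_name``. One row
    per class; classes with no members get n = 0 and NaN statistics.
    """
    rows = []
    if isinstance(values, Raster):
        if mask is None:
            raise StatsError("raster stratification requires a label mask")
        assert_coregistered(values, mask)
        vals, valid = _dsm_array(values)
        labels = np.asarray(mask.data)
        for cid in scheme_ids:
            sel = valid & (labels == cid)
            rows.append(_stats_row(vals[sel], class_id=cid, scale=scale))
    else:
        cloud = values
        if cloud.class_id is None:
            raise StatsError("cloud has no class labels; run transfer_labels")
        if scalar_name is None or scalar_name not in cloud.scalars:
            raise StatsError(f"cloud scalar {scalar_name!r} not found")
        v = np.asarray(cloud.scalars[scalar_name], dtype=np.float64)
        finite = np.isfinite(v)
        for cid in scheme_ids:
            sel = finite & (cloud.class_id == cid) & (cloud.class_id != LABEL_NODATA)
            rows.append(_stats_row(v[sel], class_id=cid, scale=scale))
    return pd.DataFrame(rows)
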