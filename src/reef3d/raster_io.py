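"""Georeferenced raster containers and GeoTIFF I/O.

Everything downstream (tiling, terrain derivatives, cloud/mesh
projection) operates on millimetre-scale, north-up, axis-aligned grids
in a shared metric frame. This module holds the single in-memory raster
type, reads/writes it as GeoTIFF (georeferencing via the
ModelPixelScale / ModelTiepoint tags; nodata via GDAL_NODATA), and
enforces the co-registration contract that every two-raster operation
assumes.

Grid convention: cell centers. Pixel (row, col) maps to world
``(x_origin + (col + 0.5) * cell, y_origin - (row + 0.5) * cell)``;
row index increases as world y decreases (north-up).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import tifffile

from .classes import LABEL_NODATA
from .errors import CoregistrationError, FormatError

__all__ = [
    "GridTransform",
    "Raster",
    "load_raster",
    "save_raster",
    "assert_coregistered",
    "FLOAT_NODATA",
    "BAND_MEANINGS",
]

#: default nodata sentinel for float rasters (common GIS convention)
FLOAT_NODATA = -9999.0

BAND_MEANINGS = ("rgb", "height", "label", "scalar")

# GeoTIFF / GDAL tag codes
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


@dataclass(frozen=True)
class GridTransform:
    """Axis-aligned, north-up affine transform (origin = top-left corner)."""

    x_origin: float
    y_origin: float
    cell_size: float

    def __post_init__(self) -> None:
        if not (self.cell_size > 0):
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")

    def cell_center(self, row, col):
        """World (x, y) of the center of pixel (row, col)."""
        x = self.x_origin + (np.asarray(col) + 0.5) * self.cell_size
        y = self.y_origin - (np.asarray(row) + 0.5) * self.cell_size
        return x, y

    def world_to_cell(self, x, y):
        """(row, col) integer indices of the cell containing world (x, y)."""
        col = np.floor((np.asarray(x) - self.x_origin) / self.cell_size).astype(np.int64)
        row = np.floor((self.y_origin - np.asarray(y)) / self.cell_size).astype(np.int64)
        return row, col

    def world_to_grid_coords(self, x, y):
        """Fractional (row, col) coordinates of world (x, y) on the
        cell-center grid (cell centers sit at integer coordinates)."""
        col = (np.asarray(x) - self.x_origin) / self.cell_size - 0.5
        row = (self.y_origin - np.asarray(y)) / self.cell_size - 0.5
        return row, col


@dataclass
class Raster:
    """A single- or three-band grid with transform and nodata sentinel.

    ``data`` is (rows, cols) for height/label/scalar or (rows, cols, 3)
    for rgb. Height rasters are finite wherever not nodata; label
    rasters hold only valid class ids or the nodata sentinel.
    """

    data: np.ndarray
    transform: GridTransform
    nodata: float
    band_meaning: str

    def __post_init__(self) -> None:
        if self.band_meaning not in BAND_MEANINGS:
            raise ValueError(f"unknown band_meaning {self.band_meaning!r}")
        self.data = np.asarray(self.data)
        if self.band_meaning == "rgb":
            if self.data.ndim != 3 or self.data.shape[2] != 3:
                raise FormatError(
                    f"rgb raster must be (rows, cols, 3), got {self.data.shape}"
                )
        else:
            if self.data.ndim != 2:
                raise FormatError(
                    f"{self.band_meaning} raster must be 2D, got {self.data.shape}"
                )
        self._validate_values()

    def _validate_values(self) -> None:
        if self.band_meaning == "label":
            vals = np.unique(self.data)
            bad = [v for v in vals if v != self.nodata and v not in (0, 1, 2)]
            if bad:
                raise FormatError(f"label raster contains invalid class ids {bad}")
        elif self.band_meaning == "height":
            d = np.asarray(self.data, dtype=np.float64)
            valid = d != self.nodata
            if not np.all(np.isfinite(d[valid])):
                raise FormatError("height raster has non-finite cells outside nodata")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[0], self.data.shape[1]

    @property
    def n_bands(self) -> int:
        return 1 if self.data.ndim == 2 else self.data.shape[2]

    @property
    def valid_mask(self) -> np.ndarray:
        """Boolean mask of cells that are not nodata (all-band for rgb)."""
        if self.data.ndim == 3:
            return np.all(self.data != self.nodata, axis=2)
        return self.data != self.nodata

    def copy(self, **changes) -> "Raster":
        r = replace(self, **({"data": self.data.copy()} | changes))
        return r


def _default_nodata(band_meaning: str) -> float:
    return float(LABEL_NODATA) if band_meaning == "label" else FLOAT_NODATA


def load_raster(path, expected_meaning: str, transform: GridTransform | None = None) -> "Raster":
    """Read a GeoTIFF (or PNG label mask) as a :class:`Raster`.

    PNG carries no georeference, so loading one requires ``transform``
    from a paired raster. Band count must match ``expected_meaning``
    (rgb -> 3 bands, anything else -> 1).
    """
    path = Path(path)
    if expected_meaning not in BAND_MEANINGS:
        raise ValueError(f"unknown band meaning {expected_meaning!r}")
    if not path.exists():
        raise IOError(f"raster file not found: {path}")

    if path.suffix.lower() == ".png":
        import imageio.v3 as iio

        data = np.asarray(iio.imread(path))
        if transform is None:
            raise FormatError("PNG has no georeference; a paired transform is required")
        nodata = _default_nodata(expected_meaning)
    else:
        try:
            with tifffile.TiffFile(path) as tif:
                page = tif.pages[0]
                data = page.asarray()
                scale = _tag_value(page.tags, _TAG_PIXEL_SCALE)
                tie = _tag_value(page.tags, _TAG_TIEPOINT)
                nod = _tag_value(page.tags, _TAG_GDAL_NODATA)
        except Exception as exc:  # unreadable / not a TIFF
            raise IOError(f"cannot read raster {path}: {exc}") from exc
        if transform is None:
            if scale is None or tie is None:
                raise FormatError(f"{path} has no geotransform tags")
            sx, sy = float(scale[0]), float(scale[1])
            if not math.isclose(sx, sy, rel_tol=1e-9):
                raise FormatError(f"anisotropic cells unsupported ({sx} x {sy})")
            # tiepoint maps raster (i, j, k) -> world (x, y, z); we write (0,0)
            i, j = float(tie[0]), float(tie[1])
            x, y = float(tie[3]), float(tie[4])
            transform = GridTransform(x - i * sx, y + j * sy, sx)
        nodata = float(nod) if nod is not None else _default_nodata(expected_meaning)

    n_bands = 1 if data.ndim == 2 else data.shape[2]
    want = 3 if expected_meaning == "rgb" else 1
    if n_bands != want:
        raise FormatError(
            f"{path}: expected {want} band(s) for {expected_meaning}, found {n_bands}"
        )
    if expected_meaning != "rgb" and data.ndim == 3:
        data = data[:, :, 0]
    return Raster(data=data, transform=transform, nodata=nodata,
                  band_meaning=expected_meaning)


def _tag_value(tags, code):
    tag = tags.get(code)
    if tag is None:
        return None
    return tag.value


def save_raster(r: Raster, path) -> None:
    """Write a :class:`Raster` as a GeoTIFF with georeference + nodata tags.

    Round-trips data (bit-exact for integer grids, float32-exact for
    float grids), transform and nodata through :func:`load_raster`.
    """
    path = Path(path)
    t = r.transform
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (t.cell_size, t.cell_size, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, t.x_origin, t.y_origin, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(r.nodata)),
    ]
    data = r.data
    if r.band_meaning == "rgb":
        photometric = "rgb"
    else:
        photometric = "minisblack"
        if r.band_meaning in ("height", "scalar"):
            data = np.asarray(data, dtype=np.float32)
    try:
        tifffile.imwrite(path, data, photometric=photometric, extratags=extratags)
    except OSError as exc:
        raise IOError(f"cannot write raster {path}: {exc}") from exc


def assert_coregistered(a: Raster, b: Raster, atol: float = 0.0) -> None:
    """Raise :class:`CoregistrationError` unless two rasters share a grid.

    Shapes, origins and cell sizes must match exactly (``atol`` allows a
    tolerance on origins/cell for rasters rebuilt through float I/O).
    The error message names the first differing field.
    """
    if a.shape != b.shape:
        raise CoregistrationError(f"shape mismatch: {a.shape} vs {b.shape}")
    ta, tb = a.transform, b.transform
    for name in ("cell_size", "x_origin", "y_origin"):
        va, vb = getattr(ta, name), getattr(tb, name)
        if abs(va - vb) > atol:
            raise CoregistrationError(f"{name} mismatch: {va} vs {vb}")
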