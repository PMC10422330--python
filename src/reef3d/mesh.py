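"""Triangle meshes and projection of 2D semantic/scalar maps onto them.

Segmentation masks, height-change maps and roughness rasters live on
the north-up grid; reef meshes live in the same metric frame. Because
the meshes handled here are height-field-like (built from DSMs),
vertical-ray projection — look up the raster value above/below each
vertex — is exact. Class labels use nearest-cell lookup (categorical
data is never interpolated); scalars use bilinear interpolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from . import plyio
from .classes import LABEL_NODATA, ClassScheme, DEFAULT_SCHEME
from .errors import FormatError, MeshError
from .raster_io import Raster

__all__ = ["TriMesh", "project_raster_to_mesh", "colorize",
           "diverging_change_colors", "SCALAR_UNSET"]

log = logging.getLogger(__name__)

#: sentinel for vertices not covered by a projected raster
SCALAR_UNSET = np.nan


@dataclass
class TriMesh:
    """Vertices (V x 3, m), triangular faces (F x 3 indices) and named
    per-vertex attributes (class_id, scalars, uint8 rgb color)."""

    vertices: np.ndarray
    faces: np.ndarray
    vertex_attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise FormatError(f"vertices must be (V, 3), got {self.vertices.shape}")
        if self.faces.size and (self.faces.ndim != 2 or self.faces.shape[1] != 3):
            raise FormatError(f"faces must be (F, 3), got {self.faces.shape}")
        if self.faces.size:
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                raise MeshError("face indices out of range")
            a, b, c = self.faces.T
            if np.any((a == b) | (b == c) | (a == c)):
                raise MeshError("degenerate faces (repeated vertex indices)")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def face_normals(self) -> np.ndarray:
        """Unit normals per face (right-hand rule over vertex order)."""
        v = self.vertices
        e1 = v[self.faces[:, 1]] - v[self.faces[:, 0]]
        e2 = v[self.faces[:, 2]] - v[self.faces[:, 0]]
        n = np.cross(e1, e2)
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        return n / np.where(norm == 0, 1, norm)

    def save_ply(self, path, binary: bool = True) -> None:
        props = {
            "x": self.vertices[:, 0], "y": self.vertices[:, 1],
            "z": self.vertices[:, 2],
        }
        for name, vals in self.vertex_attrs.items():
            vals = np.asarray(vals)
            if name == "color":
                props["red"] = vals[:, 0].astype(np.uint8)
                props["green"] = vals[:, 1].astype(np.uint8)
                props["blue"] = vals[:, 2].astype(np.uint8)
            elif name == "class_id":
                props[name] = vals.astype(np.uint8)
            else:
                props[name] = vals.astype(np.float32)
        plyio.write_ply(path, props, faces=self.faces, binary=binary)

    @classmethod
    def load_ply(cls, path) -> "TriMesh":
        props, faces = plyio.read_ply(path)
        xyz = np.column_stack([props.pop("x"), props.pop("y"), props.pop("z")])
        attrs = {}
        if {"red", "green", "blue"} <= props.keys():
            attrs["color"] = np.column_stack(
                [props.pop("red"), props.pop("green"), props.pop("blue")]
            ).astype(np.uint8)
        attrs.update(props)
        if faces is None:
            faces = np.zeros((0, 3), dtype=np.int64)
        return cls(vertices=xyz, faces=faces, vertex_attrs=attrs)

    def save_obj(self, path) -> None:
        """OBJ export: geometry only; per-vertex colors and scalars are
        dropped (documented format limitation)."""
        with open(path, "w") as fh:
            for v in self.vertices:
                fh.write(f"v {v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
            for f in self.faces:
                fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")


def project_raster_to_mesh(mesh: TriMesh, r: Raster, attr_name: str) -> TriMesh:
    """Attach the raster value above each vertex as a vertex attribute.

    Labels are looked up in the containing cell; scalar/height rasters
    are bilinearly interpolated on the cell-center grid. Vertices
    outside the raster or over nodata get the unset sentinel
    (255 for labels, NaN for scalars). Re-projecting the same raster is
    idempotent; an existing attribute is overwritten with a warning.
    """
    if attr_name in mesh.vertex_attrs:
        log.warning("overwriting existing mesh attribute %r", attr_name)
    x, y = mesh.vertices[:, 0], mesh.vertices[:, 1]
    rows, cols = r.shape
    if r.band_meaning == "label":
        row, col = r.transform.world_to_cell(x, y)
        inside = (row >= 0) & (row < rows) & (col >= 0) & (col < cols)
        values = np.full(mesh.n_vertices, LABEL_NODATA, dtype=np.uint8)
        values[inside] = r.data[row[inside], col[inside]]
    else:
        fr, fc = r.transform.world_to_grid_coords(x, y)
        inside = (fr >= 0) & (fr <= rows - 1) & (fc >= 0) & (fc <= cols - 1)
        data = np.asarray(r.data, dtype=np.float64)
        invalid = data == r.nodata
        data = np.where(invalid, np.nan, data)
        values = np.full(mesh.n_vertices, SCALAR_UNSET, dtype=np.float64)
        values[inside] = map_coordinates(
            data, [fr[inside], fc[inside]], order=1, mode="constant",
            cval=np.nan)
    out = TriMesh(vertices=mesh.vertices, faces=mesh.faces,
                  vertex_attrs=dict(mesh.vertex_attrs))
    out.vertex_attrs[attr_name] = values
    return out


def diverging_change_colors(values_mm: np.ndarray, vmax: float = 50.0) -> np.ndarray:
    """Red-white-blue colors for height change in mm.

    0 -> white, +vmax -> full red, -vmax -> full blue; values beyond
    +-vmax are clamped (display truncation only — statistics are never
    truncated). NaN -> mid grey.
    """
    v = np.asarray(values_mm, dtype=np.float64)
    nanmask = ~np.isfinite(v)
    t = np.clip(np.where(nanmask, 0.0, v), -vmax, vmax) / vmax
    rgb = np.empty(v.shape + (3,), dtype=np.float64)
    pos = t >= 0
    rgb[pos] = np.stack([np.ones(pos.sum()), 1 - t[pos], 1 - t[pos]], axis=-1)
    rgb[~pos] = np.stack([1 + t[~pos], 1 + t[~pos], np.ones((~pos).sum())], axis=-1)
    out = np.round(rgb * 255).astype(np.uint8)
    out[nanmask] = (128, 128, 128)
    return out


def colorize(mesh: TriMesh, attr_name: str,
             scheme: ClassScheme | None = None, vmax: float = 50.0) -> TriMesh:
    """Set per-vertex colors from an attribute.

    Class attributes use the class scheme's display colors (nodata ->
    black); scalar attributes use the diverging red-white-blue map over
    ``[-vmax, +vmax]`` mm.
    """
    if attr_name not in mesh.vertex_attrs:
        raise KeyError(f"mesh has no attribute {attr_name!r}")
    vals = np.asarray(mesh.vertex_attrs[attr_name])
    if attr_name == "class_id" or vals.dtype.kind in "ui":
        scheme = scheme or DEFAULT_SCHEME
        colors = np.zeros((mesh.n_vertices, 3), dtype=np.uint8)
        for cid in scheme.ids:
            colors[vals == cid] = scheme.color_of(cid)
    else:
        colors = diverging_change_colors(vals, vmax=vmax)
    out = TriMesh(vertices=mesh.vertices, faces=mesh.faces,
                  vertex_attrs=dict(mesh.vertex_attrs))
    out.vertex_attrs["color"] = colors
    return out
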