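"""Multi-scale 3D roughness on dense point clouds.

Roughness of a point is its perpendicular distance to the
total-least-squares plane fitted to the point's neighbors within a
given radius (20 / 50 / 100 mm are the scales of interest: polyp to
colony). The query point itself is excluded from its own fit; fewer
than 3 valid (non-collinear) neighbors yields nodata for that point.
Labels are transferred onto points from a semantic raster by vertical
cell lookup, so distributions can be stratified by benthic class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import plyio
from .classes import LABEL_NODATA
from .errors import FormatError, ParameterError
from .raster_io import Raster

__all__ = ["LabeledCloud", "PlaneFit", "radius_neighbors", "fit_plane",
           "roughness", "transfer_labels", "ROUGHNESS_NODATA"]

#: sentinel for points whose plane fit is degenerate
ROUGHNESS_NODATA = np.nan


@dataclass
class LabeledCloud:
    """N x 3 point coordinates (m) with optional per-point class ids and
    named per-point scalars (e.g. ``roughness_r20``)."""

    xyz: np.ndarray
    class_id: np.ndarray | None = None
    scalars: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=np.float64)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise FormatError(f"xyz must be (N, 3), got {self.xyz.shape}")
        if not np.all(np.isfinite(self.xyz)):
            raise FormatError("point coordinates must be finite")
        if self.class_id is not None:
            self.class_id = np.asarray(self.class_id, dtype=np.uint8)
            if self.class_id.shape != (len(self.xyz),):
                raise FormatError("class_id must be one value per point")

    def __len__(self) -> int:
        return len(self.xyz)

    def save_ply(self, path, binary: bool = True) -> None:
        props = {
            "x": self.xyz[:, 0].astype(np.float64),
            "y": self.xyz[:, 1].astype(np.float64),
            "z": self.xyz[:, 2].astype(np.float64),
        }
        if self.class_id is not None:
            props["class_id"] = self.class_id
        for name, vals in self.scalars.items():
            props[name] = np.asarray(vals, dtype=np.float32)
        plyio.write_ply(path, props, binary=binary)

    @classmethod
    def load_ply(cls, path) -> "LabeledCloud":
        props, _ = plyio.read_ply(path)
        for axis in "xyz":
            if axis not in props:
                raise FormatError(f"PLY vertex element lacks property {axis!r}")
        xyz = np.column_stack([props.pop("x"), props.pop("y"), props.pop("z")])
        class_id = props.pop("class_id", None)
        return cls(xyz=xyz, class_id=class_id, scalars=dict(props))


@dataclass(frozen=True)
class PlaneFit:
    """Total-least-squares plane: centroid + unit normal + rms residual."""

    centroid: np.ndarray
    normal: np.ndarray
    rms_residual: float


def radius_neighbors(cloud: LabeledCloud, query_index: int, radius: float,
                     tree: cKDTree | None = None) -> np.ndarray:
    """Indices of all points within Euclidean distance <= radius of the
    query point, excluding the query point itself."""
    if radius <= 0:
        raise ParameterError(f"radius must be positive, got {radius}")
    if tree is None:
        tree = cKDTree(cloud.xyz)
    idx = tree.query_ball_point(cloud.xyz[query_index], radius)
    return np.array([i for i in idx if i != query_index], dtype=np.int64)


def fit_plane(points: np.ndarray) -> PlaneFit | None:
    """Fit a total-least-squares plane through >= 3 points.

    The normal is the eigenvector of the point covariance with the
    smallest eigenvalue. Returns ``None`` for degenerate input
    (< 3 points, or collinear within numerical rank).
    """
    points = np.asarray(points, dtype=np.float64)
    if len(points) < 3:
        return None
    centroid = points.mean(axis=0)
    d = points - centroid
    cov = d.T @ d
    evals, evecs = np.linalg.eigh(cov)
    # collinear: two near-zero eigenvalues relative to the largest
    scale = max(evals[-1], 1e-300)
    if evals[1] / scale < 1e-12:
        return None
    normal = evecs[:, 0]
    if normal[2] < 0:
        normal = -normal
    rms = float(np.sqrt(max(evals[0], 0.0) / len(points)))
    return PlaneFit(centroid=centroid, normal=normal, rms_residual=rms)


def point_plane_distance(point: np.ndarray, plane: PlaneFit) -> float:
    """Unsigned perpendicular distance of a point to a fitted plane."""
    return float(abs(np.dot(np.asarray(point) - plane.centroid, plane.normal)))


def roughness(cloud: LabeledCloud, radii, min_neighbors: int = 3) -> LabeledCloud:
    """Compute per-point roughness at each radius (m).

    Adds a scalar ``roughness_r<mm>`` per radius: the distance of each
    point to the plane fitted to its neighbors within that radius, NaN
    where the fit is degenerate. Returns a new cloud sharing
    coordinates and labels.
    """
    radii = [float(r) for r in np.atleast_1d(radii)]
    if any(r <= 0 for r in radii):
        raise ParameterError("all radii must be positive")
    tree = cKDTree(cloud.xyz)
    out = LabeledCloud(xyz=cloud.xyz, class_id=cloud.class_id,
                       scalars=dict(cloud.scalars))
    for r in radii:
        name = f"roughness_r{int(round(r * 1000))}"
        values = np.full(len(cloud), ROUGHNESS_NODATA, dtype=np.float64)
        neighbor_lists = tree.query_ball_point(cloud.xyz, r)
        for i, nbrs in enumerate(neighbor_lists):
            nbrs = [j for j in nbrs if j != i]
            if len(nbrs) < min_neighbors:
                continue
            plane = fit_plane(cloud.xyz[nbrs])
            if plane is None:
                continue
            values[i] = point_plane_distance(cloud.xyz[i], plane)
        out.scalars[name] = values
    return out


def transfer_labels(cloud: LabeledCloud, mask: Raster) -> LabeledCloud:
    """Label each point with the class of the raster cell containing its
    (x, y); points outside the raster or over nodata get the label
    nodata sentinel (255)."""
    if mask.band_meaning != "label":
        raise FormatError("transfer_labels requires a label raster")
    row, col = mask.transform.world_to_cell(cloud.xyz[:, 0], cloud.xyz[:, 1])
    rows, cols = mask.shape
    inside = (row >= 0) & (row < rows) & (col >= 0) & (col < cols)
    labels = np.full(len(cloud), LABEL_NODATA, dtype=np.uint8)
    labels[inside] = mask.data[row[inside], col[inside]]
    return LabeledCloud(xyz=cloud.xyz, class_id=labels,
                        scalars=dict(cloud.scalars))
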