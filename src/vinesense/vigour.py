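"""Digital vigour model: ground/canopy classification, DSM/DTM/DVM rasters,
trunk-centred zonal statistics and wire-height vigour classes.

Estimating vine height against a flat datum fails on sloping terrain, where
elevation can change more within a row than the height of the vines.  The
approach here removes the terrain: classify the dense point cloud into
ground and canopy, rasterise canopy tops (DSM) and a gap-filled bare-earth
surface (DTM), and subtract.  The difference — the digital vigour model
(DVM) — is terrain-free canopy height, summarised per plant in a small disc
around the trunk and mapped to the 1-5 vigour classes defined by the
trellis wires (bottom/middle/top at 1.2/1.55/1.75 m).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial import Delaunay, cKDTree

from .containers import CANOPY, GROUND, ElevationGrid, GeoTransform, PointCloud
from .errors import ValidationError

__all__ = [
    "ClassificationParams",
    "VigourThresholds",
    "ZonalParams",
    "classify_ground",
    "rasterize_dsm",
    "rasterize_dtm",
    "compute_dvm",
    "zonal_vigour",
    "assign_vigour_class",
    "classify_plants",
    "idw_interpolate",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClassificationParams:
    """Geometric constraints of the iterative ground filter.

    ``max_distance`` bounds the vertical distance between a candidate point
    and the provisional terrain surface; ``max_angle`` bounds the slope of
    the segment joining the candidate to the nearest accepted ground points,
    i.e. the maximum admissible ground slope within the scene.
    """

    max_distance: float = 0.6
    max_angle: float = 70.0
    grid_cell: float = 1.0

    def __post_init__(self) -> None:
        if self.max_distance <= 0:
            raise ValidationError("max_distance must be positive")
        if not 0 < self.max_angle < 90:
            raise ValidationError("max_angle must lie in (0, 90) degrees")


@dataclass(frozen=True)
class VigourThresholds:
    """Trellis wire heights (m) delimiting the five vigour classes."""

    bottom_wire: float = 1.2
    middle_wire: float = 1.55
    top_wire: float = 1.75
    dead_height: float = 0.1

    def __post_init__(self) -> None:
        if not 0 < self.dead_height < self.bottom_wire < self.middle_wire < self.top_wire:
            raise ValidationError(
                "need 0 < dead_height < bottom_wire < middle_wire < top_wire"
            )


@dataclass(frozen=True)
class ZonalParams:
    radius: float = 0.2
    statistics: tuple = ("max", "mean", "count")


# ---------------------------------------------------------------------------
# ground/canopy classification


def _seed_ground(cloud: PointCloud, grid_cell: float) -> np.ndarray:
    """Indices of the lowest point in each coarse grid cell."""
    cx = np.floor(cloud.x / grid_cell).astype(np.int64)
    cy = np.floor(cloud.y / grid_cell).astype(np.int64)
    order = np.lexsort((cloud.z, cx, cy))
    keys = np.stack([cy[order], cx[order]], axis=1)
    first = np.ones(len(order), dtype=bool)
    first[1:] = np.any(keys[1:] != keys[:-1], axis=1)
    return order[first]


_DEGENERATE_AREA = 1e-9


def _plane_slope_and_dist(tri_xyz: np.ndarray, pts: np.ndarray):
    """Per-candidate slope (deg) of its supporting plane and vertical distance.

    ``tri_xyz`` is (n, 3, 3): three plane-defining ground points per
    candidate.  Degenerate (collinear) triangles yield NaN slope.
    """
    e1 = tri_xyz[:, 1] - tri_xyz[:, 0]
    e2 = tri_xyz[:, 2] - tri_xyz[:, 0]
    normal = np.cross(e1, e2)
    area2 = np.linalg.norm(normal[:, :2], axis=1) ** 2 + normal[:, 2] ** 2
    horiz = np.hypot(normal[:, 0], normal[:, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.degrees(np.arctan2(horiz, np.abs(normal[:, 2])))
        # plane: normal . (p - v0) = 0 solved for z at the candidate (x, y)
        z_plane = tri_xyz[:, 0, 2] - (
            normal[:, 0] * (pts[:, 0] - tri_xyz[:, 0, 0])
            + normal[:, 1] * (pts[:, 1] - tri_xyz[:, 0, 1])
        ) / normal[:, 2]
    degenerate = (area2 < _DEGENERATE_AREA) | (np.abs(normal[:, 2]) < 1e-12)
    slope[degenerate] = np.nan
    z_plane[degenerate] = np.nan
    return slope, np.abs(pts[:, 2] - z_plane)


def _accept_points(xyz: np.ndarray, ground_idx: np.ndarray, cand_idx: np.ndarray,
                   params: ClassificationParams, tri: Delaunay) -> np.ndarray:
    """Candidates meeting the surface-distance and slope constraints this round.

    A candidate joins the ground when the supporting facet of the provisional
    surface — its containing TIN triangle, or the plane of its three nearest
    ground points outside the hull — has slope ≤ ``max_angle`` (the maximum
    admissible ground slope) and the candidate lies within ``max_distance``
    vertically of that plane.  When the supporting points are collinear the
    test degrades to the segment to the nearest ground point (distance and
    inclination bounds).
    """
    if cand_idx.size == 0:
        return cand_idx
    pts = xyz[cand_idx]
    gxyz = xyz[ground_idx]
    simplex = tri.find_simplex(pts[:, :2])
    inside = simplex >= 0
    accepted = np.zeros(len(cand_idx), dtype=bool)

    if np.any(inside):
        sub = np.flatnonzero(inside)
        verts = tri.simplices[simplex[sub]]
        slope, vdist = _plane_slope_and_dist(gxyz[verts], pts[sub])
        ok = (vdist <= params.max_distance) & (slope <= params.max_angle)
        accepted[sub] = np.where(np.isnan(slope), False, ok)

    if np.any(~inside):
        # outside the provisional hull: plane through the 3 nearest ground pts
        sub = np.flatnonzero(~inside)
        tree = cKDTree(gxyz[:, :2])
        k = min(3, len(gxyz))
        _, nn = tree.query(pts[sub, :2], k=k)
        nn = np.atleast_2d(nn.reshape(len(sub), -1))
        if k == 3:
            slope, vdist = _plane_slope_and_dist(gxyz[nn], pts[sub])
        else:
            slope = np.full(len(sub), np.nan)
            vdist = np.full(len(sub), np.nan)
        plane_ok = (vdist <= params.max_distance) & (slope <= params.max_angle)

        # degenerate support: segment to the nearest ground point
        dz = np.abs(pts[sub, 2] - gxyz[nn[:, 0], 2])
        dh = np.hypot(pts[sub, 0] - gxyz[nn[:, 0], 0],
                      pts[sub, 1] - gxyz[nn[:, 0], 1])
        with np.errstate(divide="ignore", invalid="ignore"):
            angle = np.degrees(np.arctan2(dz, dh))
        segment_ok = (dz <= params.max_distance) & (angle <= params.max_angle)
        accepted[sub] = np.where(np.isnan(slope), segment_ok, plane_ok)

    return cand_idx[accepted]


def classify_ground(cloud: PointCloud,
                    params: ClassificationParams | None = None) -> PointCloud:
    """Label every point ground or canopy by iterative surface densification.

    Seeds the terrain with per-cell minima on a coarse grid, triangulates
    them into a provisional surface, then repeatedly admits points that lie
    within ``max_distance`` vertically of the surface and whose connecting
    segments to the supporting vertices stay below ``max_angle``, until a
    fixpoint.  Everything not admitted is canopy.  Prior labels are ignored,
    so the operation is idempotent.
    """
    params = params or ClassificationParams()
    if len(cloud) == 0:
        raise ValidationError("cannot classify an empty cloud")

    xyz = cloud.xyz
    seeds = _seed_ground(cloud, params.grid_cell)
    xy_seed = np.unique(np.round(xyz[seeds, :2], 9), axis=0)
    if len(xy_seed) < 3 or np.linalg.matrix_rank(xy_seed - xy_seed[0]) < 2:
        raise ValidationError(
            "degenerate geometry: ground seeds do not span a plane "
            "(are all points in one vertical column?)"
        )

    is_ground = np.zeros(len(cloud), dtype=bool)
    is_ground[seeds] = True
    while True:
        ground_idx = np.flatnonzero(is_ground)
        tri = Delaunay(xyz[ground_idx, :2])
        cand_idx = np.flatnonzero(~is_ground)
        newly = _accept_points(xyz, ground_idx, cand_idx, params, tri)
        if newly.size == 0:
            break
        is_ground[newly] = True

    labels = np.where(is_ground, GROUND, CANOPY).astype(np.uint8)
    return PointCloud(xyz.copy(), labels)


# ---------------------------------------------------------------------------
# rasterisation


def _grid_for(xy: np.ndarray, cell: float) -> tuple[GeoTransform, tuple[int, int]]:
    x0 = np.floor(xy[:, 0].min() / cell) * cell
    y1 = np.ceil(xy[:, 1].max() / cell) * cell
    ncols = int(np.ceil((xy[:, 0].max() - x0) / cell)) + 1
    nrows = int(np.ceil((y1 - xy[:, 1].min()) / cell)) + 1
    return GeoTransform(x0, y1, cell), (nrows, ncols)


def _cell_indices(transform: GeoTransform, shape, x, y):
    row, col = transform.index_of(x, y)
    ok = (row >= 0) & (row < shape[0]) & (col >= 0) & (col < shape[1])
    return row, col, ok


def rasterize_dsm(cloud: PointCloud, cell: float = 0.05,
                  grid: tuple[GeoTransform, tuple[int, int]] | None = None) -> ElevationGrid:
    """Surface model: per-cell maximum z over all points; empty cells nodata."""
    if len(cloud) == 0:
        raise ValidationError("cannot rasterize an empty cloud")
    transform, shape = grid if grid is not None else _grid_for(cloud.xyz[:, :2], cell)
    values = np.full(shape, -np.inf)
    row, col, ok = _cell_indices(transform, shape, cloud.x, cloud.y)
    np.maximum.at(values, (row[ok], col[ok]), cloud.z[ok])
    values[~np.isfinite(values)] = np.nan
    return ElevationGrid(values, transform, role="DSM")


def rasterize_dtm(ground: PointCloud, cell: float = 0.05,
                  grid: tuple[GeoTransform, tuple[int, int]] | None = None,
                  idw_neighbours: int = 8) -> ElevationGrid:
    """Bare-earth model: per-cell mean of ground points, gaps interpolated.

    Cells without ground returns (under the canopy) are filled by linear
    interpolation on the triangulation of populated cell centres; cells
    outside that hull fall back to inverse-distance weighting over the
    ``idw_neighbours`` nearest populated cells, so no nodata remains.
    """
    mask = ground.labels == GROUND
    pts = ground.subset(mask) if mask.any() else ground
    if len(pts) < 3:
        raise ValidationError(f"need at least 3 ground points, got {len(pts)}")
    transform, shape = grid if grid is not None else _grid_for(pts.xyz[:, :2], cell)

    total = np.zeros(shape)
    count = np.zeros(shape, dtype=np.int64)
    row, col, ok = _cell_indices(transform, shape, pts.x, pts.y)
    np.add.at(total, (row[ok], col[ok]), pts.z[ok])
    np.add.at(count, (row[ok], col[ok]), 1)
    with np.errstate(invalid="ignore"):
        values = np.where(count > 0, total / np.maximum(count, 1), np.nan)

    holes = count == 0
    if np.any(holes):
        filled_rc = np.argwhere(~holes)
        if len(filled_rc) < 3:
            raise ValidationError("too few populated DTM cells to interpolate")
        fx, fy = transform.cell_center(filled_rc[:, 0], filled_rc[:, 1])
        hole_rc = np.argwhere(holes)
        hx, hy = transform.cell_center(hole_rc[:, 0], hole_rc[:, 1])
        interp = LinearNDInterpolator(np.column_stack([fx, fy]),
                                      values[~holes], fill_value=np.nan)
        est = interp(np.column_stack([hx, hy]))
        outside = ~np.isfinite(est)
        if np.any(outside):  # IDW fallback beyond the ground hull
            tree = cKDTree(np.column_stack([fx, fy]))
            k = min(idw_neighbours, len(fx))
            dist, idx = tree.query(np.column_stack([hx, hy])[outside], k=k)
            dist = np.atleast_2d(dist)
            idx = np.atleast_2d(idx)
            w = 1.0 / np.maximum(dist, 1e-12) ** 2
            est[outside] = (w * values[~holes][idx]).sum(axis=1) / w.sum(axis=1)
        values[holes] = est
    return ElevationGrid(values, transform, role="DTM")


def compute_dvm(dsm: ElevationGrid, dtm: ElevationGrid,
                negative_tolerance: float = 0.05) -> ElevationGrid:
    """DVM = DSM − DTM, clipped to non-negative heights.

    Interpolation can leave small negatives; values below
    ``-negative_tolerance`` are counted and logged before clipping.  Cells
    where the DSM is nodata stay nodata.
    """
    if dsm.shape != dtm.shape or dsm.transform != dtm.transform:
        raise ValidationError("DSM and DTM must share one grid")
    diff = dsm.values - dtm.values
    n_neg = int(np.count_nonzero(diff < -negative_tolerance))
    if n_neg:
        log.warning("DVM: %d cell(s) below -%.2f m before clipping",
                    n_neg, negative_tolerance)
    values = np.clip(diff, 0.0, None)
    values[~np.isfinite(dsm.values)] = np.nan
    return ElevationGrid(values, dsm.transform, role="DVM")


# ---------------------------------------------------------------------------
# per-plant statistics and classes


def zonal_vigour(dvm: ElevationGrid, plants,
                 params: ZonalParams | None = None) -> pd.DataFrame:
    """Height statistics over DVM cells within ``radius`` of each trunk.

    A cell contributes when its centre lies inside the disc; ``count`` is
    the number of contributing finite cells.  Plants with no cells in reach
    (radius below the cell size) get missing stats and a warning.
    """
    params = params or ZonalParams()
    rows_out = []
    nrows, ncols = dvm.shape
    t = dvm.transform
    for plant in plants:
        px, py = plant.x, plant.y
        r0 = max(0, int(np.floor((t.origin_y - (py + params.radius)) / t.cell)))
        r1 = min(nrows - 1, int(np.ceil((t.origin_y - (py - params.radius)) / t.cell)))
        c0 = max(0, int(np.floor(((px - params.radius) - t.origin_x) / t.cell)))
        c1 = min(ncols - 1, int(np.ceil(((px + params.radius) - t.origin_x) / t.cell)))
        stats = {"tree_number": plant.tree_number, "max": np.nan, "mean": np.nan,
                 "count": 0}
        if r1 >= r0 and c1 >= c0:
            rr, cc = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
            cx, cy = t.cell_center(rr, cc)
            inside = (cx - px) ** 2 + (cy - py) ** 2 <= params.radius**2
            vals = dvm.values[rr[inside], cc[inside]]
            vals = vals[np.isfinite(vals)]
            if vals.size:
                stats["max"] = float(vals.max())
                stats["mean"] = float(vals.mean())
                stats["count"] = int(vals.size)
        if stats["count"] == 0:
            log.warning("plant %s: no DVM cells within %.2f m of trunk",
                        plant.tree_number, params.radius)
        rows_out.append(stats)
    return pd.DataFrame(rows_out).set_index("tree_number")


def assign_vigour_class(height, thresholds: VigourThresholds | None = None):
    """Map canopy height (m) to vigour class 1-5 against the trellis wires.

    Class 5 at or above the top wire; 4 between middle and top; 3 between
    bottom and middle; 2 above ``dead_height`` but below the bottom wire;
    1 (dead) at or below ``dead_height``.  Accepts scalars or arrays.
    """
    th = thresholds or VigourThresholds()
    h = np.asarray(height, dtype=float)
    cls = np.select(
        [h >= th.top_wire, h >= th.middle_wire, h >= th.bottom_wire, h > th.dead_height],
        [5, 4, 3, 2],
        default=1,
    )
    return int(cls) if np.isscalar(height) else cls


def classify_plants(zonal: pd.DataFrame, thresholds: VigourThresholds | None = None,
                    statistic: str = "max") -> pd.Series:
    """Vigour class per plant from zonal heights; no canopy cells → class 1."""
    th = thresholds or VigourThresholds()
    heights = zonal[statistic].to_numpy(float)
    cls = assign_vigour_class(np.nan_to_num(heights, nan=0.0), th)
    cls = np.where((zonal["count"].to_numpy() == 0) | ~np.isfinite(heights), 1, cls)
    return pd.Series(cls, index=zonal.index, name="dvm_class")


def idw_interpolate(xy: np.ndarray, values: np.ndarray,
                    grid: tuple[GeoTransform, tuple[int, int]],
                    power: float = 2.0, max_radius: float | None = None) -> ElevationGrid:
    """Inverse-distance-weighted raster from per-plant samples.

    Exact at sample locations; output bounded by the sample min/max (weights
    are convex).  Cells farther than ``max_radius`` from every sample are
    nodata.
    """
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    values = np.asarray(values, dtype=float).reshape(-1)
    if len(xy) != len(values) or len(xy) == 0:
        raise ValidationError("need matching, non-empty samples")
    transform, shape = grid
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    cx, cy = transform.cell_center(rows.ravel(), cols.ravel())
    cells = np.column_stack([cx, cy])

    tree = cKDTree(xy)
    k = min(12, len(xy))
    dist, idx = tree.query(cells, k=k)
    dist = np.atleast_2d(dist.reshape(len(cells), -1))
    idx = np.atleast_2d(idx.reshape(len(cells), -1))
    out = np.full(len(cells), np.nan)

    exact = dist[:, 0] < 1e-9
    out[exact] = values[idx[exact, 0]]
    rest = ~exact
    if max_radius is not None:
        within = dist <= max_radius
        rest &= within.any(axis=1)
    else:
        within = np.ones_like(dist, dtype=bool)
    w = np.where(within, 1.0 / np.maximum(dist, 1e-12) ** power, 0.0)
    denom = w[rest].sum(axis=1)
    out[rest] = (w[rest] * values[idx[rest]]).sum(axis=1) / denom
    return ElevationGrid(out.reshape(shape), transform, role="DVM")
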