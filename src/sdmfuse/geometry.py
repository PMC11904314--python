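"""Study domain, regular grid discretization, and quadrature.

The expected number of points of an inhomogeneous Poisson process over a
region Ω is ∫_Ω λ(s) ds, which is intractable for a log-Gaussian intensity
and is approximated by a quadrature rule: points s_j with positive weights
w_j (km²) such that Σ_j w_j = |Ω|.  Here the rule is midpoint quadrature on
a regular grid clipped to the domain polygon: one node per grid cell that
intersects Ω, weighted by the clipped cell area.  Nodes sit at the centroid
of the clipped cell region so that every node lies inside Ω even along the
boundary (for interior cells this is exactly the cell midpoint).

All geometry is planar with km units; geographic coordinates must be
projected first (see :func:`sdmfuse.data_io.project_lonlat`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import shape as shapely_shape
from shapely.geometry.base import BaseGeometry

from .errors import SDMFuseError

#: clipped cells smaller than this (km²) are dropped from quadrature schemes
MIN_CELL_AREA = 1e-12


@dataclass(frozen=True)
class SpatialDomain:
    """Planar study region Ω (simple polygon or multipolygon, km units)."""

    boundary: BaseGeometry

    def __post_init__(self):
        if self.boundary.is_empty or self.boundary.area <= 0:
            raise SDMFuseError("empty-domain", "domain polygon has zero area")
        if not self.boundary.is_valid:
            raise SDMFuseError("empty-domain", "domain polygon is not simple/valid")

    @property
    def area(self) -> float:
        """Area |Ω| in km²."""
        return float(self.boundary.area)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return tuple(self.boundary.bounds)

    def contains(self, x, y) -> np.ndarray:
        """Vectorized point-in-domain test (boundary counts as inside)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return shapely.intersects(self.boundary, shapely.points(x, y))

    @classmethod
    def from_geojson(cls, path) -> "SpatialDomain":
        """Load a Polygon/MultiPolygon from a GeoJSON file.

        Accepts a bare geometry, a Feature, or a FeatureCollection whose
        first feature carries the domain polygon.
        """
        with open(path) as fh:
            obj = json.load(fh)
        if obj.get("type") == "FeatureCollection":
            obj = obj["features"][0]
        if obj.get("type") == "Feature":
            obj = obj["geometry"]
        return cls(shapely_shape(obj))

    def to_geojson(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(shapely.geometry.mapping(self.boundary), fh)


@dataclass(frozen=True)
class Grid:
    """Regular nx × ny grid over a bounding box, clipped to a domain.

    Cells are indexed row-major, ``i = iy * nx + ix``; cell (ix, iy) spans
    ``[x0 + ix·dx, x0 + (ix+1)·dx] × [y0 + iy·dy, y0 + (iy+1)·dy]``.
    """

    nx: int
    ny: int
    x0: float
    y0: float
    dx: float
    dy: float
    inside: np.ndarray = field(repr=False)  # (nx*ny,) bool
    clipped_area: np.ndarray = field(repr=False)  # (nx*ny,) km²
    domain: SpatialDomain | None = None

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    @property
    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Cell-center coordinates as two (nx*ny,) arrays."""
        cx = self.x0 + (np.arange(self.nx) + 0.5) * self.dx
        cy = self.y0 + (np.arange(self.ny) + 0.5) * self.dy
        gx, gy = np.meshgrid(cx, cy)  # row-major: y outer
        return gx.ravel(), gy.ravel()

    @property
    def cell_area(self) -> float:
        return self.dx * self.dy

    def cell_index(self, x, y) -> np.ndarray:
        """Index of the cell containing each point (clipped to the grid)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        ix = np.clip(np.floor((x - self.x0) / self.dx).astype(int), 0, self.nx - 1)
        iy = np.clip(np.floor((y - self.y0) / self.dy).astype(int), 0, self.ny - 1)
        return iy * self.nx + ix

    def in_extent(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (
            (x >= self.x0)
            & (x <= self.x0 + self.nx * self.dx)
            & (y >= self.y0)
            & (y <= self.y0 + self.ny * self.dy)
        )


@dataclass(frozen=True)
class IntegrationScheme:
    """Quadrature nodes s_j (km) and weights w_j (km²) with Σ w_j = |Ω|."""

    points: np.ndarray  # (m, 2)
    weights: np.ndarray  # (m,)

    def __post_init__(self):
        if np.any(self.weights <= 0):
            raise SDMFuseError("empty-scheme", "non-positive quadrature weight")

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())

    def integrate(self, f) -> float:
        """Approximate ∫_Ω f(s) ds with the rule; f takes (x, y) arrays."""
        return float(self.weights @ f(self.points[:, 0], self.points[:, 1]))


def make_grid(domain: SpatialDomain, nx: int, ny: int) -> Grid:
    """Tile the domain's bounding box into nx × ny cells and clip to Ω.

    Clipped areas are exact polygon intersections, so they sum to |Ω|
    regardless of resolution.
    """
    if nx < 2 or ny < 2:
        raise SDMFuseError("grid-too-coarse", f"nx={nx}, ny={ny}; need at least 2×2")
    xmin, ymin, xmax, ymax = domain.bounds
    dx = (xmax - xmin) / nx
    dy = (ymax - ymin) / ny
    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny))
    ix, iy = ix.ravel(), iy.ravel()
    boxes = shapely.box(
        xmin + ix * dx, ymin + iy * dy, xmin + (ix + 1) * dx, ymin + (iy + 1) * dy
    )
    clipped = shapely.area(shapely.intersection(boxes, domain.boundary))
    return Grid(
        nx=nx,
        ny=ny,
        x0=xmin,
        y0=ymin,
        dx=dx,
        dy=dy,
        inside=clipped > MIN_CELL_AREA,
        clipped_area=clipped,
        domain=domain,
    )


def build_integration_scheme(grid: Grid, domain: SpatialDomain | None = None) -> IntegrationScheme:
    """One quadrature node per cell intersecting Ω, weight = clipped area.

    Interior cells contribute their midpoint; boundary cells contribute the
    centroid of the clipped region so the node is inside Ω.
    """
    domain = domain if domain is not None else grid.domain
    if domain is None:
        raise SDMFuseError("empty-domain", "grid has no associated domain")
    keep = np.flatnonzero(grid.clipped_area > MIN_CELL_AREA)
    if keep.size == 0:
        raise SDMFuseError("empty-scheme", "no grid cell intersects the domain")
    cx, cy = grid.centers
    px, py = cx[keep].copy(), cy[keep].copy()
    w = grid.clipped_area[keep]

    # move nodes of partially clipped cells to the clipped region's centroid
    partial = np.flatnonzero(w < grid.cell_area * (1 - 1e-12))
    if partial.size:
        ixs = keep[partial] % grid.nx
        iys = keep[partial] // grid.nx
        boxes = shapely.box(
            grid.x0 + ixs * grid.dx,
            grid.y0 + iys * grid.dy,
            grid.x0 + (ixs + 1) * grid.dx,
            grid.y0 + (iys + 1) * grid.dy,
        )
        pieces = shapely.intersection(boxes, domain.boundary)
        cent = shapely.centroid(pieces)
        ok = shapely.intersects(pieces, cent)
        rep = shapely.point_on_surface(pieces)
        px[partial] = np.where(ok, shapely.get_x(cent), shapely.get_x(rep))
        py[partial] = np.where(ok, shapely.get_y(cent), shapely.get_y(rep))

    return IntegrationScheme(points=np.column_stack([px, py]), weights=w)


def scheme_to_frame(scheme: IntegrationScheme):
    """Serialize a scheme as a (x, y, weight) table."""
    import pandas as pd

    return pd.DataFrame(
        {"x": scheme.points[:, 0], "y": scheme.points[:, 1], "weight": scheme.weights}
    )
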