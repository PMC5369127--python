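"""Referent grid and spatialization engine.

Every raw layer — point samples, polygon zones, site inventories, finer or
offset rasters — is discretized onto a single regular metric lattice (the
*referent grid*, 1 km² cells by default) before any indicator arithmetic.
Coordinates are planar metric throughout; a projected CRS is assumed
upstream and no geodesy is performed.

Cell indexing is row-major from the top-left: cell (i, j) covers the
half-open square [x0 + j·s, x0 + (j+1)·s) × (y0 − (i+1)·s, y0 − i·s], which
prevents double counting on shared edges.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import lu_factor, lu_solve
from scipy.optimize import least_squares
from scipy.spatial.distance import cdist
import shapely
from shapely.geometry import Point, box
from shapely.strtree import STRtree

__all__ = [
    "ReferentGrid",
    "RasterField",
    "ZoneMap",
    "SiteSet",
    "build_referent_grid",
    "aggregate_surface_ratio",
    "rasterize_zones",
    "buffer_partition",
    "interpolate_points",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferentGrid:
    """Regular lattice with top-left origin and row-major indexing.

    Parameters
    ----------
    x0, y0
        Coordinates of the grid's top-left corner, metres.
    cell_size
        Side length of the square cells, metres.
    n_rows, n_cols
        Lattice dimensions.
    """

    x0: float
    y0: float
    cell_size: float
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the full lattice footprint."""
        s = self.cell_size
        return (self.x0, self.y0 - self.n_rows * s, self.x0 + self.n_cols * s, self.y0)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (X, Y), each of shape (n_rows, n_cols), of cell centres."""
        s = self.cell_size
        xs = self.x0 + (np.arange(self.n_cols) + 0.5) * s
        ys = self.y0 - (np.arange(self.n_rows) + 0.5) * s
        return np.meshgrid(xs, ys)

    def cell_box(self, i: int, j: int):
        """Shapely box of cell (i, j)."""
        s = self.cell_size
        return box(self.x0 + j * s, self.y0 - (i + 1) * s,
                   self.x0 + (j + 1) * s, self.y0 - i * s)

    def cell_index(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/column indices of the cells containing planar points.

        Points outside the lattice get clipped indices; callers that care
        should bounds-check against :attr:`extent` first.
        """
        s = self.cell_size
        j = np.clip(np.floor((np.asarray(x) - self.x0) / s).astype(int), 0, self.n_cols - 1)
        i = np.clip(np.floor((self.y0 - np.asarray(y)) / s).astype(int), 0, self.n_rows - 1)
        return i, j


@dataclass
class RasterField:
    """Per-cell values on a :class:`ReferentGrid` with a validity mask.

    ``mask`` is True where the cell holds a valid value; False marks
    nodata ("no measurement possible"), which is distinct from a measured
    zero exposure.
    """

    grid: ReferentGrid
    values: np.ndarray
    mask: np.ndarray | None = None
    units: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}")
        if self.mask is None:
            self.mask = np.ones(self.grid.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.grid.shape:
                raise ValueError("mask shape does not match grid shape")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError(f"non-finite values inside the valid mask of {self.name!r}")

    @property
    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]

    def copy_with(self, values: np.ndarray, name: str | None = None,
                  units: str | None = None, mask: np.ndarray | None = None) -> "RasterField":
        return RasterField(
            grid=self.grid,
            values=values,
            mask=self.mask.copy() if mask is None else mask,
            units=self.units if units is None else units,
            name=self.name if name is None else name,
        )


@dataclass
class ZoneMap:
    """Polygon partition (or cover) with one numeric attribute per zone."""

    ids: list
    polygons: list
    attributes: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.attributes = np.asarray(self.attributes, dtype=float)
        if len(self.ids) != len(set(self.ids)):
            raise ValueError("zone identifiers must be unique")
        if not (len(self.ids) == len(self.polygons) == len(self.attributes)):
            raise ValueError("ids, polygons and attributes must have equal length")
        bad = [zid for zid, p in zip(self.ids, self.polygons) if not p.is_valid]
        if bad:
            raise ValueError(f"invalid (self-intersecting) polygon geometry for zones {bad}")

    def __len__(self) -> int:
        return len(self.ids)

    def with_attributes(self, attributes: np.ndarray, name: str | None = None) -> "ZoneMap":
        return ZoneMap(ids=list(self.ids), polygons=list(self.polygons),
                       attributes=attributes, name=self.name if name is None else name)


@dataclass
class SiteSet:
    """Point locations of potentially contaminated sites."""

    xy: np.ndarray

    def __post_init__(self) -> None:
        self.xy = np.atleast_2d(np.asarray(self.xy, dtype=float))
        if self.xy.size and self.xy.shape[1] != 2:
            raise ValueError("site coordinates must be an (n, 2) array")
        if not np.all(np.isfinite(self.xy)):
            raise ValueError("site coordinates must be finite")

    def __len__(self) -> int:
        return 0 if self.xy.size == 0 else self.xy.shape[0]


# ---------------------------------------------------------------------------
# Grid construction
# ---------------------------------------------------------------------------

def build_referent_grid(extent: tuple[float, float, float, float],
                        cell_size: float) -> ReferentGrid:
    """Smallest grid of ``cell_size`` squares covering ``extent``.

    The origin snaps to the extent's top-left corner; the last row/column
    may overhang the extent (ceiling rule).
    """
    xmin, ymin, xmax, ymax = map(float, extent)
    if not (xmax > xmin and ymax > ymin):
        raise ValueError(f"degenerate extent {extent}")
    if cell_size <= 0:
        raise ValueError(f"cell_size must be > 0, got {cell_size}")
    # guard against float fuzz turning an exact division into an extra cell
    eps = 1e-9
    n_cols = max(1, math.ceil((xmax - xmin) / cell_size - eps))
    n_rows = max(1, math.ceil((ymax - ymin) / cell_size - eps))
    return ReferentGrid(x0=xmin, y0=ymax, cell_size=cell_size,
                        n_rows=n_rows, n_cols=n_cols)


# ---------------------------------------------------------------------------
# Surface-ratio aggregation between axis-aligned grids
# ---------------------------------------------------------------------------

def _interval_overlaps(starts_a, size_a, n_a, starts_b, size_b, n_b) -> np.ndarray:
    """(n_a, n_b) matrix of 1-D overlap lengths between two interval families."""
    a0 = np.asarray(starts_a)[:, None]
    b0 = np.asarray(starts_b)[None, :]
    lo = np.maximum(a0, b0)
    hi = np.minimum(a0 + size_a, b0 + size_b)
    return np.clip(hi - lo, 0.0, None)


def aggregate_surface_ratio(source: RasterField, target: ReferentGrid,
                            kind: str = "intensive") -> RasterField:
    """Transfer a raster onto the referent grid with overlap-area weights.

    ``intensive`` quantities (concentrations, Lden) take the overlap-area
    weighted mean of valid source cells; ``extensive`` quantities
    (emissions, population counts) are split proportionally to overlap
    area so totals are conserved. A target cell is nodata iff no valid
    source cell overlaps it.
    """
    if kind not in ("intensive", "extensive"):
        raise ValueError(f"kind must be 'intensive' or 'extensive', got {kind!r}")
    sg = source.grid
    # 1-D overlaps along x (columns) and y (rows); rows run downward from y0
    tx = target.x0 + np.arange(target.n_cols) * target.cell_size
    sx = sg.x0 + np.arange(sg.n_cols) * sg.cell_size
    wx = _interval_overlaps(tx, target.cell_size, target.n_cols,
                            sx, sg.cell_size, sg.n_cols)          # (tc, sc)
    ty = target.y0 - (np.arange(target.n_rows) + 1) * target.cell_size
    sy = sg.y0 - (np.arange(sg.n_rows) + 1) * sg.cell_size
    wy = _interval_overlaps(ty, target.cell_size, target.n_rows,
                            sy, sg.cell_size, sg.n_rows)          # (tr, sr)

    v = np.where(source.mask, source.values, 0.0)
    m = source.mask.astype(float)
    weighted = wy @ v @ wx.T                 # Σ v·area over valid source cells
    cover = wy @ m @ wx.T                    # Σ area over valid source cells
    tiny = 1e-12 * sg.cell_size ** 2
    valid = cover > tiny
    out = np.zeros(target.shape)
    if kind == "intensive":
        out[valid] = weighted[valid] / cover[valid]
        units = source.units
    else:
        out[valid] = weighted[valid] / (sg.cell_size ** 2)
        units = source.units
    return RasterField(grid=target, values=out, mask=valid, units=units,
                       name=source.name)


# ---------------------------------------------------------------------------
# Zone rasterization
# ---------------------------------------------------------------------------

def rasterize_zones(zones: ZoneMap, grid: ReferentGrid) -> RasterField:
    """Area-weighted mean of the zone attribute per referent cell.

    Cells not covered by any zone are nodata.
    """
    tree = STRtree(zones.polygons)
    values = np.zeros(grid.shape)
    mask = np.zeros(grid.shape, dtype=bool)
    for i in range(grid.n_rows):
        for j in range(grid.n_cols):
            cell = grid.cell_box(i, j)
            idx = tree.query(cell)
            if len(idx) == 0:
                continue
            w_total = 0.0
            acc = 0.0
            for k in idx:
                a = cell.intersection(zones.polygons[k]).area
                if a > 0.0:
                    w_total += a
                    acc += a * zones.attributes[k]
            if w_total > 1e-9 * grid.cell_size ** 2:
                values[i, j] = acc / w_total
                mask[i, j] = True
    return RasterField(grid=grid, values=values, mask=mask, name=zones.name)


# ---------------------------------------------------------------------------
# Buffer partitioning around sites
# ---------------------------------------------------------------------------

def buffer_partition(sites: SiteSet, radius_m: float, grid: ReferentGrid,
                     quad_segs: int = 128) -> RasterField:
    """Proximity density: per cell, summed buffer-overlap fractions.

    Each site contributes area(cell ∩ disc(site, radius)) / area(cell);
    overlapping buffers from distinct sites are summed (site *density*),
    not unioned. Cells far from every site score 0 (valid, not nodata).
    """
    if radius_m <= 0:
        raise ValueError(f"radius_m must be > 0, got {radius_m}")
    s = grid.cell_size
    cell_area = s * s
    values = np.zeros(grid.shape)
    for x, y in np.atleast_2d(sites.xy) if len(sites) else []:
        disc = Point(x, y).buffer(radius_m, quad_segs=quad_segs)
        # regular lattice: restrict to the cells the disc's bbox touches
        j0 = max(0, int(math.floor((x - radius_m - grid.x0) / s)))
        j1 = min(grid.n_cols - 1, int(math.floor((x + radius_m - grid.x0) / s)))
        i0 = max(0, int(math.floor((grid.y0 - (y + radius_m)) / s)))
        i1 = min(grid.n_rows - 1, int(math.floor((grid.y0 - (y - radius_m)) / s)))
        for i in range(i0, i1 + 1):
            for j in range(j0, j1 + 1):
                a = grid.cell_box(i, j).intersection(disc).area
                if a > 0.0:
                    values[i, j] += a / cell_area
    return RasterField(grid=grid, values=values, name="site_proximity",
                       units="buffer area fraction")


# ---------------------------------------------------------------------------
# Point-to-grid interpolation
# ---------------------------------------------------------------------------

def _dedupe_points(xy: np.ndarray, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average values at duplicated locations (kriging system would be singular)."""
    order = np.lexsort((xy[:, 1], xy[:, 0]))
    xy_s, v_s = xy[order], values[order]
    uniq, inv = np.unique(xy_s, axis=0, return_inverse=True)
    if len(uniq) == len(xy_s):
        return xy, values
    warnings.warn("duplicate sample locations: averaging values per location",
                  stacklevel=3)
    sums = np.bincount(inv, weights=v_s)
    counts = np.bincount(inv)
    return uniq, sums / counts


def _exponential_variogram(h, nugget, sill, rng_):
    return nugget + sill * (1.0 - np.exp(-h / rng_))


def _fit_variogram(xy: np.ndarray, values: np.ndarray, n_bins: int = 12):
    """WLS fit of an isotropic exponential variogram to the empirical cloud."""
    d = cdist(xy, xy)
    iu = np.triu_indices(len(xy), k=1)
    h = d[iu]
    g = 0.5 * (values[:, None] - values[None, :])[iu] ** 2
    hmax = np.quantile(h, 0.7)
    edges = np.linspace(0.0, hmax, n_bins + 1)
    centers, gammas, counts = [], [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (h > lo) & (h <= hi)
        if sel.sum() >= 5:
            centers.append(h[sel].mean())
            gammas.append(g[sel].mean())
            counts.append(sel.sum())
    centers = np.asarray(centers)
    gammas = np.asarray(gammas)
    counts = np.asarray(counts)
    if len(centers) < 3:
        raise ValueError("too few distinct lags to fit a variogram")
    var = values.var()
    x0 = np.array([0.1 * var + 1e-12, max(var, 1e-12), max(centers.mean(), 1e-9)])

    def resid(p):
        return np.sqrt(counts) * (_exponential_variogram(centers, *p) - gammas)

    lb = [0.0, 1e-12, 1e-9]
    ub = [np.inf, np.inf, np.inf]
    fit = least_squares(resid, x0, bounds=(lb, ub))
    return tuple(fit.x)


def interpolate_points(xy: np.ndarray, values: np.ndarray, grid: ReferentGrid,
                       method: str = "idw", params: dict | None = None) -> RasterField:
    """Interpolate scattered samples to cell centres.

    ``idw``: inverse-distance weighting with exponent ``params['power']``
    (default 2); a sample within 1e-9 m of a cell centre is returned
    exactly. ``ordinary_kriging``: isotropic exponential variogram fitted
    by weighted least squares on the empirical variogram, then the
    ordinary-kriging system solved per cell centre.
    """
    params = dict(params or {})
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    values = np.asarray(values, dtype=float)
    if xy.size == 0:
        raise ValueError("no samples to interpolate")
    if method not in ("idw", "ordinary_kriging"):
        raise ValueError(f"unknown interpolation method {method!r}")
    if method == "ordinary_kriging" and len(xy) < 10:
        raise ValueError("ordinary kriging needs at least 10 samples")
    xy, values = _dedupe_points(xy, values)

    X, Y = grid.cell_centers()
    centers = np.column_stack([X.ravel(), Y.ravel()])
    d = cdist(centers, xy)

    if method == "idw":
        p = float(params.get("power", 2.0))
        exact = d < 1e-9
        with np.errstate(divide="ignore"):
            w = d ** (-p)
        w[exact.any(axis=1)] = 0.0
        w[exact] = 1.0
        out = (w @ values) / w.sum(axis=1)
    else:
        nugget, sill, vr = params.get("variogram", (None, None, None))
        if nugget is None:
            nugget, sill, vr = _fit_variogram(xy, values)
        n = len(xy)
        gamma = _exponential_variogram(cdist(xy, xy), nugget, sill, vr)
        np.fill_diagonal(gamma, 0.0)
        A = np.empty((n + 1, n + 1))
        A[:n, :n] = gamma
        A[n, :n] = 1.0
        A[:n, n] = 1.0
        A[n, n] = 0.0
        lu = lu_factor(A)
        B = np.empty((n + 1, len(centers)))
        B[:n] = _exponential_variogram(d.T, nugget, sill, vr)
        B[n] = 1.0
        lam = lu_solve(lu, B)[:n]
        out = lam.T @ values

    return RasterField(grid=grid, values=out.reshape(grid.shape),
                       name="interpolated")
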