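"""Synthetic study region with known ground truth.

Emulates the raw layer inventory of a regional cumulative-exposure study:
topsoil trace-metal point samples, an inventory of potentially
contaminated sites clustered along an industrial axis, fine-grid air
concentration rasters, district emission tables, water-distribution-unit
exceedance counts, a sparse road-noise (Lden) raster, a heavy-tailed
population raster, and polygon layers (districts, water units, census
blocks) that exactly tile the extent. Injected hotspots are recorded in a
:class:`SyntheticTruth` object so downstream hotspot-detection stages can
be scored against a known answer.

Defaults emulate the study conditions at roughly one tenth of the regional
area (a 60 km × 40 km domain, i.e. 40×60 one-km cells) with layer
densities matched to the regional inventory: ~800 soil sample points and
~40 contaminated sites for 2,400 km², noise values on 10% of cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from shapely.geometry import LineString, box
from shapely.ops import voronoi_diagram
from shapely.geometry import MultiPoint

from .grid import RasterField, ReferentGrid, SiteSet, ZoneMap, build_referent_grid

__all__ = [
    "RegionConfig",
    "SyntheticTruth",
    "RegionBundle",
    "SOIL_POLLUTANTS",
    "AIR_POLLUTANTS",
    "EMISSION_POLLUTANTS",
    "generate_region",
    "generate_tail_contrast_pair",
]

# marginal mean / sd (same units as the layer) for the smooth background of
# each pollutant surface; typical regional topsoil (mg/kg) and annual-mean
# air (µg/m³) levels.  sd ≤ mean/3 keeps backgrounds positive and hotspot
# exceedance guarantees valid.
SOIL_POLLUTANTS: dict[str, tuple[float, float]] = {
    "Cd": (0.40, 0.12), "Pb": (35.0, 10.0), "As": (9.0, 2.5),
}
AIR_POLLUTANTS: dict[str, tuple[float, float]] = {
    "NO2": (18.0, 5.0), "PM10": (16.0, 4.0), "O3": (50.0, 8.0),
}
# district emission totals, t/yr: lognormal parameters (median, sigma_log)
EMISSION_POLLUTANTS: dict[str, tuple[float, float]] = {
    "benzene": (2.0, 1.0), "PAH": (0.5, 1.2), "PM10": (40.0, 0.8),
}

_DIMENSIONS = ("soil", "air", "water", "noise")


@dataclass(frozen=True)
class RegionConfig:
    """Parameters of the synthetic study region."""

    extent: tuple[float, float, float, float] = (0.0, 0.0, 60_000.0, 40_000.0)
    cell_size: float = 1000.0
    n_soil_points: int = 800
    n_sites: int = 40
    n_districts: int = 30
    n_water_units: int = 40
    n_census_blocks: int = 150
    hotspots_per_dimension: int = 3
    hotspot_amplitude: float = 5.0
    background_length_scale_m: float = 5000.0
    noise_coverage_fraction: float = 0.10
    #: number of dimensions (in the order soil, air, water, noise) whose
    #: first hotspot shares a single location; 0 or 1 means no co-location.
    n_shared_hotspot_dimensions: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        xmin, ymin, xmax, ymax = self.extent
        w, h = xmax - xmin, ymax - ymin
        if w < 10 * self.cell_size or h < 10 * self.cell_size:
            raise ValueError("extent width/height must be ≥ 10 × cell_size")
        for name in ("n_soil_points", "n_sites", "n_districts", "n_water_units",
                     "n_census_blocks", "hotspots_per_dimension"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be ≥ 0")
        if not 0.0 <= self.noise_coverage_fraction <= 1.0:
            raise ValueError("noise_coverage_fraction must be in [0, 1]")
        if not 0 <= self.n_shared_hotspot_dimensions <= 4:
            raise ValueError("n_shared_hotspot_dimensions must be in 0..4")


@dataclass
class Hotspot:
    center: tuple[float, float]
    radius_m: float
    amplitude: float


@dataclass
class SyntheticTruth:
    """Injected hotspots and pre-degradation latent surfaces per dimension."""

    hotspots: dict[str, list[Hotspot]]
    latent: dict[str, RasterField]
    background_mean: dict[str, float]

    def shared_center(self) -> tuple[float, float] | None:
        """The co-located hotspot centre, if any dimension pair shares one."""
        seen: dict[tuple[float, float], int] = {}
        for hs in self.hotspots.values():
            for h in hs:
                seen[h.center] = seen.get(h.center, 0) + 1
        shared = [c for c, k in seen.items() if k >= 2]
        return shared[0] if shared else None


@dataclass
class RegionBundle:
    """All raw layers of one synthetic region."""

    config: RegionConfig
    grid: ReferentGrid
    soil_points: dict[str, np.ndarray]          # "xy" -> (n,2); pollutant -> (n,)
    sites: SiteSet
    air_rasters: dict[str, RasterField]         # 500 m resolution
    emissions: dict[str, np.ndarray]            # pollutant -> per-district totals
    water_exceedances: np.ndarray               # (n_units, n_years) counts
    noise: RasterField                          # referent resolution, sparse
    population: RasterField                     # 200 m resolution
    districts: ZoneMap
    water_units: ZoneMap
    census_blocks: ZoneMap
    truth: SyntheticTruth | None

    N_WATER_YEARS: int = 4


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def _fine_grid(extent, cell: float) -> ReferentGrid:
    return build_referent_grid(extent, cell)


def _smooth_background(rng: np.random.Generator, grid: ReferentGrid,
                       mean: float, sd: float, length_scale_m: float) -> np.ndarray:
    """Smoothed white noise with the requested marginal mean/sd.

    A Gaussian blur of seeded noise gives cheap, seedable spatial
    autocorrelation with correlation length ≈ ``length_scale_m``; values
    are clipped at 5% of the mean so concentrations stay positive.
    """
    sigma_cells = max(length_scale_m / grid.cell_size, 0.5)
    white = rng.standard_normal(grid.shape)
    sm = gaussian_filter(white, sigma=sigma_cells, mode="reflect")
    s = sm.std()
    if s < 1e-12:
        return np.full(grid.shape, mean)
    return np.clip(mean + sd * sm / s, 0.05 * mean, None)


def _hotspot_bumps(grid: ReferentGrid, hotspots: list[Hotspot], mean: float) -> np.ndarray:
    """Additive Gaussian bumps scaled by the background mean."""
    X, Y = grid.cell_centers()
    out = np.zeros(grid.shape)
    for h in hotspots:
        d2 = (X - h.center[0]) ** 2 + (Y - h.center[1]) ** 2
        out += mean * h.amplitude * np.exp(-d2 / (2.0 * h.radius_m ** 2))
    return out


def _draw_hotspots(rng: np.random.Generator, cfg: RegionConfig,
                   shared: tuple[float, float] | None, use_shared: bool) -> list[Hotspot]:
    xmin, ymin, xmax, ymax = cfg.extent
    w, h = xmax - xmin, ymax - ymin
    out = []
    for k in range(cfg.hotspots_per_dimension):
        if k == 0 and use_shared and shared is not None:
            cx, cy = shared
        else:
            cx = xmin + w * rng.uniform(0.1, 0.9)
            cy = ymin + h * rng.uniform(0.1, 0.9)
        # amplitude drawn strictly above the configured floor and radii kept
        # wide relative to the cell size so the bump still exceeds
        # mean × hotspot_amplitude after discretization to cell centres
        out.append(Hotspot(
            center=(cx, cy),
            radius_m=rng.uniform(2500.0, 4500.0),
            amplitude=cfg.hotspot_amplitude * rng.uniform(1.2, 1.6),
        ))
    return out


def _poisson_disk(rng: np.random.Generator, extent, n: int, dmin: float,
                  max_tries: int = 20000) -> np.ndarray:
    """n random points with pairwise separation ≥ dmin (rejection sampling)."""
    xmin, ymin, xmax, ymax = extent
    pts: list[tuple[float, float]] = []
    tries = 0
    while len(pts) < n and tries < max_tries:
        tries += 1
        p = (rng.uniform(xmin, xmax), rng.uniform(ymin, ymax))
        if all((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 >= dmin * dmin
               for q in pts):
            pts.append(p)
    if len(pts) < n:
        raise ValueError(f"cannot place {n} zone seeds with {dmin} m separation")
    return np.asarray(pts)


def _voronoi_partition(rng: np.random.Generator, extent, n_zones: int,
                       prefix: str, dmin: float) -> ZoneMap:
    """Random Voronoi tessellation clipped to the extent (exact tiling).

    Seed points keep a minimum separation so no zone degenerates to a
    sliver: with dmin ≥ 2.2 × cell size, each zone contains a disc of
    radius dmin/2 around its seed and is guaranteed to be the
    largest-overlap winner in at least the referent cell holding the seed.
    """
    xmin, ymin, xmax, ymax = extent
    domain = box(*extent)
    if n_zones == 1:
        return ZoneMap(ids=[f"{prefix}0"], polygons=[domain], attributes=[0.0],
                       name=prefix)
    pts = MultiPoint([tuple(p) for p in _poisson_disk(rng, extent, n_zones, dmin)])
    cells = voronoi_diagram(pts, envelope=domain)
    polys = [c.intersection(domain) for c in cells.geoms]
    polys = [p for p in polys if p.area > 0]
    # voronoi_diagram returns regions in arbitrary-but-deterministic order;
    # sort by centroid for reproducible ids
    polys.sort(key=lambda p: (round(p.centroid.x, 6), round(p.centroid.y, 6)))
    return ZoneMap(ids=[f"{prefix}{i}" for i in range(len(polys))],
                   polygons=polys, attributes=np.zeros(len(polys)), name=prefix)


def _zone_containing(zones: ZoneMap, xy: tuple[float, float]) -> int:
    from shapely.geometry import Point
    p = Point(*xy)
    for k, poly in enumerate(zones.polygons):
        if poly.covers(p):
            return k
    # numerically on an edge: nearest zone
    return int(np.argmin([poly.distance(p) for poly in zones.polygons]))


def _corridor_noise(rng: np.random.Generator, cfg: RegionConfig,
                    grid: ReferentGrid, hotspots: list[Hotspot]) -> RasterField:
    """Sparse Lden raster along random road corridors.

    Values 55–75 dB(A) on exactly round(f·n) cells nearest to the
    polylines (corridor pattern); nodata elsewhere. If the noise dimension
    carries hotspots, one corridor is routed through each hotspot centre.
    """
    xmin, ymin, xmax, ymax = cfg.extent
    n_cells = grid.n_cells
    k = int(round(cfg.noise_coverage_fraction * n_cells))
    values = np.zeros(grid.shape)
    mask = np.zeros(grid.shape, dtype=bool)
    if k == 0:
        return RasterField(grid=grid, values=values, mask=mask,
                           units="dB(A)", name="lden")
    lines = []
    n_lines = 3
    for li in range(n_lines):
        # random chord across the domain
        a = (xmin + (xmax - xmin) * rng.random(), ymin)
        b = (xmin + (xmax - xmin) * rng.random(), ymax)
        if rng.random() < 0.5:
            a = (xmin, ymin + (ymax - ymin) * rng.random())
            b = (xmax, ymin + (ymax - ymin) * rng.random())
        if li < len(hotspots):
            mid = hotspots[li].center
            lines.append(LineString([a, mid, b]))
        else:
            lines.append(LineString([a, b]))
    X, Y = grid.cell_centers()
    pts = np.column_stack([X.ravel(), Y.ravel()])
    import shapely
    geoms = shapely.points(pts[:, 0], pts[:, 1])
    dist = np.min(np.stack([shapely.distance(geoms, ln) for ln in lines]), axis=0)
    order = np.argsort(dist, kind="stable")
    sel = order[:k]
    flat_mask = np.zeros(n_cells, dtype=bool)
    flat_mask[sel] = True
    lden = 55.0 + 20.0 * np.exp(-dist / 1500.0) + rng.normal(0.0, 1.0, n_cells)
    lden = np.clip(lden, 55.0, 75.0)
    values = np.where(flat_mask, lden, 0.0).reshape(grid.shape)
    mask = flat_mask.reshape(grid.shape)
    return RasterField(grid=grid, values=values, mask=mask,
                       units="dB(A)", name="lden")


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------

def generate_region(config: RegionConfig) -> RegionBundle:
    """Generate all raw layers of a synthetic region plus ground truth.

    Identical configs (including seed) yield bit-identical bundles.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    grid = build_referent_grid(cfg.extent, cfg.cell_size)
    if cfg.n_soil_points > 0 and cfg.n_soil_points > 100 * grid.n_cells:
        raise ValueError("n_soil_points unreasonably exceeds the cell count")

    xmin, ymin, xmax, ymax = cfg.extent

    # ---- hotspot truth -----------------------------------------------------
    shared = None
    if cfg.n_shared_hotspot_dimensions >= 2 and cfg.hotspots_per_dimension > 0:
        shared = (xmin + (xmax - xmin) * rng.uniform(0.25, 0.75),
                  ymin + (ymax - ymin) * rng.uniform(0.25, 0.75))
    shared_dims = set(_DIMENSIONS[:cfg.n_shared_hotspot_dimensions]) if shared else set()
    hotspots = {dim: _draw_hotspots(rng, cfg, shared, dim in shared_dims)
                for dim in _DIMENSIONS}

    # ---- soil points -------------------------------------------------------
    soil_fine = _fine_grid(cfg.extent, 500.0)
    soil_surfaces = {}
    for pol, (mean, sd) in SOIL_POLLUTANTS.items():
        bg = _smooth_background(rng, soil_fine, mean, sd, cfg.background_length_scale_m)
        soil_surfaces[pol] = bg + _hotspot_bumps(soil_fine, hotspots["soil"], mean)
    pts_xy = np.column_stack([rng.uniform(xmin, xmax, cfg.n_soil_points),
                              rng.uniform(ymin, ymax, cfg.n_soil_points)])
    soil_points: dict[str, np.ndarray] = {"xy": pts_xy}
    if cfg.n_soil_points:
        pi, pj = soil_fine.cell_index(pts_xy[:, 0], pts_xy[:, 1])
        for pol in SOIL_POLLUTANTS:
            noise = np.exp(rng.normal(0.0, 0.25, cfg.n_soil_points))
            soil_points[pol] = soil_surfaces[pol][pi, pj] * noise
    else:
        for pol in SOIL_POLLUTANTS:
            soil_points[pol] = np.empty(0)

    # ---- contaminated sites along a linear "furrow" axis -------------------
    cx, cy = (xmin + xmax) / 2.0, (ymin + ymax) / 2.0
    theta = rng.uniform(0.0, np.pi)
    half = 0.45 * min(xmax - xmin, ymax - ymin)
    t = rng.uniform(-half, half, cfg.n_sites)
    perp = rng.normal(0.0, 2000.0, cfg.n_sites)
    sx = cx + t * np.cos(theta) - perp * np.sin(theta)
    sy = cy + t * np.sin(theta) + perp * np.cos(theta)
    sites = SiteSet(np.column_stack([np.clip(sx, xmin, xmax),
                                     np.clip(sy, ymin, ymax)])
                    if cfg.n_sites else np.empty((0, 2)))

    # ---- air concentration rasters (finer than referent) -------------------
    air_fine = _fine_grid(cfg.extent, 500.0)
    air_rasters = {}
    air_latent_sum = np.zeros(air_fine.shape)
    for pol, (mean, sd) in AIR_POLLUTANTS.items():
        surf = (_smooth_background(rng, air_fine, mean, sd, cfg.background_length_scale_m)
                + _hotspot_bumps(air_fine, hotspots["air"], mean))
        air_latent_sum += surf / mean
        air_rasters[pol] = RasterField(grid=air_fine, values=surf,
                                       units="ug/m3", name=f"air_{pol}")

    # ---- polygon layers ----------------------------------------------------
    area = (xmax - xmin) * (ymax - ymin)

    def _dmin(n: int) -> float:
        # cap the separation by the packing limit for large zone counts
        return min(2.2 * cfg.cell_size, 0.6 * math.sqrt(area / max(n, 1)))

    districts = _voronoi_partition(rng, cfg.extent, max(cfg.n_districts, 1),
                                   "D", _dmin(cfg.n_districts))
    water_units = _voronoi_partition(rng, cfg.extent, max(cfg.n_water_units, 1),
                                     "W", _dmin(cfg.n_water_units))
    census_blocks = _voronoi_partition(rng, cfg.extent,
                                       max(cfg.n_census_blocks, 1),
                                       "B", _dmin(cfg.n_census_blocks))

    # ---- district emissions ------------------------------------------------
    nd = len(districts)
    emissions = {}
    air_hot_districts = {_zone_containing(districts, h.center)
                         for h in hotspots["air"]}
    for pol, (median, slog) in EMISSION_POLLUTANTS.items():
        tot = median * np.exp(rng.normal(0.0, slog, nd))
        for k in air_hot_districts:
            tot[k] *= cfg.hotspot_amplitude
        emissions[pol] = tot

    # ---- water exceedance counts (zero-inflated Poisson) -------------------
    nw = len(water_units)
    n_years = RegionBundle.N_WATER_YEARS
    active = rng.random(nw) < 0.25
    lam = np.where(active, 1.2, 0.0)
    water_hot_units = {_zone_containing(water_units, h.center)
                       for h in hotspots["water"]}
    for k in water_hot_units:
        lam[k] = max(cfg.hotspot_amplitude, 2.0)
    water_exceedances = rng.poisson(np.broadcast_to(lam[:, None], (nw, n_years)))

    # ---- noise corridors ---------------------------------------------------
    noise = _corridor_noise(rng, cfg, grid, hotspots["noise"])

    # ---- population (heavy-tailed, fine grid) ------------------------------
    pop_fine = _fine_grid(cfg.extent, 200.0)
    smooth = _smooth_background(rng, pop_fine, 0.0, 1.0, cfg.background_length_scale_m)
    pop = np.exp(np.log(3.0) + 1.2 * smooth + 0.4 * rng.standard_normal(pop_fine.shape))
    population = RasterField(grid=pop_fine, values=pop, units="persons",
                             name="population")

    # ---- latent truth surfaces at referent resolution ----------------------
    latent = {}
    bg_mean = {}
    X, Y = grid.cell_centers()
    for dim in _DIMENSIONS:
        if dim == "soil":
            mean = 1.0  # unitless: mean-normalized pollutant average
            base = np.zeros(grid.shape)
            for pol, (m, s) in SOIL_POLLUTANTS.items():
                coarse = _aggregate_mean(soil_surfaces[pol], soil_fine, grid)
                base += coarse / m
            base /= len(SOIL_POLLUTANTS)
        elif dim == "air":
            mean = 1.0
            base = _aggregate_mean(air_latent_sum, air_fine, grid) / len(AIR_POLLUTANTS)
        elif dim == "water":
            mean = 1.0
            score = water_exceedances.sum(axis=1) / n_years
            from .grid import rasterize_zones
            base = rasterize_zones(water_units.with_attributes(score), grid).values
        else:  # noise
            mean = 55.0
            base = np.where(noise.mask, noise.values, 0.0)
        latent[dim] = RasterField(grid=grid, values=base, name=f"latent_{dim}")
        bg_mean[dim] = mean

    truth = SyntheticTruth(hotspots=hotspots, latent=latent, background_mean=bg_mean)
    return RegionBundle(
        config=cfg, grid=grid, soil_points=soil_points, sites=sites,
        air_rasters=air_rasters, emissions=emissions,
        water_exceedances=water_exceedances, noise=noise, population=population,
        districts=districts, water_units=water_units, census_blocks=census_blocks,
        truth=truth,
    )


def _aggregate_mean(fine_values: np.ndarray, fine: ReferentGrid,
                    coarse: ReferentGrid) -> np.ndarray:
    from .grid import aggregate_surface_ratio
    f = RasterField(grid=fine, values=fine_values)
    return aggregate_surface_ratio(f, coarse, kind="intensive").values


# ---------------------------------------------------------------------------
# tail-contrast pair
# ---------------------------------------------------------------------------

def generate_tail_contrast_pair(n_cells: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """One heavy-tailed and one light-tailed exposure vector of equal length.

    Vector A is lognormal with sigma_log = 1.5 (heavy right tail, like an
    emission or topsoil-HQ field dominated by a few industrial cells);
    vector B is a Beta(2, 2) scaled to [0, 2] (bounded, light-tailed, like
    a regional background concentration ratio). Used to reproduce the
    transform-sensitivity effect: rank-percentile scores smooth A's
    extremes while normal scores preserve their separation.
    """
    if n_cells < 100:
        raise ValueError("n_cells must be ≥ 100")
    rng = np.random.default_rng(seed)
    heavy = rng.lognormal(mean=0.0, sigma=1.5, size=n_cells)
    light = 2.0 * rng.beta(2.0, 2.0, size=n_cells)
    return heavy, light
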