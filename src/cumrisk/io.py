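"""Readers and writers for the package's plain-text formats.

Rasters travel as CSV(x, y, value) listing valid cells only, with a JSON
sidecar (``<file>.meta.json``) that carries the exact grid geometry,
units, name and provenance, so a write→read round trip reproduces values,
mask and geometry. Vectors travel as GeoJSON (polygons, points) or CSV
(points). CSV dialect is fixed: comma separator, "." decimal, UTF-8,
mandatory header row.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import mapping, shape

from .grid import RasterField, ReferentGrid, SiteSet, ZoneMap
from .standardize import DEFAULT_BACKGROUND_RULES, METHODS
from .synthetic import RegionConfig

__all__ = [
    "PipelineConfig",
    "read_raster",
    "write_raster",
    "read_vector",
    "write_vector",
    "read_toxicity_csv",
    "read_exposure_factors_csv",
    "file_sha256",
]

_FLOAT_FMT = "%.17g"


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PipelineConfig:
    """Everything a full run needs; defaults follow the framework's stated
    parameters (1 km referent cells, 300 m site buffers, 90th-percentile
    contribution threshold)."""

    region: RegionConfig = dataclasses.field(default_factory=RegionConfig)
    buffer_radius_m: float = 300.0
    background_rules: dict = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_BACKGROUND_RULES))
    methods: tuple = ("normal_score", "percentile_rank")
    contribution_percentile: float = 0.9
    slope_window: int = 51
    interp_method: str = "idw"
    interp_params: dict = dataclasses.field(default_factory=dict)
    correlate_on: str = "standardized"   # or "raw"
    toxicity_csv: str | None = None
    exposure_factors_csv: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.methods = tuple(self.methods)
        for m in self.methods:
            if m not in METHODS:
                raise ValueError(f"unknown standardization method {m!r}; "
                                 f"choose from {METHODS}")
        if not 0 < self.contribution_percentile < 1:
            raise ValueError("contribution_percentile must be in (0, 1)")
        if self.buffer_radius_m <= 0:
            raise ValueError("buffer_radius_m must be > 0")
        if self.interp_method not in ("idw", "ordinary_kriging"):
            raise ValueError(f"unknown interp_method {self.interp_method!r}")
        if self.correlate_on not in ("standardized", "raw"):
            raise ValueError("correlate_on must be 'standardized' or 'raw'")
        for p in (self.toxicity_csv, self.exposure_factors_csv):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured file not found: {p}")
        # region seed follows the pipeline seed unless set apart explicitly
        if self.region.seed != self.seed:
            self.region = dataclasses.replace(self.region, seed=self.seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["region"]["extent"] = list(self.region.extent)
        d["methods"] = list(self.methods)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        region = d.pop("region", {})
        if isinstance(region, dict):
            if "extent" in region:
                region["extent"] = tuple(region["extent"])
            region = RegionConfig(**region)
        return cls(region=region, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# raster I/O
# ---------------------------------------------------------------------------

def _meta_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def write_raster(field: RasterField, path: str | Path,
                 provenance: dict | None = None) -> None:
    """CSV of valid cells (x, y, value) plus a geometry/provenance sidecar."""
    path = Path(path)
    X, Y = field.grid.cell_centers()
    m = field.mask
    df = pd.DataFrame({"x": X[m], "y": Y[m], "value": field.values[m]})
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    g = field.grid
    meta = {
        "format": "cumrisk-raster-csv",
        "grid": {"x0": g.x0, "y0": g.y0, "cell_size": g.cell_size,
                 "n_rows": g.n_rows, "n_cols": g.n_cols},
        "units": field.units,
        "name": field.name,
        "n_valid": int(m.sum()),
        "provenance": provenance or {},
    }
    with open(_meta_path(path), "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)


def read_raster(path: str | Path) -> RasterField:
    """Read a raster CSV; uses the sidecar when present, otherwise infers
    the grid from the cell-centre coordinates."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"raster file not found: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    if not {"x", "y", "value"}.issubset(df.columns):
        raise ValueError(f"malformed raster CSV {path}: needs columns x,y,value")
    mp = _meta_path(path)
    if mp.exists():
        with open(mp, encoding="utf-8") as fh:
            meta = json.load(fh)
        g = ReferentGrid(**meta["grid"])
        units, name = meta.get("units", ""), meta.get("name", "")
    else:
        xs = np.sort(df["x"].unique())
        ys = np.sort(df["y"].unique())
        dx = np.diff(xs)
        dy = np.diff(ys)
        steps = np.concatenate([dx[dx > 0], dy[dy > 0]])
        if steps.size == 0:
            raise ValueError(f"cannot infer grid geometry from {path}")
        s = float(steps.min())
        g = ReferentGrid(
            x0=float(xs.min() - s / 2), y0=float(ys.max() + s / 2), cell_size=s,
            n_rows=int(round((ys.max() - ys.min()) / s)) + 1,
            n_cols=int(round((xs.max() - xs.min()) / s)) + 1)
        units, name = "", path.stem
    values = np.zeros(g.shape)
    mask = np.zeros(g.shape, dtype=bool)
    i, j = g.cell_index(df["x"].to_numpy(), df["y"].to_numpy())
    values[i, j] = df["value"].to_numpy()
    mask[i, j] = True
    return RasterField(grid=g, values=values, mask=mask, units=units, name=name)


# ---------------------------------------------------------------------------
# vector I/O
# ---------------------------------------------------------------------------

def write_vector(obj: ZoneMap | SiteSet, path: str | Path,
                 extra_properties: dict | None = None) -> None:
    """GeoJSON FeatureCollection; ZoneMap polygons carry id + value."""
    path = Path(path)
    features = []
    if isinstance(obj, ZoneMap):
        for zid, poly, attr in zip(obj.ids, obj.polygons, obj.attributes):
            props = {"id": zid, "value": float(attr)}
            if extra_properties:
                props.update({k: v[zid] for k, v in extra_properties.items()
                              if zid in v})
            features.append({"type": "Feature", "geometry": mapping(poly),
                             "properties": props})
    elif isinstance(obj, SiteSet):
        for k in range(len(obj)):
            features.append({
                "type": "Feature",
                "geometry": {"type": "Point",
                             "coordinates": [obj.xy[k, 0], obj.xy[k, 1]]},
                "properties": {"id": k}})
    else:
        raise TypeError(f"cannot write {type(obj).__name__} as vector")
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_vector(path: str | Path) -> ZoneMap | SiteSet:
    """Read GeoJSON (polygons → ZoneMap, points → SiteSet) or CSV points."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"vector file not found: {path}")
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path, float_precision="round_trip")
        if not {"x", "y"}.issubset(df.columns):
            raise ValueError(f"point CSV {path} needs columns x,y")
        return SiteSet(df[["x", "y"]].to_numpy(dtype=float))
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    feats = data.get("features", [])
    if not feats:
        raise ValueError(f"empty GeoJSON {path}")
    gtypes = {f["geometry"]["type"] for f in feats}
    if gtypes <= {"Point"}:
        xy = np.array([f["geometry"]["coordinates"] for f in feats], dtype=float)
        return SiteSet(xy)
    if gtypes <= {"Polygon", "MultiPolygon"}:
        ids, polys, attrs, bad = [], [], [], []
        for k, f in enumerate(feats):
            poly = shape(f["geometry"])
            fid = f.get("properties", {}).get("id", k)
            if not poly.is_valid:
                bad.append(fid)
            ids.append(fid)
            polys.append(poly)
            attrs.append(float(f.get("properties", {}).get("value", 0.0)))
        if bad:
            raise ValueError(f"invalid polygon geometry for feature ids {bad}")
        return ZoneMap(ids=ids, polygons=polys, attributes=np.asarray(attrs),
                       name=path.stem)
    raise ValueError(f"unsupported geometry types {sorted(gtypes)} in {path}")


# ---------------------------------------------------------------------------
# toxicity / exposure-factor tables
# ---------------------------------------------------------------------------

def read_toxicity_csv(path: str | Path):
    """Columns: pollutant, rfd, air_standard, water_threshold,
    cancer_weight, noncancer_weight; blanks allowed per pollutant."""
    from .transforms import ToxicityTable

    df = pd.read_csv(path, float_precision="round_trip")
    if "pollutant" not in df.columns:
        raise ValueError(f"toxicity CSV {path} needs a 'pollutant' column")
    kw = {}
    for col in ("rfd", "air_standard", "water_threshold",
                "cancer_weight", "noncancer_weight"):
        if col in df.columns:
            sub = df[["pollutant", col]].dropna()
            kw[col] = dict(zip(sub["pollutant"], sub[col].astype(float)))
    return ToxicityTable(**kw)


def read_exposure_factors_csv(path: str | Path):
    """Columns: age_class, soil_ingestion_kg_day, exposure_frequency,
    body_weight_kg."""
    from .transforms import AgeClass, ExposureFactors

    df = pd.read_csv(path, float_precision="round_trip")
    needed = {"age_class", "soil_ingestion_kg_day", "exposure_frequency",
              "body_weight_kg"}
    if not needed.issubset(df.columns):
        raise ValueError(f"exposure-factor CSV {path} needs columns {sorted(needed)}")
    classes = [AgeClass(r.age_class, float(r.soil_ingestion_kg_day),
                        float(r.exposure_frequency), float(r.body_weight_kg))
               for r in df.itertuples()]
    return ExposureFactors(age_classes=classes)


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
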