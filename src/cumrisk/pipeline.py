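"""Pipeline orchestration: simulate → spatialize → transform → standardize
→ compose → diagnose.

Stage functions are pure (layers in, layers out) so they can run in
memory; :func:`run_pipeline` chains them, writes every intermediate with a
provenance sidecar, and logs per-stage cell counts and timing. Identical
config + seed ⇒ byte-identical outputs (timing lives only in the log).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import diagnostics as diag
from .grid import (RasterField, aggregate_surface_ratio, buffer_partition,
                   build_referent_grid, interpolate_points, rasterize_zones)
from .io import (PipelineConfig, file_sha256, read_exposure_factors_csv,
                 read_toxicity_csv, write_raster, write_vector)
from .standardize import StandardizedField, check_equity, standardize_field
from .synthetic import RegionBundle, generate_region
from .transforms import (DEFAULT_EXPOSURE_FACTORS, DEFAULT_TOXICITY,
                         SubIndicator, air_concentration_indicator,
                         combine_equity, emission_score, noise_indicator,
                         soil_concentration_indicator, water_exceedance_score)

__all__ = [
    "spatialize_bundle",
    "transform_layers",
    "standardize_components",
    "diagnose_method",
    "run_indicator_stages",
    "run_pipeline",
    "PipelineError",
]

logger = logging.getLogger("cumrisk")

DIMENSIONS = ("soil", "air", "water", "noise")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and offending layer."""

    def __init__(self, stage: str, layer: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on layer {layer!r}: {cause}")
        self.stage = stage
        self.layer = layer
        self.__cause__ = cause


def _stage(stage: str, layer: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001 - rewrap with stage context
        raise PipelineError(stage, layer, exc) from exc


# ---------------------------------------------------------------------------
# stage 2: spatialize raw layers onto the referent grid
# ---------------------------------------------------------------------------

def spatialize_bundle(bundle: RegionBundle, cfg: PipelineConfig
                      ) -> dict[str, RasterField]:
    """Discretize every raw layer onto the referent grid."""
    grid = bundle.grid
    out: dict[str, RasterField] = {}

    xy = bundle.soil_points["xy"]
    for pol, vals in bundle.soil_points.items():
        if pol == "xy":
            continue
        f = _stage("spatialize", f"soil_{pol}", interpolate_points,
                   xy, vals, grid, method=cfg.interp_method,
                   params=cfg.interp_params)
        out[f"soil_conc_{pol}"] = f.copy_with(f.values, name=f"soil_conc_{pol}",
                                              units="mg/kg")

    out["proximity"] = _stage("spatialize", "sites", buffer_partition,
                              bundle.sites, cfg.buffer_radius_m, grid)

    for pol, raster in bundle.air_rasters.items():
        out[f"air_conc_{pol}"] = _stage("spatialize", f"air_{pol}",
                                        aggregate_surface_ratio, raster, grid,
                                        "intensive")

    # district totals are spread as areal densities (t/yr/km²) so the
    # rasterized value is independent of district size
    areas_km2 = np.array([p.area for p in bundle.districts.polygons]) / 1e6
    for pol, totals in bundle.emissions.items():
        zm = bundle.districts.with_attributes(totals / areas_km2,
                                              name=f"emission_{pol}")
        out[f"emission_{pol}"] = _stage("spatialize", f"emission_{pol}",
                                        rasterize_zones, zm, grid)

    score = _stage("transform", "water", water_exceedance_score,
                   bundle.water_exceedances, bundle.N_WATER_YEARS)
    zm = bundle.water_units.with_attributes(score, name="water_score")
    out["water_score"] = _stage("spatialize", "water", rasterize_zones, zm, grid)

    out["noise"] = _stage("spatialize", "noise", aggregate_surface_ratio,
                          bundle.noise, grid, "intensive")
    out["population"] = _stage("spatialize", "population",
                               aggregate_surface_ratio, bundle.population,
                               grid, "extensive")
    return out


# ---------------------------------------------------------------------------
# stage 3: exposure transformation into sub-indicator components
# ---------------------------------------------------------------------------

def transform_layers(spatial: dict[str, RasterField], cfg: PipelineConfig,
                     tox=None, factors=None) -> dict[str, SubIndicator]:
    """Six sub-indicator components from the discretized layers."""
    if tox is None:
        tox = (read_toxicity_csv(cfg.toxicity_csv)
               if cfg.toxicity_csv else DEFAULT_TOXICITY)
    if factors is None:
        factors = (read_exposure_factors_csv(cfg.exposure_factors_csv)
                   if cfg.exposure_factors_csv else DEFAULT_EXPOSURE_FACTORS)

    conc = {k.removeprefix("soil_conc_"): v for k, v in spatial.items()
            if k.startswith("soil_conc_")}
    air = {k.removeprefix("air_conc_"): v for k, v in spatial.items()
           if k.startswith("air_conc_")}
    emis = {k.removeprefix("emission_"): v for k, v in spatial.items()
            if k.startswith("emission_")}

    out: dict[str, SubIndicator] = {}
    out["soil_hq"] = _stage("transform", "soil_hq", soil_concentration_indicator,
                            conc, factors, tox)
    out["proximity"] = SubIndicator(field=spatial["proximity"],
                                    dimension="proximity")
    out["air_conc"] = _stage("transform", "air_conc", air_concentration_indicator,
                             air, tox)
    out["emission"] = _stage("transform", "emission", emission_score, emis, tox)
    water = spatial["water_score"]
    out["water"] = SubIndicator(
        field=water.copy_with(np.where(water.mask, water.values, 0.0),
                              name="water", mask=water.mask),
        dimension="water")
    out["noise"] = _stage("transform", "noise", noise_indicator, spatial["noise"])
    return out


# ---------------------------------------------------------------------------
# stage 4: standardization and equity combination
# ---------------------------------------------------------------------------

def standardize_components(components: dict[str, SubIndicator], method: str,
                           cfg: PipelineConfig
                           ) -> tuple[dict[str, StandardizedField],
                                      dict[str, RasterField]]:
    """Four standardized dimension fields plus the raw combined fields.

    Air and soil are first combined from their two components under the
    equity constraint (each component standardized, then summed, range
    [0, 2]) and the combined field is re-standardized so all four
    dimensions enter the composite with equal mean and range.
    """
    rules = cfg.background_rules
    combined_air = _stage("standardize", "air", combine_equity,
                          components["air_conc"], components["emission"],
                          method, rules)
    combined_soil = _stage("standardize", "soil", combine_equity,
                           components["proximity"], components["soil_hq"],
                           method, rules)
    raw = {
        "soil": combined_soil,
        "air": combined_air,
        "water": components["water"].field,
        "noise": components["noise"].field,
    }
    std = {dim: _stage("standardize", dim, standardize_field,
                       raw[dim], dim, method, rules)
           for dim in DIMENSIONS}
    return std, raw


# ---------------------------------------------------------------------------
# stages 5–6: composite + diagnostics
# ---------------------------------------------------------------------------

def diagnose_method(std: dict[str, StandardizedField],
                    raw: dict[str, RasterField],
                    composite: diag.CompositeField,
                    cfg: PipelineConfig) -> dict:
    """All per-method diagnostics as plain tables."""
    fields = [std[d] for d in DIMENSIONS]
    corr_inputs = fields if cfg.correlate_on == "standardized" else \
        [raw[d] for d in DIMENSIONS]
    corr = diag.correlation_matrix(corr_inputs, names=list(DIMENSIONS))
    contrib = diag.contribution_above_percentile(
        composite, q=cfg.contribution_percentile)
    equity = check_equity(fields)

    hetero_rows = []
    for d in DIMENSIONS:
        if std[d].n_background > 0:
            hetero_rows.append({
                "dimension": d,
                "ratio": diag.heteroscedasticity_ratio(std[d]),
                "n_background": std[d].n_background,
            })
    hetero = pd.DataFrame(hetero_rows)

    slope_rows = []
    for d in DIMENSIONS:
        rv = raw[d].values.ravel()
        sv = std[d].field.values.ravel()
        order = np.argsort(rv, kind="stable")
        w = min(cfg.slope_window, rv.size if rv.size % 2 else rv.size - 1)
        slopes = diag.transform_slope(rv[order], sv[order], w)
        top = slice(int(0.9 * len(slopes)), None)
        with np.errstate(invalid="ignore"):
            slope_rows.append({
                "dimension": d,
                "mean_slope": float(np.nanmean(slopes)),
                "top_decile_mean_slope": float(np.nanmean(slopes[top])),
            })
    slopes_df = pd.DataFrame(slope_rows)

    gof = {d: diag.fit_rank_distribution(std[d].field.values.ravel())
           for d in DIMENSIONS}
    return {"correlations": corr, "contributions": contrib, "equity": equity,
            "heteroscedasticity": hetero, "slopes": slopes_df, "gof": gof}


@dataclasses.dataclass
class MethodResult:
    standardized: dict[str, StandardizedField]
    raw_combined: dict[str, RasterField]
    composite: diag.CompositeField
    blocks: pd.DataFrame
    diagnostics: dict


@dataclasses.dataclass
class RunResult:
    bundle: RegionBundle
    spatial: dict[str, RasterField]
    components: dict[str, SubIndicator]
    by_method: dict[str, MethodResult]


def run_indicator_stages(bundle: RegionBundle, cfg: PipelineConfig) -> RunResult:
    """Run every stage after simulation, in memory."""
    spatial = spatialize_bundle(bundle, cfg)
    components = transform_layers(spatial, cfg)
    by_method = {}
    for method in cfg.methods:
        std, raw = standardize_components(components, method, cfg)
        composite = _stage("compose", method, diag.composite_indicator,
                           [std[d] for d in DIMENSIONS])
        blocks = _stage("compose", "census_blocks",
                        diag.population_weighted_aggregate, composite,
                        spatial["population"], bundle.census_blocks)
        dd = _stage("diagnose", method, diagnose_method, std, raw, composite, cfg)
        by_method[method] = MethodResult(standardized=std, raw_combined=raw,
                                         composite=composite, blocks=blocks,
                                         diagnostics=dd)
    return RunResult(bundle=bundle, spatial=spatial, components=components,
                     by_method=by_method)


# ---------------------------------------------------------------------------
# file-backed full run
# ---------------------------------------------------------------------------

def _write_sidecar(path: Path, stage: str, cfg: PipelineConfig,
                   inputs: dict[str, str]) -> None:
    meta = {"stage": stage, "seed": cfg.seed,
            "parameters": cfg.to_dict(), "input_hashes": inputs}
    with open(path.with_name(path.name + ".provenance.json"), "w",
              encoding="utf-8") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)


def _write_df(df: pd.DataFrame, path: Path, stage: str, cfg: PipelineConfig,
              inputs: dict[str, str], index: bool = False) -> None:
    df.to_csv(path, index=index, float_format="%.12g")
    _write_sidecar(path, stage, cfg, inputs)


def write_bundle(bundle: RegionBundle, raw_dir: Path, cfg: PipelineConfig) -> None:
    """Write every raw layer of a simulated region."""
    raw_dir.mkdir(parents=True, exist_ok=True)
    sp = bundle.soil_points
    pd.DataFrame({"x": sp["xy"][:, 0], "y": sp["xy"][:, 1],
                  **{p: v for p, v in sp.items() if p != "xy"}}
                 ).to_csv(raw_dir / "soil_points.csv", index=False,
                          float_format="%.17g")
    pd.DataFrame({"x": bundle.sites.xy[:, 0], "y": bundle.sites.xy[:, 1]}
                 ).to_csv(raw_dir / "sites.csv", index=False,
                          float_format="%.17g")
    for pol, raster in bundle.air_rasters.items():
        write_raster(raster, raw_dir / f"air_{pol}.csv")
    pd.DataFrame({"district_id": bundle.districts.ids,
                  **bundle.emissions}).to_csv(
        raw_dir / "emissions.csv", index=False, float_format="%.17g")
    we = pd.DataFrame(bundle.water_exceedances,
                      columns=[f"year{i+1}" for i in
                               range(bundle.water_exceedances.shape[1])])
    we.insert(0, "unit_id", bundle.water_units.ids)
    we.to_csv(raw_dir / "water_exceedances.csv", index=False)
    write_raster(bundle.noise, raw_dir / "noise.csv")
    write_raster(bundle.population, raw_dir / "population.csv")
    write_vector(bundle.districts, raw_dir / "districts.geojson")
    write_vector(bundle.water_units, raw_dir / "water_units.geojson")
    write_vector(bundle.census_blocks, raw_dir / "census_blocks.geojson")
    truth = {
        "background_mean": bundle.truth.background_mean,
        "hotspots": {d: [dataclasses.asdict(h) for h in hs]
                     for d, hs in bundle.truth.hotspots.items()},
    }
    with open(raw_dir / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    for dim, latent in bundle.truth.latent.items():
        write_raster(latent, raw_dir / f"latent_{dim}.csv")
    for p in sorted(raw_dir.glob("*.csv")) + sorted(raw_dir.glob("*.geojson")):
        if not p.name.endswith(".meta.json"):
            _write_sidecar(p, "simulate", cfg, {})


def load_bundle(run_dir: str | Path) -> tuple[RegionBundle, PipelineConfig]:
    """Reload a simulated region (or user-substituted layers) from disk.

    Expects the layout written by :func:`write_bundle` under
    ``run_dir/raw``; ground truth is loaded when present, else None.
    """
    from .io import read_raster, read_vector
    from .synthetic import Hotspot, SyntheticTruth

    run_dir = Path(run_dir)
    raw = run_dir / "raw"
    if not raw.is_dir():
        raise FileNotFoundError(f"no raw/ layer directory under {run_dir}")
    cfg = (PipelineConfig.from_yaml(run_dir / "config.yaml")
           if (run_dir / "config.yaml").exists() else PipelineConfig())

    sp = pd.read_csv(raw / "soil_points.csv", float_precision="round_trip")
    soil_points = {"xy": sp[["x", "y"]].to_numpy(float)}
    for col in sp.columns:
        if col not in ("x", "y"):
            soil_points[col] = sp[col].to_numpy(float)
    sites = read_vector(raw / "sites.csv")
    air_rasters = {p.stem.removeprefix("air_"): read_raster(p)
                   for p in sorted(raw.glob("air_*.csv"))
                   if not p.name.endswith(".meta.json")}
    em = pd.read_csv(raw / "emissions.csv", float_precision="round_trip")
    emissions = {c: em[c].to_numpy(float) for c in em.columns
                 if c != "district_id"}
    we = pd.read_csv(raw / "water_exceedances.csv", float_precision="round_trip")
    water_exceedances = we.drop(columns=["unit_id"]).to_numpy()
    noise = read_raster(raw / "noise.csv")
    population = read_raster(raw / "population.csv")
    districts = read_vector(raw / "districts.geojson")
    water_units = read_vector(raw / "water_units.geojson")
    census_blocks = read_vector(raw / "census_blocks.geojson")
    grid = build_referent_grid(cfg.region.extent, cfg.region.cell_size) \
        if noise.grid.cell_size != cfg.region.cell_size else noise.grid

    truth = None
    if (raw / "truth.json").exists():
        with open(raw / "truth.json", encoding="utf-8") as fh:
            tj = json.load(fh)
        latent = {d: read_raster(raw / f"latent_{d}.csv") for d in DIMENSIONS
                  if (raw / f"latent_{d}.csv").exists()}
        truth = SyntheticTruth(
            hotspots={d: [Hotspot(center=tuple(h["center"]),
                                  radius_m=h["radius_m"],
                                  amplitude=h["amplitude"])
                          for h in hs]
                      for d, hs in tj["hotspots"].items()},
            latent=latent, background_mean=tj["background_mean"])
    bundle = RegionBundle(
        config=cfg.region, grid=grid, soil_points=soil_points, sites=sites,
        air_rasters=air_rasters, emissions=emissions,
        water_exceedances=water_exceedances, noise=noise,
        population=population, districts=districts, water_units=water_units,
        census_blocks=census_blocks, truth=truth,
        N_WATER_YEARS=water_exceedances.shape[1])
    return bundle, cfg


def _setup_logging(out_dir: Path) -> logging.Handler:
    fh = logging.FileHandler(out_dir / "run.log", mode="w", encoding="utf-8")
    fh.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(fh)
    if not any(isinstance(h, logging.StreamHandler)
               and not isinstance(h, logging.FileHandler)
               for h in logger.handlers):
        sh = logging.StreamHandler()
        sh.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        logger.addHandler(sh)
    logger.setLevel(logging.INFO)
    return fh


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> RunResult:
    """Full file-backed run; returns the in-memory result as well."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fh = _setup_logging(out_dir)
    try:
        t0 = time.perf_counter()
        cfg.to_yaml(out_dir / "config.yaml")
        bundle = _stage("simulate", "region", generate_region, cfg.region)
        logger.info("simulate: grid %dx%d (%d cells), %d soil points, %d sites",
                    bundle.grid.n_rows, bundle.grid.n_cols, bundle.grid.n_cells,
                    len(bundle.soil_points["xy"]), len(bundle.sites))
        write_bundle(bundle, out_dir / "raw", cfg)
        raw_hashes = {p.name: file_sha256(p)
                      for p in sorted((out_dir / "raw").glob("*.csv"))}

        t1 = time.perf_counter()
        result = run_indicator_stages(bundle, cfg)
        logger.info("stages complete in %.2f s (simulate %.2f s)",
                    time.perf_counter() - t1, t1 - t0)

        sp_dir = out_dir / "spatial"
        sp_dir.mkdir(exist_ok=True)
        for name, field in result.spatial.items():
            write_raster(field, sp_dir / f"{name}.csv",
                         provenance={"stage": "spatialize", "seed": cfg.seed,
                                     "input_hashes": raw_hashes})
            logger.info("spatialize: %s — %d valid cells", name,
                        int(field.mask.sum()))

        ind_dir = out_dir / "indicators"
        ind_dir.mkdir(exist_ok=True)
        for name, sub in result.components.items():
            write_raster(sub.field, ind_dir / f"{name}.csv",
                         provenance={"stage": "transform", "seed": cfg.seed,
                                     "input_hashes": raw_hashes})

        for method, mr in result.by_method.items():
            mdir = out_dir / "standardized" / method
            mdir.mkdir(parents=True, exist_ok=True)
            for dim, sf in mr.standardized.items():
                write_raster(sf.field, mdir / f"{dim}.csv", provenance={
                    "stage": "standardize", "seed": cfg.seed, "method": method,
                    "n": sf.field.grid.n_cells, "n_background": sf.n_background,
                    "background_value": None if np.isnan(sf.background_value)
                    else sf.background_value})
            for dim, fld in mr.raw_combined.items():
                write_raster(fld, mdir / f"raw_{dim}.csv", provenance={
                    "stage": "standardize", "seed": cfg.seed, "method": method})
            comp_dir = out_dir / "composite"
            comp_dir.mkdir(exist_ok=True)
            write_raster(mr.composite.field,
                         comp_dir / f"composite_{method}.csv",
                         provenance={"stage": "compose", "seed": cfg.seed,
                                     "method": method})
            _write_df(mr.blocks, comp_dir / f"blocks_{method}.csv", "compose",
                      cfg, raw_hashes)
            blocks_map = dict(zip(mr.blocks["block_id"], mr.blocks["value"]))
            write_vector(bundle.census_blocks.with_attributes(
                np.array([blocks_map[z] for z in bundle.census_blocks.ids])),
                comp_dir / f"blocks_{method}.geojson")

            ddir = out_dir / "diagnostics"
            ddir.mkdir(exist_ok=True)
            dd = mr.diagnostics
            _write_df(dd["correlations"], ddir / f"correlations_{method}.csv",
                      "diagnose", cfg, raw_hashes, index=True)
            _write_df(dd["contributions"], ddir / f"contributions_{method}.csv",
                      "diagnose", cfg, raw_hashes)
            _write_df(dd["equity"].table, ddir / f"equity_{method}.csv",
                      "diagnose", cfg, raw_hashes)
            if len(dd["heteroscedasticity"]):
                _write_df(dd["heteroscedasticity"],
                          ddir / f"heteroscedasticity_{method}.csv",
                          "diagnose", cfg, raw_hashes)
            _write_df(dd["slopes"], ddir / f"slopes_{method}.csv", "diagnose",
                      cfg, raw_hashes)
            gof_all = pd.concat([g.assign(dimension=d)
                                 for d, g in dd["gof"].items()],
                                ignore_index=True)
            _write_df(gof_all, ddir / f"gof_{method}.csv", "diagnose", cfg,
                      raw_hashes)
            logger.info("method %s: composite max %.4f, equity %s", method,
                        mr.composite.field.values.max(),
                        "PASS" if dd["equity"].passed else "reported")
        logger.info("pipeline finished in %.2f s", time.perf_counter() - t0)
        return result
    finally:
        logger.removeHandler(fh)
        fh.close()
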