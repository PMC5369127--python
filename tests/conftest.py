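import numpy as np
import pytest

from cumrisk import (PipelineConfig, RegionConfig, build_referent_grid,
                     generate_region, run_indicator_stages)
from cumrisk.grid import RasterField
from cumrisk.standardize import StandardizedField


@pytest.fixture(scope="session")
def small_grid():
    """6 rows × 10 cols of 1 km cells."""
    return build_referent_grid((0.0, 0.0, 10_000.0, 6_000.0), 1000.0)


@pytest.fixture(scope="session")
def region_bundle():
    """Default-scale synthetic region shared across read-only tests."""
    return generate_region(RegionConfig(seed=42))


@pytest.fixture(scope="session")
def pipeline_result(region_bundle):
    return run_indicator_stages(region_bundle, PipelineConfig(seed=42))


@pytest.fixture
def tiny_pipeline_config():
    """Small region for fast end-to-end runs."""
    region = RegionConfig(extent=(0.0, 0.0, 20_000.0, 15_000.0),
                          n_soil_points=120, n_sites=15, n_districts=8,
                          n_water_units=10, n_census_blocks=25,
                          hotspots_per_dimension=2, seed=7)
    return PipelineConfig(region=region, seed=7)


def make_standardized(grid, scores, method="percentile_rank", dimension="air",
                      background_mask=None, background_value=float("nan")):
    """Hand-built StandardizedField for diagnostics tests."""
    scores = np.asarray(scores, dtype=float).reshape(grid.shape)
    bg = (np.zeros(grid.shape, dtype=bool) if background_mask is None
          else np.asarray(background_mask, dtype=bool).reshape(grid.shape))
    return StandardizedField(
        field=RasterField(grid=grid, values=scores, name=dimension),
        method=method, background_mask=bg, background_value=background_value,
        n_background=int(bg.sum()), dimension=dimension)
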