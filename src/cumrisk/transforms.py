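"""Exposure transformation: discretized layers → risk-factor sub-indicators.

The four dimensions are soil, air, water and noise. Soil combines a
site-proximity density with a topsoil ingestion hazard-quotient sum; air
combines concentration/standard ratios with a toxicity-weighted emission
score; water is a threshold-exceedance score per distribution unit; noise
is the Lden level itself.

The soil dose arithmetic here is a single-pathway (soil ingestion)
screening model: ADD = concentration × intake × frequency / body weight,
HQ = ADD / RfD, HQs summed across pollutants assuming independence of
action. Richer multimedia transfer models can be plugged in upstream by
supplying precomputed ADD fields to :func:`soil_concentration_indicator`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np

from .grid import RasterField

__all__ = [
    "ToxicityTable",
    "ExposureFactors",
    "SubIndicator",
    "DEFAULT_TOXICITY",
    "DEFAULT_EXPOSURE_FACTORS",
    "average_daily_dose",
    "hazard_quotient",
    "soil_concentration_indicator",
    "air_concentration_indicator",
    "emission_score",
    "water_exceedance_score",
    "noise_indicator",
    "combine_equity",
]

DIMENSIONS = ("soil", "air", "water", "noise")


@dataclass
class ToxicityTable:
    """Per-pollutant reference values.

    rfd
        Oral reference dose, mg·kg⁻¹·day⁻¹ (chronic non-cancer).
    air_standard
        Annual air quality standard, µg·m⁻³.
    water_threshold
        Drinking-water threshold in substance units.
    cancer_weight, noncancer_weight
        Dimensionless toxicity weights for emission screening.
    """

    rfd: dict[str, float] = dc_field(default_factory=dict)
    air_standard: dict[str, float] = dc_field(default_factory=dict)
    water_threshold: dict[str, float] = dc_field(default_factory=dict)
    cancer_weight: dict[str, float] = dc_field(default_factory=dict)
    noncancer_weight: dict[str, float] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("rfd", "air_standard", "water_threshold"):
            for pol, v in getattr(self, name).items():
                if v <= 0:
                    raise ValueError(f"{name}[{pol!r}] must be > 0, got {v}")


@dataclass(frozen=True)
class AgeClass:
    name: str
    soil_ingestion_kg_day: float     # e.g. 1e-4 kg/day ≈ 100 mg/day for a child
    exposure_frequency: float        # fraction of days, (0, 1]
    body_weight_kg: float

    def __post_init__(self) -> None:
        if self.soil_ingestion_kg_day <= 0 or self.body_weight_kg <= 0:
            raise ValueError("ingestion rate and body weight must be > 0")
        if not 0 < self.exposure_frequency <= 1:
            raise ValueError("exposure frequency must be in (0, 1]")


@dataclass
class ExposureFactors:
    """Per-age-class soil ingestion parameters."""

    age_classes: list[AgeClass]

    def __post_init__(self) -> None:
        if not self.age_classes:
            raise ValueError("at least one age class is required")


# screening defaults: oral RfDs (mg/kg/day) and EU annual air standards
# (µg/m³) of the pollutants the synthetic generator emits
DEFAULT_TOXICITY = ToxicityTable(
    rfd={"Cd": 1e-3, "Pb": 3.5e-3, "As": 3e-4},
    air_standard={"NO2": 40.0, "PM10": 40.0, "O3": 120.0},
    water_threshold={"As": 10.0, "F": 1.5},
    cancer_weight={"benzene": 1.0, "PAH": 1.0, "PM10": 0.1},
    noncancer_weight={"benzene": 0.2, "PAH": 0.5, "PM10": 1.0},
)

DEFAULT_EXPOSURE_FACTORS = ExposureFactors(age_classes=[
    AgeClass("child", soil_ingestion_kg_day=1e-4, exposure_frequency=1.0,
             body_weight_kg=15.0),
    AgeClass("adult", soil_ingestion_kg_day=5e-5, exposure_frequency=1.0,
             body_weight_kg=70.0),
])


@dataclass
class SubIndicator:
    """A named risk-factor field before or after standardization."""

    field: RasterField
    dimension: str
    stage: str = "raw"

    def __post_init__(self) -> None:
        if self.dimension not in DIMENSIONS and self.dimension not in (
                "proximity", "soil_hq", "air_conc", "emission"):
            raise ValueError(f"unknown dimension {self.dimension!r}")
        if self.stage not in ("raw", "standardized"):
            raise ValueError(f"stage must be 'raw' or 'standardized', got {self.stage!r}")
        if self.stage == "raw" and np.any(self.field.valid_values < 0):
            raise ValueError(f"raw sub-indicator {self.dimension} has negative values")


# ---------------------------------------------------------------------------
# dose / hazard-quotient arithmetic
# ---------------------------------------------------------------------------

def average_daily_dose(conc, intake: float, frequency: float, body_weight: float):
    """ADD (mg·kg⁻¹·day⁻¹) from a soil concentration (mg·kg⁻¹ soil).

    Linear single-pathway ingestion model:
    ADD = conc × intake × frequency / body_weight.
    """
    if body_weight <= 0:
        raise ValueError(f"body_weight must be > 0, got {body_weight}")
    if intake <= 0 or frequency <= 0:
        raise ValueError("intake and frequency must be > 0")
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentration must be ≥ 0")
    return conc * intake * frequency / body_weight


def hazard_quotient(add, rfd: float):
    """HQ = ADD / RfD; HQ > 1 flags potential non-cancer concern."""
    if rfd <= 0:
        raise ValueError(f"rfd must be > 0, got {rfd}")
    return np.asarray(add, dtype=float) / rfd


# ---------------------------------------------------------------------------
# per-dimension sub-indicator components
# ---------------------------------------------------------------------------

def soil_concentration_indicator(conc_fields: dict[str, RasterField],
                                 factors: ExposureFactors = DEFAULT_EXPOSURE_FACTORS,
                                 tox: ToxicityTable = DEFAULT_TOXICITY) -> SubIndicator:
    """Topsoil concentration indicator: summed HQs, max over age classes.

    Per cell and age class the hazard quotients of all pollutants are
    summed (independence of action); the cellwise maximum over age
    classes is retained as a conservative screening value.
    """
    missing = [p for p in conc_fields if p not in tox.rfd]
    if missing:
        raise KeyError(f"no RfD for pollutants {missing}")
    if not conc_fields:
        raise ValueError("at least one concentration field is required")
    first = next(iter(conc_fields.values()))
    per_age = []
    for ac in factors.age_classes:
        hq_sum = np.zeros(first.grid.shape)
        for pol, fld in conc_fields.items():
            add = average_daily_dose(fld.values, ac.soil_ingestion_kg_day,
                                     ac.exposure_frequency, ac.body_weight_kg)
            hq_sum += hazard_quotient(add, tox.rfd[pol])
        per_age.append(hq_sum)
    out = np.maximum.reduce(per_age)
    mask = np.logical_and.reduce([f.mask for f in conc_fields.values()])
    field = RasterField(grid=first.grid, values=np.where(mask, out, 0.0),
                        mask=mask, units="HQ sum", name="soil_hq")
    return SubIndicator(field=field, dimension="soil_hq")


def air_concentration_indicator(conc_fields: dict[str, RasterField],
                                tox: ToxicityTable = DEFAULT_TOXICITY) -> SubIndicator:
    """Σ over pollutants of (annual mean concentration / air standard)."""
    missing = [p for p in conc_fields if p not in tox.air_standard]
    if missing:
        raise KeyError(f"no air quality standard for pollutants {missing}")
    if not conc_fields:
        raise ValueError("at least one concentration field is required")
    first = next(iter(conc_fields.values()))
    out = np.zeros(first.grid.shape)
    mask = np.ones(first.grid.shape, dtype=bool)
    for pol, fld in conc_fields.items():
        out += fld.values / tox.air_standard[pol]
        mask &= fld.mask
    field = RasterField(grid=first.grid, values=np.where(mask, out, 0.0),
                        mask=mask, units="sum of conc/standard", name="air_conc")
    return SubIndicator(field=field, dimension="air_conc")


def _minmax_component(v: np.ndarray, mask: np.ndarray, label: str) -> np.ndarray:
    lo, hi = v[mask].min(), v[mask].max()
    if hi - lo <= 0:
        warnings.warn(f"emission component {label!r} is constant over valid cells; "
                      "it contributes 0 everywhere", stacklevel=3)
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def emission_score(emission_fields: dict[str, RasterField],
                   tox: ToxicityTable = DEFAULT_TOXICITY,
                   weights: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> SubIndicator:
    """Relative emission risk score in [0, 1].

    Three components — total emissions T, cancer-weighted Wc and
    respiratory non-cancer-weighted Wn — are each min–max scaled to [0,1]
    over valid cells and averaged (equal weights by default; the relative
    weighting is configurable).
    """
    if not emission_fields:
        raise ValueError("at least one emission field is required")
    first = next(iter(emission_fields.values()))
    mask = np.logical_and.reduce([f.mask for f in emission_fields.values()])
    T = np.zeros(first.grid.shape)
    Wc = np.zeros(first.grid.shape)
    Wn = np.zeros(first.grid.shape)
    for pol, fld in emission_fields.items():
        T += fld.values
        Wc += fld.values * tox.cancer_weight.get(pol, 0.0)
        Wn += fld.values * tox.noncancer_weight.get(pol, 0.0)
    comps = [_minmax_component(c, mask, lbl)
             for c, lbl in ((T, "total"), (Wc, "cancer"), (Wn, "noncancer"))]
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("component weights must be ≥ 0 with positive sum")
    out = sum(wi * c for wi, c in zip(w, comps)) / w.sum()
    field = RasterField(grid=first.grid, values=np.where(mask, out, 0.0),
                        mask=mask, units="scaled score", name="emission")
    return SubIndicator(field=field, dimension="emission")


def water_exceedance_score(annual_exceedances: np.ndarray,
                           n_years: int | None = None) -> np.ndarray:
    """Per-zone score: multi-year average of threshold-exceedance counts.

    Concentrations below thresholds contribute nothing — zones with no
    exceedance score 0 and are later treated as background.
    """
    counts = np.atleast_2d(np.asarray(annual_exceedances, dtype=float))
    if n_years is None:
        n_years = counts.shape[1]
    if n_years < 1:
        raise ValueError("n_years must be ≥ 1")
    if counts.shape[1] != n_years:
        raise ValueError(f"expected {n_years} yearly columns, got {counts.shape[1]}")
    if np.any(counts < 0):
        raise ValueError("exceedance counts must be ≥ 0")
    return counts.sum(axis=1) / n_years


def noise_indicator(lden_field: RasterField) -> SubIndicator:
    """Pass-through of the discretized Lden field; nodata stays nodata."""
    if np.any(lden_field.valid_values < 0):
        raise ValueError("Lden values must be ≥ 0")
    return SubIndicator(field=lden_field.copy_with(lden_field.values.copy(),
                                                   name="noise"),
                        dimension="noise")


def combine_equity(a: SubIndicator, b: SubIndicator, method: str = "normal_score",
                   background_rules: dict[str, str] | None = None) -> RasterField:
    """Equity-weighted combination of two sub-indicator components.

    Each component is standardized with the chosen rank transform (so both
    enter with identical mean and range) and the scores are summed
    cellwise, giving values in [0, 2]. Used for air (concentrations +
    emissions) and soil (proximity + topsoil HQ).
    """
    from .standardize import standardize_sub_indicator

    if a.field.grid != b.field.grid:
        raise ValueError("combine_equity requires both fields on the same grid")
    sa = standardize_sub_indicator(a, method=method, background_rules=background_rules)
    sb = standardize_sub_indicator(b, method=method, background_rules=background_rules)
    vals = sa.field.values + sb.field.values
    return RasterField(grid=a.field.grid, values=vals,
                       units="sum of standardized scores",
                       name=f"{a.dimension}+{b.dimension}")
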