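"""Composite indicator and the diagnostics of its construction.

The composite is the cellwise sum of the standardized sub-indicators; the
diagnostics quantify how construction choices shape it: Spearman
correlation structure between dimensions, the decomposition of cells in
the upper tail (above the 90th percentile by default) into per-dimension
percentage contributions, sliding-window slopes of the transform curves
(extremum smoothing), the background-gap heteroscedasticity ratio, and
goodness-of-fit ranking of symmetric score distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from shapely.strtree import STRtree

from .grid import RasterField, ZoneMap
from .standardize import StandardizedField

__all__ = [
    "CompositeField",
    "composite_indicator",
    "population_weighted_aggregate",
    "correlation_matrix",
    "contribution_above_percentile",
    "transform_slope",
    "heteroscedasticity_ratio",
    "fit_rank_distribution",
]


@dataclass
class CompositeField:
    """Cellwise sum of k standardized sub-indicators (values in [0, k])."""

    field: RasterField
    components: list[StandardizedField]
    method: str

    @property
    def k(self) -> int:
        return len(self.components)


def composite_indicator(fields: list[StandardizedField]) -> CompositeField:
    """Sum standardized sub-indicators cellwise.

    Cells that are background in every input stay valid — they carry the
    summed background scores.
    """
    if len(fields) < 2:
        raise ValueError("composite needs at least 2 sub-indicators")
    methods = {f.method for f in fields}
    if len(methods) > 1:
        raise ValueError(f"mixed standardization methods {sorted(methods)}")
    g = fields[0].field.grid
    if any(f.field.grid != g for f in fields):
        raise ValueError("grid mismatch between sub-indicators")
    total = np.sum([f.field.values for f in fields], axis=0)
    out = RasterField(grid=g, values=total, units="summed scores",
                      name=f"composite_{fields[0].method}")
    return CompositeField(field=out, components=list(fields),
                          method=fields[0].method)


# ---------------------------------------------------------------------------
# population-weighted aggregation to census blocks
# ---------------------------------------------------------------------------

def population_weighted_aggregate(composite: CompositeField,
                                  population: RasterField,
                                  blocks: ZoneMap) -> pd.DataFrame:
    """Population-weighted mean composite per census block.

    Each referent cell is assigned to exactly one block by largest
    polygon–cell overlap. Blocks whose member cells carry zero total
    population fall back to the unweighted mean and are flagged.
    """
    g = composite.field.grid
    if population.grid != g:
        raise ValueError("population raster must live on the composite grid")
    tree = STRtree(blocks.polygons)
    assign = np.full(g.shape, -1, dtype=int)
    for i in range(g.n_rows):
        for j in range(g.n_cols):
            cell = g.cell_box(i, j)
            idx = tree.query(cell)
            if len(idx) == 0:
                continue
            areas = [cell.intersection(blocks.polygons[k]).area for k in idx]
            best = int(np.argmax(areas))
            if areas[best] > 0:
                assign[i, j] = idx[best]

    comp = composite.field.values
    pop = np.where(population.mask, population.values, 0.0)
    if np.any(pop < 0):
        raise ValueError("population must be ≥ 0")
    rows = []
    for k, zid in enumerate(blocks.ids):
        member = assign == k
        n_cells = int(member.sum())
        if n_cells == 0:
            raise ValueError(f"census block {zid!r} contains no referent cell")
        w = pop[member]
        c = comp[member]
        total_pop = float(w.sum())
        if total_pop > 0:
            value = float((w * c).sum() / total_pop)
            flagged = False
        else:
            value = float(c.mean())
            flagged = True
        rows.append({"block_id": zid, "value": value, "total_population": total_pop,
                     "n_cells": n_cells, "zero_population": flagged})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# correlation structure
# ---------------------------------------------------------------------------

def correlation_matrix(fields: list, names: list[str] | None = None) -> pd.DataFrame:
    """Pairwise Spearman rank correlations over jointly valid cells.

    Accepts StandardizedField or raw RasterField inputs. Entries for
    constant fields are reported missing (NaN).
    """
    rasters = [f.field if isinstance(f, StandardizedField) else f for f in fields]
    if len(rasters) < 2:
        raise ValueError("need at least 2 fields")
    if names is None:
        names = [getattr(f, "dimension", None) or r.name or f"field{i}"
                 for i, (f, r) in enumerate(zip(fields, rasters))]
    n = len(rasters)
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            m = rasters[i].mask & rasters[j].mask
            if m.sum() < 3:
                raise ValueError("fewer than 3 shared valid cells")
            a, b = rasters[i].values[m], rasters[j].values[m]
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                r = np.nan
            else:
                r = stats.spearmanr(a, b).statistic
            out[i, j] = out[j, i] = r
    return pd.DataFrame(out, index=names, columns=names)


# ---------------------------------------------------------------------------
# top-tail contribution decomposition
# ---------------------------------------------------------------------------

def contribution_above_percentile(composite: CompositeField, q: float = 0.9,
                                  pooled: bool = False) -> pd.DataFrame:
    """Per-dimension percentage contribution over upper-tail cells.

    Cells strictly above the empirical q-quantile of the composite are
    selected (ties at the threshold excluded). By default each selected
    cell's share (score/composite) is averaged over cells
    (share-then-average, which preserves the sum-to-100 property);
    ``pooled=True`` instead reports Σ score / Σ composite.
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    comp = composite.field
    vals = comp.values[comp.mask]
    if vals.size <= 1.0 / (1.0 - q):
        raise ValueError("too few cells for this percentile")
    thr = np.quantile(vals, q)
    sel = comp.mask & (comp.values > thr)
    if sel.sum() == 0:
        raise ValueError("no cells strictly above the threshold (all tied)")
    c = comp.values[sel]
    if np.any(c <= 0):
        raise ValueError("composite is 0 in a selected cell")
    rows = []
    for f in composite.components:
        s = f.field.values[sel]
        if pooled:
            pct = 100.0 * s.sum() / c.sum()
        else:
            pct = float(np.mean(s / c) * 100.0)
        rows.append({"dimension": f.dimension or f.field.name,
                     "contribution_pct": pct})
    out = pd.DataFrame(rows)
    out.attrs["threshold"] = float(thr)
    out.attrs["n_cells"] = int(sel.sum())
    return out


# ---------------------------------------------------------------------------
# transform-curve slope and background-gap diagnostics
# ---------------------------------------------------------------------------

def transform_slope(raw: np.ndarray, scores: np.ndarray, window: int) -> np.ndarray:
    """OLS slope of score vs raw value in a sliding centred window.

    Inputs must be sorted by raw value. Positions whose centred window
    would overhang an end are NaN. A window with zero raw-value variance
    gets slope 0 (tied raw values are transformed to tied scores).
    """
    raw = np.asarray(raw, dtype=float).ravel()
    scores = np.asarray(scores, dtype=float).ravel()
    if raw.shape != scores.shape:
        raise ValueError("raw and scores must have equal length")
    n = raw.size
    if window < 3:
        raise ValueError("window must be ≥ 3")
    if window > n:
        raise ValueError(f"window {window} larger than n={n}")
    if np.any(np.diff(raw) < 0):
        raise ValueError("inputs must be sorted by raw value")
    from numpy.lib.stride_tricks import sliding_window_view
    rw = sliding_window_view(raw, window)
    sw = sliding_window_view(scores, window)
    rm = rw.mean(axis=1, keepdims=True)
    sm = sw.mean(axis=1, keepdims=True)
    var = ((rw - rm) ** 2).sum(axis=1)
    cov = ((rw - rm) * (sw - sm)).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        slopes = np.where(var > 0, cov / np.where(var > 0, var, 1.0), 0.0)
    out = np.full(n, np.nan)
    half = (window - 1) // 2
    out[half:half + slopes.size] = slopes
    return out


def heteroscedasticity_ratio(field: StandardizedField) -> float:
    """Background score divided by the smallest non-background score.

    Values near 1 mean the background assignment created almost no gap;
    small values flag a large gap (strong heteroscedasticity).
    """
    if field.n_background == 0:
        raise ValueError("field has no background cells")
    bg = field.background_mask
    non_bg = field.field.values[~bg]
    if non_bg.size == 0:
        raise ValueError("field has no non-background cells")
    return float(field.background_value / non_bg.min())


# ---------------------------------------------------------------------------
# goodness-of-fit ranking of symmetric score distributions
# ---------------------------------------------------------------------------

def _moment_fit(values: np.ndarray, family: str):
    mu, sd = values.mean(), values.std(ddof=1)
    if family == "normal":
        return stats.norm(loc=mu, scale=sd)
    if family == "uniform":
        half = np.sqrt(3.0) * sd
        return stats.uniform(loc=mu - half, scale=2 * half)
    if family == "logistic":
        return stats.logistic(loc=mu, scale=sd * np.sqrt(3.0) / np.pi)
    raise ValueError(f"unknown candidate family {family!r}")


def _anderson_darling(values: np.ndarray, dist) -> float:
    x = np.sort(values)
    n = x.size
    F = np.clip(dist.cdf(x), 1e-12, 1 - 1e-12)
    i = np.arange(1, n + 1)
    return float(-n - np.mean((2 * i - 1) * (np.log(F) + np.log1p(-F[::-1]))))


def fit_rank_distribution(values: np.ndarray,
                          candidates: tuple[str, ...] = ("uniform", "normal", "logistic")
                          ) -> pd.DataFrame:
    """Rank symmetric distribution families by goodness of fit.

    Parameters are fitted by moments; candidates are sorted ascending by
    the Kolmogorov–Smirnov statistic (Anderson–Darling reported as well).
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 20:
        raise ValueError("need at least 20 values")
    bad = set(candidates) - {"uniform", "normal", "logistic"}
    if bad:
        raise ValueError(f"unsupported candidate families {sorted(bad)}")
    rows = []
    for fam in candidates:
        dist = _moment_fit(values, fam)
        ks = stats.kstest(values, dist.cdf).statistic
        rows.append({"family": fam, "ks_statistic": float(ks),
                     "ad_statistic": _anderson_darling(values, dist),
                     "loc": float(dist.mean()), "scale": float(dist.std())})
    return pd.DataFrame(rows).sort_values("ks_statistic", ignore_index=True)
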