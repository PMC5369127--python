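"""Rank-based standardization under the equity constraint.

Two transforms map each raw sub-indicator to dimensionless [0, 1] scores
derived only from the rank order of the values, so that every dimension
enters the composite with the same mean and range:

* **percentile_rank** — Hazen plotting position (r − 0.5)/n.
* **normal_score** — the Blom approximation of the expected standard
  normal order statistic, Φ⁻¹((r − 0.375)/(n + 0.25)), rescaled to [0, 1]
  using the rank-1 and rank-n scores of the full sample as anchors.

Cells with no measurement (nodata) or with zero exposure in hotspot-type
dimensions (water, noise, site proximity) are *background*: they occupy
the bottom ranks 1..k and share a single background score equal to the
mean of the transformed scores of those ranks. The same rule handles
ordinary ties: any group of equal values occupying integer ranks a..b
receives the mean of the transformed scores of a..b. On the percentile
scale this coincides exactly with transforming the averaged rank (the
transform is linear in the rank); on the normal-score scale the mean of
the transformed ranks is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .grid import RasterField
from .transforms import SubIndicator

__all__ = [
    "DEFAULT_BACKGROUND_RULES",
    "StandardizedField",
    "EquityReport",
    "flag_background",
    "rank_with_ties",
    "percentile_rank_transform",
    "normal_score_transform",
    "standardize_values",
    "standardize_field",
    "standardize_sub_indicator",
    "check_equity",
]

METHODS = ("normal_score", "percentile_rank")

#: hotspot-type dimensions treat measured zeros as background ("no water
#: exposure hotspot"); concentration-type dimensions keep zeros as ordinary
#: values and only nodata cells are background.
DEFAULT_BACKGROUND_RULES: dict[str, str] = {
    "soil": "concentration",
    "soil_hq": "concentration",
    "air": "concentration",
    "air_conc": "concentration",
    "emission": "concentration",
    "water": "hotspot",
    "noise": "hotspot",
    "proximity": "hotspot",
}


@dataclass
class StandardizedField:
    """A sub-indicator after rank standardization.

    All cells are valid (background cells hold the shared background
    score); ``background_mask`` records which cells were background.
    """

    field: RasterField
    method: str
    background_mask: np.ndarray
    background_value: float          # nan when there is no background cell
    n_background: int
    dimension: str = ""

    def __post_init__(self) -> None:
        v = self.field.valid_values
        if v.size and (v.min() < -1e-12 or v.max() > 1 + 1e-12):
            raise ValueError("standardized values must lie in [0, 1]")
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")

    @property
    def scores(self) -> np.ndarray:
        return self.field.values


# ---------------------------------------------------------------------------
# background flagging
# ---------------------------------------------------------------------------

def flag_background(field: RasterField, dimension: str,
                    rules: dict[str, str] | None = None) -> np.ndarray:
    """Boolean background mask: nodata cells, plus exact zeros for
    hotspot-type dimensions."""
    rules = DEFAULT_BACKGROUND_RULES if rules is None else {
        **DEFAULT_BACKGROUND_RULES, **rules}
    kind = rules.get(dimension, "concentration")
    if kind not in ("hotspot", "concentration"):
        raise ValueError(f"background rule for {dimension!r} must be "
                         f"'hotspot' or 'concentration', got {kind!r}")
    background = ~field.mask
    if kind == "hotspot":
        background |= field.mask & (field.values == 0.0)
    return background


# ---------------------------------------------------------------------------
# ranking with averaged ties
# ---------------------------------------------------------------------------

def rank_with_ties(values: np.ndarray, background_mask: np.ndarray | None = None
                   ) -> np.ndarray:
    """Fractional ranks in [1, n]; Σ ranks = n(n+1)/2.

    Background cells occupy ranks 1..k and each receives (k+1)/2;
    non-background cells are ranked k+1..n in increasing value order with
    ties averaged.
    """
    values = np.asarray(values, dtype=float).ravel()
    n = values.size
    if n < 2:
        raise ValueError("ranking needs at least 2 cells")
    if background_mask is None:
        background_mask = np.zeros(n, dtype=bool)
    bg = np.asarray(background_mask, dtype=bool).ravel()
    if bg.shape != values.shape:
        raise ValueError("background mask shape must match values")
    k = int(bg.sum())
    if k == n:
        raise ValueError("all cells are background; nothing to rank")
    ranks = np.empty(n, dtype=float)
    ranks[bg] = (k + 1) / 2.0
    ranks[~bg] = rankdata(values[~bg], method="average") + k
    return ranks


def _tie_spans(ranks: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """For each cell: (first integer rank, last integer rank) of its tie group.

    A group of m cells sharing averaged rank g occupies the integer ranks
    g − (m−1)/2 … g + (m−1)/2.
    """
    uniq, inv, counts = np.unique(ranks, return_inverse=True, return_counts=True)
    m = counts[inv].astype(float)
    g = ranks
    a = np.rint(g - (m - 1) / 2.0).astype(int)
    b = np.rint(g + (m - 1) / 2.0).astype(int)
    return a, b, m


def _check_rank_vector(ranks: np.ndarray, n: int) -> np.ndarray:
    ranks = np.asarray(ranks, dtype=float).ravel()
    if n <= 0:
        raise ValueError("n must be ≥ 1")
    if ranks.size != n:
        raise ValueError(f"rank vector has {ranks.size} entries, expected n={n}")
    if not np.isclose(ranks.sum(), n * (n + 1) / 2.0, rtol=0, atol=1e-6):
        raise ValueError("invalid rank vector: Σ ranks != n(n+1)/2")
    return ranks


# ---------------------------------------------------------------------------
# the two transforms
# ---------------------------------------------------------------------------

def percentile_rank_transform(ranks: np.ndarray, n: int) -> np.ndarray:
    """Hazen percentile scores (rank − 0.5)/n, strictly inside (0, 1)."""
    ranks = _check_rank_vector(ranks, n)
    return (ranks - 0.5) / n


def _blom(r, n: int):
    return norm.ppf((np.asarray(r, dtype=float) - 0.375) / (n + 0.25))


def normal_score_transform(ranks: np.ndarray, n: int) -> np.ndarray:
    """Normal scores rescaled to [0, 1].

    Each tie group receives the mean of the Blom scores of the integer
    ranks it occupies; the result is rescaled with the rank-1 and rank-n
    scores as anchors, so an untied minimum maps to 0 and an untied
    maximum to 1, while a tied bottom (background) group lands strictly
    above 0.
    """
    ranks = _check_rank_vector(ranks, n)
    if np.unique(ranks).size < 2:
        raise ValueError("normal score transform needs ≥ 2 distinct rank values")
    # prefix sums of the Blom grid make tie-group means O(1) each
    z_grid = _blom(np.arange(1, n + 1), n)
    cz = np.concatenate([[0.0], np.cumsum(z_grid)])
    a, b, m = _tie_spans(ranks)
    z = (cz[b] - cz[a - 1]) / m
    z1, zn = z_grid[0], z_grid[-1]
    return (z - z1) / (zn - z1)


_TRANSFORMS = {
    "percentile_rank": percentile_rank_transform,
    "normal_score": normal_score_transform,
}


# ---------------------------------------------------------------------------
# high-level standardization
# ---------------------------------------------------------------------------

def standardize_values(values: np.ndarray, background_mask: np.ndarray | None,
                       method: str) -> tuple[np.ndarray, float]:
    """Scores in [0, 1] plus the shared background score (nan if none)."""
    if method not in _TRANSFORMS:
        raise ValueError(f"unknown standardization method {method!r}")
    values = np.asarray(values, dtype=float).ravel()
    n = values.size
    bg = (np.zeros(n, dtype=bool) if background_mask is None
          else np.asarray(background_mask, dtype=bool).ravel())
    ranks = rank_with_ties(values, bg)
    scores = _TRANSFORMS[method](ranks, n)
    background_value = float(scores[bg][0]) if bg.any() else float("nan")
    return scores, background_value


def standardize_field(field: RasterField, dimension: str, method: str,
                      background_rules: dict[str, str] | None = None
                      ) -> StandardizedField:
    """Standardize a raster field with the per-dimension background rule."""
    bg2d = flag_background(field, dimension, background_rules)
    scores, background_value = standardize_values(
        np.where(field.mask, field.values, 0.0), bg2d, method)
    out = RasterField(grid=field.grid, values=scores.reshape(field.grid.shape),
                      units="standardized score",
                      name=f"{dimension}_{method}")
    return StandardizedField(field=out, method=method, background_mask=bg2d,
                             background_value=background_value,
                             n_background=int(bg2d.sum()), dimension=dimension)


def standardize_sub_indicator(sub: SubIndicator, method: str,
                              background_rules: dict[str, str] | None = None
                              ) -> StandardizedField:
    return standardize_field(sub.field, sub.dimension, method, background_rules)


# ---------------------------------------------------------------------------
# equity check
# ---------------------------------------------------------------------------

@dataclass
class EquityReport:
    table: pd.DataFrame
    passed: bool
    failures: list[str]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        status = "PASS" if self.passed else f"FAIL ({', '.join(self.failures)})"
        return f"EquityReport[{status}]\n{self.table.to_string(index=False)}"


def check_equity(fields: list[StandardizedField], tol: float = 1e-9) -> EquityReport:
    """Verify the equity constraint: equal range, and equal mean for
    fields without background inflation.

    Fields that carry background cells report their mean deviation from
    0.5 (the heteroscedasticity effect of assigning a shared background
    score) without failing the check.
    """
    if len(fields) < 2:
        raise ValueError("check_equity needs at least 2 fields")
    g = fields[0].field.grid
    if any(f.field.grid != g for f in fields):
        raise ValueError("all fields must share the same grid")
    rows = []
    for f in fields:
        v = f.field.values.ravel()
        rows.append({
            "name": f.dimension or f.field.name,
            "method": f.method,
            "mean": float(v.mean()),
            "range": float(v.max() - v.min()),
            "n_background": f.n_background,
            "mean_deviation": float(v.mean() - 0.5),
        })
    table = pd.DataFrame(rows)
    failures: list[str] = []
    ranges = table["range"].to_numpy()
    if ranges.max() - ranges.min() > tol:
        worst = table["name"][int(np.argmax(np.abs(ranges - np.median(ranges))))]
        failures.append(f"range mismatch (field {worst})")
    clean = table[table["n_background"] == 0]
    if len(clean) >= 2:
        means = clean["mean"].to_numpy()
        if means.max() - means.min() > tol:
            failures.append("mean mismatch among background-free fields")
    return EquityReport(table=table, passed=not failures, failures=failures)
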