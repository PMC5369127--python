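"""Independent oracles used by the tests.

These deliberately re-derive quantities from first principles (numerical
integration, Monte-Carlo point sampling, brute-force loops) and never call
the library code paths they are checking.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln, ndtr


def exact_normal_order_stats(n: int, n_nodes: int = 4001) -> np.ndarray:
    """E[Z_(r:n)] for r = 1..n by direct numerical integration.

    E[Z_(r:n)] = n·C(n−1, r−1) ∫ z φ(z) Φ(z)^(r−1) (1−Φ(z))^(n−r) dz,
    evaluated in log space on a dense trapezoid grid over [−9, 9].
    """
    z = np.linspace(-9.0, 9.0, n_nodes)
    log_phi = -0.5 * z * z - 0.5 * np.log(2 * np.pi)
    F = ndtr(z)
    with np.errstate(divide="ignore"):
        logF = np.log(F)
        log1mF = np.log1p(-F)
    r = np.arange(1, n + 1)[:, None]
    log_coeff = (np.log(n) + gammaln(n) - gammaln(r) - gammaln(n - r + 1))
    with np.errstate(invalid="ignore"):   # 0·(−inf) at the support edges
        log_density = log_coeff + log_phi + (r - 1) * logF + (n - r) * log1mF
        integrand = z * np.exp(log_density)
    integrand[~np.isfinite(integrand)] = 0.0
    return np.trapezoid(integrand, z, axis=1)


def brute_force_rank(values: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Re-implementation of the ranking rule with explicit loops."""
    values = np.asarray(values, dtype=float)
    background = np.asarray(background, dtype=bool)
    n = values.size
    k = int(background.sum())
    ranks = np.empty(n)
    ranks[background] = (k + 1) / 2.0
    idx = np.flatnonzero(~background)
    order = idx[np.argsort(values[idx], kind="stable")]
    pos = 0
    while pos < len(order):
        grp = [order[pos]]
        while (pos + len(grp) < len(order)
               and values[order[pos + len(grp)]] == values[grp[0]]):
            grp.append(order[pos + len(grp)])
        first = k + pos + 1
        mean_rank = first + (len(grp) - 1) / 2.0
        for g in grp:
            ranks[g] = mean_rank
        pos += len(grp)
    return ranks


def brute_force_spearman(a: np.ndarray, b: np.ndarray) -> float:
    """Rank-then-Pearson with explicit averaged ranks."""
    def avg_ranks(x):
        order = np.argsort(x, kind="stable")
        ranks = np.empty(len(x))
        pos = 0
        while pos < len(x):
            j = pos
            while j + 1 < len(x) and x[order[j + 1]] == x[order[pos]]:
                j += 1
            r = (pos + j) / 2.0 + 1.0
            for t in range(pos, j + 1):
                ranks[order[t]] = r
            pos = j + 1
        return ranks

    ra, rb = avg_ranks(np.asarray(a, float)), avg_ranks(np.asarray(b, float))
    ra -= ra.mean()
    rb -= rb.mean()
    return float((ra * rb).sum() / np.sqrt((ra ** 2).sum() * (rb ** 2).sum()))


def mc_cell_samples(rng: np.random.Generator, grid, i: int, j: int,
                    n_points: int = 100_000) -> tuple[np.ndarray, np.ndarray]:
    """Uniform random points inside referent cell (i, j)."""
    s = grid.cell_size
    x = grid.x0 + (j + rng.random(n_points)) * s
    y = grid.y0 - (i + rng.random(n_points)) * s
    return x, y


def mc_buffer_fraction(rng, grid, i, j, sites_xy, radius, n_points=100_000):
    """Monte-Carlo Σ_sites area(cell ∩ disc)/area(cell)."""
    x, y = mc_cell_samples(rng, grid, i, j, n_points)
    total = 0.0
    for sx, sy in sites_xy:
        inside = (x - sx) ** 2 + (y - sy) ** 2 <= radius * radius
        total += inside.mean()
    return total


def mc_zone_mean(rng, grid, i, j, zones, n_points=100_000):
    """Monte-Carlo area-weighted mean zone attribute over a cell."""
    import shapely

    x, y = mc_cell_samples(rng, grid, i, j, n_points)
    acc = np.zeros(n_points)
    cover = np.zeros(n_points, dtype=bool)
    for poly, attr in zip(zones.polygons, zones.attributes):
        inside = shapely.contains_xy(poly, x, y)
        acc = np.where(inside & ~cover, attr, acc)
        cover |= inside
    if not cover.any():
        return np.nan
    return float(acc[cover].mean())


def mc_aggregate_intensive(rng, target, i, j, source, n_points=100_000):
    """Monte-Carlo mean of the source raster sampled inside a target cell."""
    x, y = mc_cell_samples(rng, target, i, j, n_points)
    g = source.grid
    xmin, ymin, xmax, ymax = g.extent
    inb = (x >= xmin) & (x < xmax) & (y > ymin) & (y <= ymax)
    si, sj = g.cell_index(x[inb], y[inb])
    valid = source.mask[si, sj]
    if not valid.any():
        return np.nan
    return float(source.values[si, sj][valid].mean())
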