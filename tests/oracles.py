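"""Independent oracles for cross-checking the package's fits.

These deliberately take a different computational path from the package's
joint multi-start L-BFGS-B: the background means are profiled out (in closed
form for the proportional family, by bounded scalar minimization for the
sigmoid), and the low-dimensional focal-parameter surface is explored on a
dense grid followed by a Nelder-Mead polish.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import optimize
from scipy.special import expit


def cell_stats(table, design):
    """Per-(background, m) counts, means and within-cell sum of squares."""
    y = table.log_values()
    gids = table.genotype_ids().to_numpy()
    stats: dict[tuple[int, int], list[float]] = {}
    for yi, gid in zip(y, gids):
        stats.setdefault(design.cell_of(gid), []).append(yi)
    cells = sorted(stats)
    n = np.array([len(stats[c]) for c in cells], dtype=float)
    ybar = np.array([np.mean(stats[c]) for c in cells])
    sw = sum(float(np.sum((np.asarray(stats[c]) - np.mean(stats[c])) ** 2)) for c in cells)
    b = np.array([c[0] for c in cells])
    m = np.array([c[1] for c in cells])
    return b, m, n, ybar, sw


def profiled_loglik(rss: float, n: int) -> float:
    return -(n / 2.0) * (math.log(2.0 * math.pi * max(rss, 1e-300) / n) + 1.0)


def _proportional_profile_rss(b, m, n, ybar, sw, nb, d0, e):
    # mu(cell) = beta_b * (1 + m*d0*e) + m*d0 - m*d0*e*beta_0: linear in beta
    X = np.zeros((len(b), nb))
    offset = np.zeros(len(b))
    for i in range(len(b)):
        X[i, b[i]] += 1.0 + m[i] * d0 * e
        X[i, 0] += -m[i] * d0 * e
        offset[i] = m[i] * d0
    w = np.sqrt(n)
    beta, *_ = np.linalg.lstsq(X * w[:, None], (ybar - offset) * w, rcond=None)
    resid = ybar - (X @ beta + offset)
    return sw + float(n @ (resid * resid))


def _sigmoid_profile_rss(b, m, n, ybar, sw, nb, A, x0, r):
    total = sw
    for j in range(nb):
        sel0 = (b == j) & (m == 0)
        sel1 = (b == j) & (m == 1)
        n0 = n[sel0].sum()
        y0 = float(np.average(ybar[sel0], weights=n[sel0])) if sel0.any() else 0.0

        if not sel1.any():
            total += 0.0  # beta_j = y0 exactly; only pooled-mean scatter remains
            beta = y0
        else:
            n1 = n[sel1].sum()
            y1 = float(np.average(ybar[sel1], weights=n[sel1]))

            def f(beta):
                mu1 = beta + A * expit((beta - x0) / r)
                return n0 * (y0 - beta) ** 2 + n1 * (y1 - mu1) ** 2

            res = optimize.minimize_scalar(
                f, bounds=(min(y0, y1) - 2.0, max(y0, y1) + 2.0), method="bounded",
                options={"xatol": 1e-12},
            )
            beta = res.x
        mu = beta + m[(b == j)] * A * expit((beta - x0) / r)
        d = ybar[b == j] - mu
        total += float(n[b == j] @ (d * d))
    return total


def grid_oracle_loglik(table, design, family: str, n_grid: int = 15) -> float:
    """Best profiled log-likelihood from a dense grid + Nelder-Mead polish."""
    b, m, n, ybar, sw = cell_stats(table, design)
    nb = design.n_backgrounds
    ntot = int(n.sum())

    if family == "proportional":
        d0_grid = np.linspace(-1.0, 1.0, 2 * n_grid + 1)
        e_grid = np.linspace(-5.0, 5.0, 2 * n_grid + 1)
        best = None
        for d0, e in itertools.product(d0_grid, e_grid):
            rss = _proportional_profile_rss(b, m, n, ybar, sw, nb, d0, e)
            if best is None or rss < best[0]:
                best = (rss, np.array([d0, e]))
        res = optimize.minimize(
            lambda t: _proportional_profile_rss(b, m, n, ybar, sw, nb, *t),
            best[1], method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
        )
        return profiled_loglik(min(res.fun, best[0]), ntot)

    if family == "sigmoid":
        lo, hi = ybar.min(), ybar.max()
        A_grid = np.linspace(-1.0, 1.0, n_grid)
        x_grid = np.linspace(lo - 0.5, hi + 0.5, n_grid)
        r_grid = np.geomspace(0.02, 2.0, n_grid)
        best = None
        for A, x0, r in itertools.product(A_grid, x_grid, r_grid):
            rss = _sigmoid_profile_rss(b, m, n, ybar, sw, nb, A, x0, r)
            if best is None or rss < best[0]:
                best = (rss, np.array([A, x0, r]))
        res = optimize.minimize(
            lambda t: _sigmoid_profile_rss(b, m, n, ybar, sw, nb, t[0], t[1], max(t[2], 1e-3)),
            best[1], method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
        )
        return profiled_loglik(min(res.fun, best[0]), ntot)

    raise ValueError(family)
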