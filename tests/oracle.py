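"""Independent brute-force maximizers used to validate the EM fits.

These evaluate the observed-data log-likelihood on an iteratively refined
(p, rho) grid, sharing no code with the EM implementation under test.
"""

import numpy as np
from scipy.special import xlogy


def _ll_female(n2f, n1f, n0f, pf, rho):
    qf = 1.0 - pf
    pq = pf * qf
    return (xlogy(n2f, pf * pf + rho * pq)
            + xlogy(n1f, 2.0 * (1.0 - rho) * pq)
            + xlogy(n0f, qf * qf + rho * pq))


def _zoomed_max(f, n_grid=81, n_zoom=6):
    """Maximize f(x, y) over the unit square by repeated grid refinement."""
    x_lo = y_lo = 0.0
    x_hi = y_hi = 1.0
    best = -np.inf
    best_xy = (0.5, 0.5)
    for _ in range(n_zoom):
        xs = np.linspace(x_lo, x_hi, n_grid)
        ys = np.linspace(y_lo, y_hi, n_grid)
        X, Y = np.meshgrid(xs, ys, indexing="ij")
        with np.errstate(divide="ignore", invalid="ignore"):
            Z = f(X, Y)
        i, j = np.unravel_index(np.nanargmax(Z), Z.shape)
        if Z[i, j] > best:
            best, best_xy = float(Z[i, j]), (float(X[i, j]), float(Y[i, j]))
        hx = (x_hi - x_lo) / (n_grid - 1)
        hy = (y_hi - y_lo) / (n_grid - 1)
        x_lo, x_hi = max(0.0, X[i, j] - 2 * hx), min(1.0, X[i, j] + 2 * hx)
        y_lo, y_hi = max(0.0, Y[i, j] - 2 * hy), min(1.0, Y[i, j] + 2 * hy)
    return best, best_xy


def grid_max_h1(counts):
    """Max log-likelihood over (p_m, p_f, rho); p_m profiles out exactly."""
    pm = counts.n1m / counts.Nm
    ll_m = float(xlogy(counts.n1m, pm) + xlogy(counts.n0m, 1.0 - pm))
    best, (pf, rho) = _zoomed_max(
        lambda P, R: _ll_female(counts.n2f, counts.n1f, counts.n0f, P, R))
    return ll_m + best, (pm, pf, rho)


def grid_max_h01(counts):
    """Max log-likelihood over (p, rho) with p shared between sexes."""
    def f(P, R):
        return (xlogy(counts.n1m, P) + xlogy(counts.n0m, 1.0 - P)
                + _ll_female(counts.n2f, counts.n1f, counts.n0f, P, R))
    best, (p, rho) = _zoomed_max(f)
    return best, (p, rho)
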