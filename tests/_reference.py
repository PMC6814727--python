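"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written with naive loops and dense normal equations and
deliberately avoids the library's own code paths: basis functions are
evaluated one at a time through scipy's BSpline object (not the library's
vectorised design routine), penalized fits use explicit pseudo-inverse
normal equations, and the componentwise boosting loop is a direct
transcription of the algorithm's definition.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import BSpline


def naive_basis_matrix(x, x_min, x_max, knot_count, degree):
    """Evaluate the uniform-knot B-spline basis one function at a time.

    Shares only the documented knot convention with the library: interior
    breakpoints linspace(x_min, x_max, knot_count + 1) extended ``degree``
    equally spaced knots past each boundary; linear extension outside.
    """
    inner = np.linspace(x_min, x_max, knot_count + 1)
    h = inner[1] - inner[0]
    knots = np.concatenate(
        [x_min - h * np.arange(degree, 0, -1), inner, x_max + h * np.arange(1, degree + 1)]
    )
    n_basis = knot_count + degree
    x = np.asarray(x, dtype=float)
    B = np.zeros((x.size, n_basis))
    for j in range(n_basis):
        coef = np.zeros(n_basis)
        coef[j] = 1.0
        spl = BSpline(knots, coef, degree, extrapolate=False)
        dspl = spl.derivative()
        for i, xi in enumerate(x):
            if xi < x_min:
                B[i, j] = spl(x_min) + (xi - x_min) * dspl(x_min)
            elif xi > x_max:
                B[i, j] = spl(x_max) + (xi - x_max) * dspl(x_max)
            else:
                v = spl(xi)
                B[i, j] = 0.0 if np.isnan(v) else v
    return B


def naive_penalized_fit(B, y, lam, penalty_order=2):
    """Coefficients of min ||y - Bc||^2 + lam ||D c||^2 by pseudo-inverse."""
    D = np.diff(np.eye(B.shape[1]), n=penalty_order, axis=0)
    return np.linalg.pinv(B.T @ B + lam * (D.T @ D)) @ (B.T @ y)


def naive_boost(X_cols, bases_eval, lams, y, nu, m, penalty_order=2):
    """Componentwise L2 boosting written as plain loops.

    ``bases_eval`` maps variable index j to its precomputed basis matrix.
    Returns (selection list of column indices, risk path list with the
    offset-only risk first).
    """
    n = len(y)
    offset = sum(y) / n
    F = np.full(n, offset)
    risks = [float(np.mean((y - F) ** 2))]
    selections = []
    for _ in range(m):
        u = y - F
        best_j, best_rss, best_g = None, np.inf, None
        for j in range(len(X_cols)):
            B = bases_eval[j]
            c = naive_penalized_fit(B, u, lams[j], penalty_order)
            g = B @ c
            rss = float(np.sum((u - g) ** 2))
            if rss < best_rss:
                best_j, best_rss, best_g = j, rss, g
        F = F + nu * best_g
        selections.append(best_j)
        risks.append(float(np.mean((y - F) ** 2)))
    return selections, risks


def naive_household_ols(weeks_by_household, weights_by_household):
    """Common-intercept, per-household-slope OLS by explicit normal equations.

    ``weeks_by_household`` / ``weights_by_household`` are dicts keyed by
    household, values are lists.  Returns (beta0, {household: slope}).
    """
    households = sorted(weeks_by_household)
    H = len(households)
    rows = []
    ys = []
    for i, h in enumerate(households):
        for w, y in zip(weeks_by_household[h], weights_by_household[h]):
            r = [1.0] + [0.0] * H
            r[1 + i] = w
            rows.append(r)
            ys.append(y)
    X = np.array(rows)
    y = np.array(ys)
    beta = np.linalg.pinv(X.T @ X) @ (X.T @ y)
    return float(beta[0]), {h: float(beta[1 + i]) for i, h in enumerate(households)}
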