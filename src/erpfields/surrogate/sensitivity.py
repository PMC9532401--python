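"""Variance-based sensitivity indices via univariate additive smooths.

For each (input, output) pair a penalized cubic B-spline with 10 basis
functions is fit (smoothing chosen by GCV); the index is the variance of
the fitted values divided by the variance of the output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

__all__ = ["gam_sensitivity", "SensitivityReport", "spline_smooth"]


def _bspline_basis(x: np.ndarray, n_splines: int, degree: int = 3) -> np.ndarray:
    """Cubic B-spline design matrix with n_splines basis functions over the
    data range (uniform interior knots, clamped ends)."""
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi <= lo:
        raise ValueError("input has zero range")
    n_interior = n_splines - degree - 1
    if n_interior < 0:
        raise ValueError("n_splines too small for cubic degree")
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    knots = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
    X = np.empty((len(x), n_splines))
    for j in range(n_splines):
        coef = np.zeros(n_splines)
        coef[j] = 1.0
        X[:, j] = BSpline(knots, coef, degree, extrapolate=False)(x)
    return np.nan_to_num(X)


def spline_smooth(
    x: np.ndarray, y: np.ndarray, n_splines: int = 10,
    lambdas: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Penalized-spline fitted values with GCV-selected smoothing."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    X = _bspline_basis(x, n_splines)
    D = np.diff(np.eye(n_splines), n=2, axis=0)  # second-difference penalty
    P = D.T @ D
    XtX = X.T @ X
    Xty = X.T @ y
    n = len(y)
    if lambdas is None:
        lambdas = np.logspace(-4, 6, 31)
    best = (np.inf, None)
    for lam in lambdas:
        A = XtX + lam * P
        try:
            beta = np.linalg.solve(A, Xty)
        except np.linalg.LinAlgError:
            continue
        fitted = X @ beta
        # effective dof = trace of the hat matrix
        edof = np.trace(np.linalg.solve(A, XtX))
        rss = np.sum((y - fitted) ** 2)
        gcv = n * rss / (n - edof) ** 2
        if gcv < best[0]:
            best = (gcv, fitted)
    if best[1] is None:
        raise np.linalg.LinAlgError("all smoothing candidates were singular")
    return best[1]


@dataclass
class SensitivityReport:
    """indices[input_name][output_name] in [0, 1] (up to fitting noise)."""

    indices: pd.DataFrame  # rows = inputs, columns = outputs
    n_splines: int

    def top_inputs(self, output: str, k: int = 2) -> list:
        return list(self.indices[output].sort_values(ascending=False).index[:k])


def gam_sensitivity(
    X: pd.DataFrame | np.ndarray,
    Y: pd.DataFrame | np.ndarray,
    n_splines: int = 10,
    input_names: Optional[Sequence[str]] = None,
    output_names: Optional[Sequence[str]] = None,
) -> SensitivityReport:
    """Var(smooth fitted values) / Var(output) for every (input, output) pair.

    Outputs with zero variance get no entry (index undefined); rows of X/Y
    with non-finite output values are dropped pairwise.
    """
    if isinstance(X, pd.DataFrame):
        input_names = input_names or list(X.columns)
        X = X.to_numpy(dtype=float)
    if isinstance(Y, pd.DataFrame):
        output_names = output_names or list(Y.columns)
        Y = Y.to_numpy(dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    input_names = list(input_names or [f"x{i}" for i in range(X.shape[1])])
    output_names = list(output_names or [f"y{j}" for j in range(Y.shape[1])])

    out = {}
    for j, yname in enumerate(output_names):
        y = Y[:, j]
        keep = np.isfinite(y)
        vy = np.var(y[keep])
        if vy == 0 or keep.sum() < n_splines + 2:
            continue  # undefined: reported as absent
        col = {}
        for i, xname in enumerate(input_names):
            fitted = spline_smooth(X[keep, i], y[keep], n_splines=n_splines)
            col[xname] = float(np.var(fitted) / vy)
        out[yname] = col
    indices = pd.DataFrame(out).reindex(input_names)
    return SensitivityReport(indices=indices, n_splines=n_splines)
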