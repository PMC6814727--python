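"""Penalized B-spline (P-spline) base-learners.

A base-learner for one covariate is a B-spline basis on equally spaced
knots over the training range, combined with a difference penalty on
adjacent coefficients.  The penalty weight lambda is calibrated so every
base-learner has the same effective degrees of freedom (default 4),
which keeps componentwise selection unbiased across covariates with
different distributions.

Knot layout: the training range [x_min, x_max] is split into ``knot_count``
equal segments; the knot grid extends ``degree`` extra equally spaced knots
beyond each boundary (the standard P-spline convention, no clamping), giving
``knot_count + degree`` basis functions.  Inside the range the basis is a
partition of unity; outside, evaluation extrapolates each basis function
linearly from the nearest boundary, so extrapolated rows still sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

from .errors import CalibrationError, DegenerateBasisError, InvalidArgumentError

__all__ = ["PSplineBasis", "build_basis", "calibrate_lambda", "difference_matrix"]


def difference_matrix(n_basis: int, order: int) -> np.ndarray:
    """Difference-penalty matrix D with ``order`` applied to n_basis coefficients."""
    if order < 1:
        raise InvalidArgumentError("penalty order must be >= 1")
    return np.diff(np.eye(n_basis), n=order, axis=0)


@dataclass
class PSplineBasis:
    """B-spline design for one covariate, with linear out-of-range extension."""

    var_name: str
    degree: int
    knot_count: int          # number of equal segments between the boundaries
    penalty_order: int
    x_min: float
    x_max: float
    lam: float = 0.0
    target_df: float | None = None
    knots: np.ndarray = field(init=False, repr=False)
    _lo_row: np.ndarray = field(init=False, repr=False)
    _lo_slope: np.ndarray = field(init=False, repr=False)
    _hi_row: np.ndarray = field(init=False, repr=False)
    _hi_slope: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        if self.degree < 1:
            raise InvalidArgumentError("degree must be >= 1")
        if self.knot_count < 1:
            raise InvalidArgumentError("knot_count must be >= 1")
        if not self.x_min < self.x_max:
            raise DegenerateBasisError(
                f"{self.var_name!r}: training range is degenerate ({self.x_min} == {self.x_max})"
            )
        inner = np.linspace(self.x_min, self.x_max, self.knot_count + 1)
        h = inner[1] - inner[0]
        self.knots = np.concatenate(
            [self.x_min - h * np.arange(self.degree, 0, -1), inner,
             self.x_max + h * np.arange(1, self.degree + 1)]
        )
        # rows and derivative rows at the boundaries, for linear extrapolation
        self._lo_row = self._inner_rows(np.array([self.x_min]))[0]
        self._hi_row = self._inner_rows(np.array([self.x_max]))[0]
        self._lo_slope = self._deriv_row(self.x_min)
        self._hi_slope = self._deriv_row(self.x_max)

    @property
    def n_basis(self) -> int:
        return self.knot_count + self.degree

    def _inner_rows(self, x: np.ndarray) -> np.ndarray:
        return BSpline.design_matrix(x, self.knots, self.degree, extrapolate=False).toarray()

    def _deriv_row(self, x0: float) -> np.ndarray:
        row = np.empty(self.n_basis)
        for j in range(self.n_basis):
            coef = np.zeros(self.n_basis)
            coef[j] = 1.0
            row[j] = BSpline(self.knots, coef, self.degree)(x0, nu=1)
        return row

    def design(self, x) -> np.ndarray:
        """Basis rows for each value of x (linear extension outside the range)."""
        x = np.asarray(x, dtype=float)
        flat = np.atleast_1d(x).ravel()
        B = np.zeros((flat.size, self.n_basis))
        below = flat < self.x_min
        above = flat > self.x_max
        inside = ~(below | above)
        if inside.any():
            B[inside] = self._inner_rows(flat[inside])
        if below.any():
            B[below] = self._lo_row + np.outer(flat[below] - self.x_min, self._lo_slope)
        if above.any():
            B[above] = self._hi_row + np.outer(flat[above] - self.x_max, self._hi_slope)
        return B

    def penalty(self) -> np.ndarray:
        return difference_matrix(self.n_basis, self.penalty_order)

    def spec_dict(self) -> dict:
        """JSON-serializable description (for model containers)."""
        return {
            "var_name": self.var_name,
            "degree": self.degree,
            "knot_count": self.knot_count,
            "penalty_order": self.penalty_order,
            "x_min": self.x_min,
            "x_max": self.x_max,
            "lam": self.lam,
            "target_df": self.target_df,
        }

    @classmethod
    def from_spec_dict(cls, d: dict) -> "PSplineBasis":
        return cls(**d)


def build_basis(
    x_values,
    var_name: str = "x",
    knot_count: int = 20,
    degree: int = 3,
    penalty_order: int = 2,
) -> PSplineBasis:
    """Construct a P-spline basis over the range of the training values.

    Raises :class:`DegenerateBasisError` when the covariate has fewer than
    two distinct values (a constant cannot support a spline).
    """
    x = np.asarray(x_values, dtype=float)
    if x.size < 2 or np.unique(x).size < 2:
        raise DegenerateBasisError(f"{var_name!r}: need >= 2 distinct values")
    if not np.all(np.isfinite(x)):
        raise InvalidArgumentError(f"{var_name!r}: non-finite values in training data")
    return PSplineBasis(
        var_name=var_name,
        degree=degree,
        knot_count=knot_count,
        penalty_order=penalty_order,
        x_min=float(x.min()),
        x_max=float(x.max()),
    )


def effective_df(B: np.ndarray, P: np.ndarray, lam: float) -> float:
    """trace of the penalized hat matrix B (B'B + lam P'P)^-1 B'."""
    BtB = B.T @ B
    A = BtB + lam * (P.T @ P)
    try:
        return float(np.trace(np.linalg.solve(A, BtB)))
    except np.linalg.LinAlgError:
        return float(np.trace(np.linalg.pinv(A) @ BtB))


def calibrate_lambda(
    basis: PSplineBasis,
    x_values,
    target_df: float = 4.0,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> float:
    """Find lambda giving the requested effective degrees of freedom.

    Solves trace(B (B'B + lam D'D)^-1 B') = target_df by monotone bisection
    on log lambda.  The reachable df range is (penalty_order, rank(B)]:
    lambda -> 0 gives the unpenalized rank, lambda -> infinity leaves only
    the penalty null space (polynomials of degree < penalty_order).
    The calibrated value is stored on ``basis.lam``.
    """
    B = basis.design(x_values)
    P = basis.penalty()
    if target_df >= basis.n_basis:
        raise CalibrationError(f"target_df {target_df} >= basis dimension {basis.n_basis}")

    df0 = effective_df(B, P, 0.0)
    if target_df > df0 + tol:
        raise CalibrationError(
            f"target_df {target_df} exceeds the unpenalized df {df0:.3f} for this design"
        )
    if abs(df0 - target_df) <= tol:
        basis.lam, basis.target_df = 0.0, target_df
        return 0.0
    if target_df <= basis.penalty_order:
        raise CalibrationError(
            f"target_df {target_df} <= penalty null-space dimension {basis.penalty_order}"
        )

    lo, hi = -12.0, 12.0   # log10 lambda bracket, expanded if needed
    while effective_df(B, P, 10.0**hi) > target_df and hi < 40:
        hi += 4.0
    while effective_df(B, P, 10.0**lo) < target_df and lo > -40:
        lo -= 4.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        df = effective_df(B, P, 10.0**mid)
        if abs(df - target_df) <= tol:
            basis.lam, basis.target_df = 10.0**mid, target_df
            return basis.lam
        if df > target_df:
            lo = mid
        else:
            hi = mid
    raise CalibrationError(f"lambda calibration did not converge to df={target_df}")
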