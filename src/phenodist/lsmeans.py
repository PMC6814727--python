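"""Household growth model and least-squares means.

Within a breed and age phase, average individual weight y at week w in
household h is modelled as

    y_hw = beta0 + s_h * w + e_hw

a single common intercept (all chicks share hatch weight) with one growth
slope per household, fitted by ordinary least squares jointly over all
households.  The least-squares mean of a household is the model's prediction
at a common evaluation week — the phase-average week — which adjusts for
households having been weighed at different ages:

    lsmean_h = beta0 + s_h * eval_week

Standard errors propagate the estimated covariance of (beta0, s_h) through
this linear combination, with residual variance on n - (1 + H) degrees of
freedom (floored at 1).

Rank-deficient designs (e.g. every observation at one identical week, where
intercept and slopes are confounded) are solved by minimum-norm least
squares and reported through ``design_rank`` plus a
:class:`~phenodist.errors.RankDeficiencyWarning`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cleaning import PhaseSpec, split_phase
from .errors import EmptyDatasetError, InvalidArgumentError, RankDeficiencyWarning

__all__ = ["HouseholdGrowthFit", "fit_household_model", "lsmeans_at_week"]


@dataclass
class HouseholdGrowthFit:
    """OLS fit of the common-intercept, household-slope growth model."""

    breed: str
    phase: str
    common_intercept: float
    slope_per_household: dict
    residual_variance: float
    n_obs: int
    design_rank: int
    covariance: np.ndarray          # (1+H) x (1+H), order: intercept then households
    household_order: list
    household_meta: pd.DataFrame    # sex/region/lon/lat per household (first occurrence)

    @property
    def n_households(self) -> int:
        return len(self.household_order)


def fit_household_model(
    records: pd.DataFrame, breed: str, phase: PhaseSpec | str
) -> HouseholdGrowthFit:
    """Fit the household growth model for one breed within one phase.

    ``records`` are cleaned average-weight records; they are subset to the
    breed and to the phase's sex/week window before fitting.  Requires at
    least two observations in the subset.
    """
    if isinstance(phase, str):
        from .cleaning import DEFAULT_PHASES

        phase = DEFAULT_PHASES[phase]  # raises KeyError -> caller's problem
    sub = split_phase(records[records["breed"] == breed], phase)
    if len(sub) < 2:
        raise EmptyDatasetError(
            f"breed {breed!r}, phase {phase.name!r}: need >= 2 observations, have {len(sub)}"
        )

    households = sorted(sub["household_id"].unique())
    h_index = {h: i for i, h in enumerate(households)}
    n, H = len(sub), len(households)

    X = np.zeros((n, 1 + H))
    X[:, 0] = 1.0
    rows = np.arange(n)
    cols = 1 + sub["household_id"].map(h_index).to_numpy()
    X[rows, cols] = sub["week"].to_numpy()
    y = sub["avg_weight_g"].to_numpy(dtype=float)

    rank = int(np.linalg.matrix_rank(X))
    if rank < 1 + H:
        warnings.warn(
            f"household design is rank deficient (rank {rank} < {1 + H}); "
            "using the minimum-norm least-squares solution",
            RankDeficiencyWarning,
            stacklevel=2,
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = max(n - (1 + H), 1)
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.pinv(X.T @ X)

    meta_cols = [c for c in ("sex", "region", "lon", "lat") if c in sub.columns]
    meta = (
        sub.drop_duplicates("household_id")
        .set_index("household_id")[meta_cols]
        .loc[households]
        .reset_index()
    )

    return HouseholdGrowthFit(
        breed=breed,
        phase=phase.name,
        common_intercept=float(beta[0]),
        slope_per_household={h: float(beta[1 + i]) for h, i in h_index.items()},
        residual_variance=sigma2,
        n_obs=n,
        design_rank=rank,
        covariance=cov,
        household_order=households,
        household_meta=meta,
    )


def lsmeans_at_week(fit: HouseholdGrowthFit, eval_week: float) -> pd.DataFrame:
    """Least-squares means (and SEs) for every household at ``eval_week``.

    Returns a DataFrame with columns ``household_id, breed, sex, region,
    lon, lat, phase, eval_week, lsmean_g, se_g`` (meta columns present when
    available in the fitted records).
    """
    if not np.isfinite(eval_week):
        raise InvalidArgumentError("eval_week must be finite")
    w = float(eval_week)

    b0 = fit.common_intercept
    C = fit.covariance
    out_rows = []
    for i, h in enumerate(fit.household_order):
        s = fit.slope_per_household[h]
        j = 1 + i
        var = C[0, 0] + w * w * C[j, j] + 2.0 * w * C[0, j]
        out_rows.append(
            {
                "household_id": h,
                "breed": fit.breed,
                "phase": fit.phase,
                "eval_week": w,
                "lsmean_g": b0 + s * w,
                "se_g": float(np.sqrt(max(var, 0.0))),
            }
        )
    out = pd.DataFrame(out_rows)
    meta = fit.household_meta
    if len(meta.columns) > 1:
        out = out.merge(meta, on="household_id", how="left")
    order = [
        c
        for c in ("household_id", "breed", "sex", "region", "lon", "lat", "phase", "eval_week", "lsmean_g", "se_g")
        if c in out.columns
    ]
    return out[order]
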