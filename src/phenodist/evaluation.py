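"""Prediction-precision reports.

Precision is quantified in-sample: for each region, the Pearson correlation
between the model's predictions at the household covariates and the
household least-squares means.  Following the sample-size rule for
estimating correlations, only regions with strictly more than 25 households
per breed enter the summary; smaller regions are still reported but flagged
as ungated.  The correlation standard error uses the classical large-sample
form

    se_r = (1 - r^2) / sqrt(n - 1)

Regions with fewer than 3 households have no defined correlation and are
reported with a missing r.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .boosting import BoostFit, boost_predict
from .errors import EmptySummaryWarning, InvalidArgumentError
from .stack import EnvStack

__all__ = [
    "CorrelationReport",
    "correlation_se",
    "predicted_vs_lsmeans",
    "summarize_report",
]


def correlation_se(r: float, n: int) -> float:
    """Large-sample standard error of a correlation: (1 - r^2) / sqrt(n - 1)."""
    if n < 2:
        return float("nan")
    return (1.0 - r * r) / np.sqrt(n - 1)


@dataclass
class CorrelationReport:
    """Per-region correlation rows plus a summary over gated rows."""

    table: pd.DataFrame    # breed, sex, phase, region, n, r, se_r, gated
    summary: dict          # median_r, min_r, max_r, n_gated_regions


def predicted_vs_lsmeans(
    fit: BoostFit,
    lsmeans: pd.DataFrame,
    stack: EnvStack,
    gate_n: int = 25,
    method: str = "pearson",
    m: int | None = None,
) -> CorrelationReport:
    """Correlate model predictions with household LSmeans, per region.

    ``lsmeans`` must provide ``household_id, region, lsmean_g`` and either
    grid coordinates (``row``/``col``) or ``lon``/``lat`` so each household
    can be matched to its covariate cell.  A region is gated into the
    summary only when its household count exceeds ``gate_n`` (strictly).
    """
    if method not in ("pearson", "spearman"):
        raise InvalidArgumentError(f"unknown correlation method {method!r}")
    df = lsmeans.copy()
    if "row" not in df.columns or "col" not in df.columns:
        if "lon" not in df.columns or "lat" not in df.columns:
            raise InvalidArgumentError("lsmeans need row/col or lon/lat coordinates")
        cells = [stack.cell_at(lo, la) for lo, la in zip(df["lon"], df["lat"])]
        df["row"] = [rc[0] for rc in cells]
        df["col"] = [rc[1] for rc in cells]

    X = pd.DataFrame(
        {v: stack.layer(v)[df["row"].to_numpy(), df["col"].to_numpy()] for v in fit.var_names}
    )
    df["predicted_g"] = boost_predict(fit, X, m=m)

    rows = []
    for region, grp in df.groupby("region", sort=True):
        n = len(grp)
        if n >= 3:
            if method == "pearson":
                r = float(np.corrcoef(grp["predicted_g"], grp["lsmean_g"])[0, 1])
            else:
                r = float(stats.spearmanr(grp["predicted_g"], grp["lsmean_g"]).statistic)
            se = correlation_se(r, n)
        else:
            r, se = float("nan"), float("nan")
        rows.append(
            {
                "breed": grp["breed"].iloc[0] if "breed" in grp.columns else "",
                "sex": grp["sex"].iloc[0] if "sex" in grp.columns else "",
                "phase": grp["phase"].iloc[0] if "phase" in grp.columns else "",
                "region": region,
                "n": n,
                "r": r,
                "se_r": se,
                "gated": bool(n > gate_n) and np.isfinite(r),
            }
        )
    table = pd.DataFrame(rows)
    return CorrelationReport(table=table, summary=summarize_report(table))


def summarize_report(table: pd.DataFrame) -> dict:
    """Median / min / max of r over gated rows only."""
    gated = table.loc[table["gated"], "r"] if len(table) else pd.Series(dtype=float)
    if len(gated) == 0:
        warnings.warn("no region passed the sample-size gate; summary is empty",
                      EmptySummaryWarning, stacklevel=2)
        return {"median_r": float("nan"), "min_r": float("nan"), "max_r": float("nan"),
                "n_gated_regions": 0}
    return {
        "median_r": float(gated.median()),
        "min_r": float(gated.min()),
        "max_r": float(gated.max()),
        "n_gated_regions": int(len(gated)),
    }
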