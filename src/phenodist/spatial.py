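"""Spatial prediction surfaces with environmental-range masking.

A fitted additive model is evaluated cellwise over the covariate stack to
produce a predicted-weight surface.  Cells whose environment lies outside
the range in which households were actually tested are excluded: a cell is
masked ``out_of_range`` when ANY model covariate at the cell falls strictly
outside the closed interval [training min, training max] of that covariate.
This is the conservative reading of excluding areas (deserts) whose
conditions lie outside the tested environmental range; spline extrapolation
is never trusted on the map.

Per-breed region suitability summarises the unmasked surface within each
region (mean by default; max and median selectable) and reports the region
with the highest summary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd

from .boosting import BoostFit, boost_predict
from .errors import EmptyResultError, InvalidArgumentError, SchemaError, TieWarning
from .stack import EnvStack

__all__ = [
    "MaskReason",
    "PredictionSurface",
    "RegionSuitability",
    "env_range_mask",
    "predict_surface",
    "region_suitability",
    "training_ranges",
]


class MaskReason(IntEnum):
    OK = 0
    NODATA = 1
    OUT_OF_RANGE = 2


def training_ranges(training_X: pd.DataFrame) -> dict[str, tuple[float, float]]:
    """Closed [min, max] per covariate over the model's training rows."""
    return {
        c: (float(training_X[c].min()), float(training_X[c].max()))
        for c in training_X.columns
    }


def env_range_mask(
    stack: EnvStack, training_X: pd.DataFrame | dict[str, tuple[float, float]]
) -> np.ndarray:
    """Mask grid: OK, NODATA, or OUT_OF_RANGE per cell.

    ``training_X`` is either the model's training covariate table or a
    precomputed {var: (min, max)} mapping.  A cell is OUT_OF_RANGE when any
    variable lies strictly outside its closed training interval; values
    exactly at a training extreme are in range.
    """
    ranges = training_X if isinstance(training_X, dict) else training_ranges(training_X)
    missing = [v for v in ranges if v not in stack.var_names]
    if missing:
        raise SchemaError(f"stack is missing model layers {missing}")

    mask = np.full((stack.rows, stack.cols), int(MaskReason.OK), dtype=np.int8)
    out = np.zeros((stack.rows, stack.cols), dtype=bool)
    for v, (lo, hi) in ranges.items():
        layer = stack.layer(v)
        out |= (layer < lo) | (layer > hi)
    mask[out] = int(MaskReason.OUT_OF_RANGE)
    mask[stack.nodata_mask] = int(MaskReason.NODATA)
    return mask


@dataclass
class PredictionSurface:
    """Gridded predicted weight (g); NaN wherever the cell is masked."""

    values: np.ndarray
    mask: np.ndarray           # MaskReason codes
    breed: str = ""
    sex: str = ""
    phase: str = ""
    model_m: int = 0

    def __post_init__(self):
        ok = self.mask == int(MaskReason.OK)
        if np.any(np.isnan(self.values[ok])) or np.any(~np.isnan(self.values[~ok])):
            raise InvalidArgumentError("values must be present exactly on unmasked cells")

    def to_frame(self, stack: EnvStack) -> pd.DataFrame:
        """Long-format table (row, col, lon, lat, region, predicted_g, mask_reason)."""
        rows, cols = np.meshgrid(np.arange(stack.rows), np.arange(stack.cols), indexing="ij")
        lon, lat = stack.lonlat(rows, cols)
        names = stack.region_name_grid()
        return pd.DataFrame(
            {
                "row": rows.ravel(),
                "col": cols.ravel(),
                "lon": lon.ravel(),
                "lat": lat.ravel(),
                "region": names.ravel(),
                "predicted_g": self.values.ravel(),
                "mask_reason": [MaskReason(int(v)).name.lower() for v in self.mask.ravel()],
            }
        )


def predict_surface(
    fit: BoostFit,
    stack: EnvStack,
    mask: np.ndarray,
    m: int | None = None,
    breed: str = "",
    sex: str = "",
    phase: str = "",
) -> PredictionSurface:
    """Evaluate the model on every unmasked cell of the stack."""
    if mask.shape != (stack.rows, stack.cols):
        raise InvalidArgumentError("mask shape must match the stack grid")
    ok = mask == int(MaskReason.OK)
    values = np.full((stack.rows, stack.cols), np.nan)
    if ok.any():
        r, c = np.nonzero(ok)
        X_cells = pd.DataFrame(
            {v: stack.layer(v)[r, c] for v in fit.var_names}
        )
        used_m = fit.m_stop if m is None else m
        values[r, c] = boost_predict(fit, X_cells, m=m)
    else:
        used_m = fit.m_stop if m is None else m
    return PredictionSurface(values=values, mask=mask, breed=breed, sex=sex, phase=phase,
                             model_m=used_m)


@dataclass
class RegionSuitability:
    """Per-region summary of a prediction surface with the best region."""

    breed: str
    sex: str
    phase: str
    statistic: str
    per_region: dict[str, float]
    best_region: str
    tie: bool = False


_STATS = {"mean": np.mean, "median": np.median, "max": np.max}


def region_suitability(
    surface: PredictionSurface, stack: EnvStack, statistic: str = "mean"
) -> RegionSuitability:
    """Summarise predictions per region and pick the best region.

    Regions with no unmasked cell are excluded from the ranking.  Exact ties
    for the best region are broken alphabetically and flagged with a
    :class:`TieWarning`.
    """
    if statistic not in _STATS:
        raise InvalidArgumentError(f"statistic must be one of {sorted(_STATS)}")
    fn = _STATS[statistic]
    ok = surface.mask == int(MaskReason.OK)
    per_region = {}
    for i, name in enumerate(stack.region_names):
        cells = ok & (stack.region_label == i)
        if cells.any():
            per_region[name] = float(fn(surface.values[cells]))
    if not per_region:
        raise EmptyResultError("every cell is masked; no region can be ranked")

    best_val = max(per_region.values())
    winners = sorted([n for n, v in per_region.items() if v == best_val])
    tie = len(winners) > 1
    if tie:
        warnings.warn(
            f"best-region tie between {winners}; choosing {winners[0]!r} (alphabetical)",
            TieWarning, stacklevel=2,
        )
    return RegionSuitability(
        breed=surface.breed,
        sex=surface.sex,
        phase=surface.phase,
        statistic=statistic,
        per_region=per_region,
        best_region=winners[0],
        tie=tie,
    )


def plot_surface(surface: PredictionSurface, stack: EnvStack, households: pd.DataFrame | None = None,
                 path=None):
    """Optional heatmap of a surface with households overplotted as circles."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(surface.values, cmap="viridis")
    fig.colorbar(im, ax=ax, label="predicted weight (g)")
    if households is not None:
        ax.scatter(households["col"], households["row"], s=12, facecolors="none",
                   edgecolors="white", linewidths=0.6)
    ax.set_title(f"{surface.breed} {surface.phase}".strip())
    ax.set_xlabel("col")
    ax.set_ylabel("row")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
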