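"""Record cleaning: group-to-individual conversion, filters, phase handling.

The raw data are group weighings: total weight of ``n_birds`` birds at a
household at a given age in weeks.  Cleaning converts these to average
individual weights, then applies three filters, in this order, with
first-match logging:

1. drop observations with average weight strictly below 50 g;
2. drop *all* records of any household whose maximum reported bird count
   exceeds 30 (households, not single records, are deleted);
3. drop observations at strictly less than 6 weeks of age.

The kept set is the same whatever the filter order (the rules are
independent predicates); only the logged disposition of a doubly-bad record
depends on the order.  Boundaries are strict: exactly 50 g, exactly 30
birds and exactly week 6 are all kept.

Sex-specific age phases (growing weeks 14–19 for both sexes, adult weeks
20–72 for females, both ends inclusive) partition the cleaned data, and
each phase is standardised to its average week of measurement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, EmptyDatasetError, InvalidArgumentError

__all__ = [
    "DEFAULT_PHASES",
    "PhaseSpec",
    "apply_filters",
    "phase_average_week",
    "split_phase",
    "to_average_weight",
]

KEPT = "kept"
REMOVED_UNDER50 = "removed_under50"
REMOVED_OVER30 = "removed_over30birds"
REMOVED_UNDER6WK = "removed_under6wk"
DISPOSITIONS = (KEPT, REMOVED_UNDER50, REMOVED_OVER30, REMOVED_UNDER6WK)


@dataclass(frozen=True)
class PhaseSpec:
    """A sex-specific age phase with inclusive week bounds."""

    name: str
    sex: str
    week_lo: float
    week_hi: float

    def __post_init__(self):
        if not (6 <= self.week_lo <= self.week_hi):
            raise ConfigurationError("phase must satisfy 6 <= week_lo <= week_hi")
        if self.sex not in ("male", "female"):
            raise ConfigurationError(f"unknown sex {self.sex!r}")


DEFAULT_PHASES: dict[str, PhaseSpec] = {
    "male_growing": PhaseSpec("male_growing", "male", 14, 19),
    "female_growing": PhaseSpec("female_growing", "female", 14, 19),
    "female_adult": PhaseSpec("female_adult", "female", 20, 72),
}


def to_average_weight(records: pd.DataFrame) -> pd.DataFrame:
    """Add ``avg_weight_g = group_weight_g / n_birds`` (exact division).

    Raises :class:`DataError` if any record has ``n_birds < 1`` or a
    non-positive group weight.
    """
    if (records["n_birds"] < 1).any():
        bad = records.loc[records["n_birds"] < 1, "record_id"].tolist()
        raise DataError(f"records with n_birds < 1: {bad}")
    if (records["group_weight_g"] <= 0).any():
        bad = records.loc[records["group_weight_g"] <= 0, "record_id"].tolist()
        raise DataError(f"records with non-positive group weight: {bad}")
    out = records.copy()
    out["avg_weight_g"] = out["group_weight_g"] / out["n_birds"]
    return out


def apply_filters(
    records: pd.DataFrame,
    bird_counts: pd.Series | None = None,
    min_weight_g: float = 50.0,
    max_birds: int = 30,
    min_week: float = 6.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the three cleaning filters; return (kept records, removal log).

    ``bird_counts`` optionally overrides the per-household maximum reported
    bird count (by default computed from ``records`` itself).  The removal
    log has one row per input record with columns ``record_id`` and
    ``disposition``; dispositions partition the input and use first-match
    attribution in the order under-50 g, over-30-birds, under-6-weeks.
    Input order is preserved in both outputs.
    """
    if len(records) == 0:
        log = pd.DataFrame({"record_id": [], "disposition": []})
        return records.copy(), log

    if bird_counts is None:
        bird_counts = records.groupby("household_id")["n_birds"].max()
    over30_households = set(bird_counts.index[bird_counts > max_birds])

    avg = records["avg_weight_g"].to_numpy()
    week = records["week"].to_numpy()
    in_over30 = records["household_id"].isin(over30_households).to_numpy()

    disposition = np.full(len(records), KEPT, dtype=object)
    remaining = np.ones(len(records), dtype=bool)
    for mask, label in (
        (avg < min_weight_g, REMOVED_UNDER50),
        (in_over30, REMOVED_OVER30),
        (week < min_week, REMOVED_UNDER6WK),
    ):
        hit = remaining & mask
        disposition[hit] = label
        remaining &= ~mask

    kept = records.loc[remaining].copy()
    log = pd.DataFrame({"record_id": records["record_id"].to_numpy(), "disposition": disposition})
    return kept, log


def split_phase(records: pd.DataFrame, phase: PhaseSpec | str) -> pd.DataFrame:
    """Keep records of the phase's sex with week_lo <= week <= week_hi."""
    if isinstance(phase, str):
        try:
            phase = DEFAULT_PHASES[phase]
        except KeyError:
            raise ConfigurationError(f"unknown phase name {phase!r}") from None
    mask = (
        (records["sex"] == phase.sex)
        & (records["week"] >= phase.week_lo)
        & (records["week"] <= phase.week_hi)
    )
    return records.loc[mask].copy()


def phase_average_week(records: pd.DataFrame) -> float:
    """Arithmetic mean week over every record of a phase (all breeds pooled)."""
    if len(records) == 0:
        raise EmptyDatasetError("cannot average weeks of an empty phase dataset")
    week = records["week"]
    if not np.all(np.isfinite(week)):
        raise InvalidArgumentError("weeks must be finite")
    return float(week.mean())
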