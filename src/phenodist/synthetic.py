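"""Synthetic study generator.

Emulates the statistical structure of an on-farm chicken breed-testing
program: georeferenced smallholder households scattered over a gridded
landscape, one breed tested per household, biweekly group weighings of the
birds, and a gridded stack of environmental covariates (19 bioclimatic
variables, elevation and cultivated-land fraction) that drives part of the
between-household variation in growth.

The generator provides ground truth for every downstream stage: a hidden
truth log records which records were deliberately contaminated (so the
cleaning filters can be audited exactly) and each household's true growth
line (so least-squares means and boosted-model recovery can be checked
against truth).

Growth model
------------
Birds share a common hatch weight (the intercept, in grams at week 0) and
differ in growth rate.  The environment and an unstructured household effect
act on the growth rate:

    mu_hw = intercept + rate_h * w
    rate_h = slope_mean + N(0, slope_sd) + (sum_j f_j(x_hj) + b_h) / ref_week

so that at the reference week the environmental contribution to expected
weight is exactly ``sum_j f_j(x_hj) + b_h`` grams.  Tying the household and
environmental effects to the rate (rather than to a week-0 offset) keeps the
common-hatch-weight assumption of the downstream household model true in the
generator, which makes noise-free recovery exact.

A group weighing of n birds at week w reports ``n * (mu_hw + eps)`` with
``eps ~ N(0, residual_sd)`` on the mean individual weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .errors import ConfigurationError, InvalidArgumentError
from .stack import EnvStack

__all__ = [
    "BIOCLIM_VARIABLES",
    "Contamination",
    "TrueSurfaceSpec",
    "TruthLog",
    "default_surface_spec",
    "gen_env_stack",
    "gen_households",
    "gen_weight_records",
]

#: The 21 canonical environmental layers: 19 bioclimatic summaries, elevation
#: and the fraction of cultivated land, each with a plausible value range used
#: to rescale the simulated random fields (temperatures in deg C, temperature
#: seasonality in sd*100, precipitation in mm, elevation in m, cultivated
#: land in percent).
BIOCLIM_VARIABLES: list[tuple[str, float, float]] = [
    ("annual_mean_temp", 10.0, 28.0),
    ("mean_diurnal_range", 8.0, 18.0),
    ("isothermality", 60.0, 90.0),
    ("temp_seasonality", 50.0, 250.0),
    ("max_temp_warmest_month", 18.0, 40.0),
    ("min_temp_coldest_month", 0.0, 18.0),
    ("temp_annual_range", 12.0, 30.0),
    ("mean_temp_wettest_quarter", 10.0, 28.0),
    ("mean_temp_driest_quarter", 8.0, 30.0),
    ("mean_temp_warmest_quarter", 12.0, 32.0),
    ("mean_temp_coldest_quarter", 6.0, 26.0),
    ("annual_precip", 150.0, 2000.0),
    ("precip_wettest_month", 50.0, 400.0),
    ("precip_driest_month", 0.0, 40.0),
    ("precip_seasonality", 40.0, 140.0),
    ("precip_wettest_quarter", 120.0, 900.0),
    ("precip_driest_quarter", 0.0, 120.0),
    ("precip_warmest_quarter", 20.0, 500.0),
    ("precip_coldest_quarter", 10.0, 600.0),
    ("elevation", 300.0, 3500.0),
    ("cultivated_land_frac", 0.0, 100.0),
]

DESERT_REGION = "desert"


def _variable_table(n_vars: int) -> list[tuple[str, float, float]]:
    table = list(BIOCLIM_VARIABLES[:n_vars])
    for i in range(len(table), n_vars):
        table.append((f"var_{i:02d}", 0.0, 1.0))
    return table


def gen_env_stack(
    rows: int,
    cols: int,
    n_vars: int = 21,
    n_regions: int = 5,
    smoothness: float = 3.0,
    seed: int = 0,
    desert_region: bool = True,
    nodata_fraction: float = 0.0,
) -> EnvStack:
    """Generate a stack of spatially smooth covariate layers with regions.

    Each layer is white noise convolved with an isotropic Gaussian kernel of
    scale ``smoothness`` (cells), then affinely rescaled to a per-variable
    plausible range.  Regions are contiguous vertical strips of near-equal
    width.  When ``desert_region`` is true the last strip is named
    ``"desert"`` and its first layer is shifted so that its minimum exceeds
    the maximum of that layer over every other region — i.e. its
    environmental conditions lie outside the range in which households can
    be placed, which downstream range-masking must detect.
    """
    if rows < 4 or cols < 4:
        raise InvalidArgumentError("rows and cols must be >= 4")
    if n_vars < 1:
        raise InvalidArgumentError("n_vars must be >= 1")
    if smoothness <= 0:
        raise InvalidArgumentError("smoothness must be > 0")
    if not (1 <= n_regions <= cols):
        raise InvalidArgumentError("n_regions must be between 1 and cols")

    rng = np.random.default_rng(seed)
    table = _variable_table(n_vars)
    values = np.empty((rows, cols, n_vars))
    for j, (_, lo, hi) in enumerate(table):
        f = gaussian_filter(rng.standard_normal((rows, cols)), sigma=smoothness, mode="reflect")
        fmin, fmax = f.min(), f.max()
        span = fmax - fmin
        if span == 0:  # pathological but possible at extreme smoothness
            values[:, :, j] = 0.5 * (lo + hi)
        else:
            values[:, :, j] = lo + (f - fmin) / span * (hi - lo)

    # Vertical strips of near-equal width; the last strip is the desert.
    edges = np.linspace(0, cols, n_regions + 1).round().astype(int)
    region_label = np.zeros((rows, cols), dtype=np.int64)
    for r in range(n_regions):
        region_label[:, edges[r]:edges[r + 1]] = r
    region_names = [f"region_{r + 1}" for r in range(n_regions)]
    if desert_region and n_regions >= 2:
        region_names[-1] = DESERT_REGION
        desert = region_label == n_regions - 1
        layer0 = values[:, :, 0]
        other_max = layer0[~desert].max()
        span0 = layer0.max() - layer0.min()
        shift = (other_max - layer0[desert].min()) + 0.25 * max(span0, 1.0)
        layer0[desert] += shift

    nodata = np.zeros((rows, cols), dtype=bool)
    if nodata_fraction > 0:
        nodata = rng.random((rows, cols)) < nodata_fraction

    return EnvStack(
        values=values,
        var_names=[name for name, _, _ in table],
        region_label=region_label,
        region_names=region_names,
        nodata_mask=nodata,
    )


def gen_households(
    stack: EnvStack, n_households: int, breeds: list[str], seed: int = 0
) -> pd.DataFrame:
    """Place households uniformly on eligible cells and assign breeds.

    Eligible cells are non-nodata and outside the desert region.  Breeds are
    assigned round-robin after a seeded shuffle of the household order, so
    per-breed counts differ by at most one and each household tests exactly
    one breed.

    Returns a DataFrame with columns
    ``household_id, breed, row, col, region, lon, lat``.
    """
    if n_households < 1:
        raise InvalidArgumentError("n_households must be >= 1")
    if not breeds:
        raise InvalidArgumentError("breeds must be nonempty")

    eligible = ~stack.nodata_mask
    if DESERT_REGION in stack.region_names:
        eligible &= stack.region_label != stack.region_names.index(DESERT_REGION)
    cells = np.argwhere(eligible)
    if len(cells) == 0:
        raise ConfigurationError("no eligible (non-desert, non-nodata) cells to place households on")

    rng = np.random.default_rng(seed)
    picks = cells[rng.integers(0, len(cells), size=n_households)]
    order = rng.permutation(n_households)
    breed_col = np.empty(n_households, dtype=object)
    for k, h in enumerate(order):
        breed_col[h] = breeds[k % len(breeds)]

    rows_, cols_ = picks[:, 0], picks[:, 1]
    lon, lat = stack.lonlat(rows_, cols_)
    names = np.asarray(stack.region_names, dtype=object)
    return pd.DataFrame(
        {
            "household_id": [f"H{i + 1:04d}" for i in range(n_households)],
            "breed": breed_col,
            "row": rows_,
            "col": cols_,
            "region": names[stack.region_label[rows_, cols_]],
            "lon": lon,
            "lat": lat,
        }
    )


@dataclass
class TrueSurfaceSpec:
    """Ground-truth additive response surface for the generator.

    ``component_functions`` maps each active variable name to a smooth scalar
    function of the raw covariate value, returning grams of expected-weight
    effect at the reference week.  All standard deviations are in grams
    except ``slope_sd`` (grams/week).
    """

    active_vars: list[str]
    component_functions: dict
    intercept: float = 40.0
    household_sd: float = 40.0
    residual_sd: float = 30.0
    slope_mean: float = 58.0
    slope_sd: float = 2.0
    ref_week: float = 16.5

    def __post_init__(self):
        if not self.active_vars:
            raise InvalidArgumentError("active_vars must be nonempty")
        missing = [v for v in self.active_vars if v not in self.component_functions]
        if missing:
            raise InvalidArgumentError(f"no component function for {missing}")
        for name in ("household_sd", "residual_sd", "slope_sd"):
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"{name} must be >= 0")
        if self.ref_week <= 0:
            raise InvalidArgumentError("ref_week must be > 0")

    def env_effect(self, stack: EnvStack, row, col) -> float:
        """Total environmental effect (grams at ref_week) at one cell."""
        total = 0.0
        for v in self.active_vars:
            total += self.component_functions[v](stack.layer(v)[row, col])
        return total


def default_surface_spec(
    stack: EnvStack,
    active_vars: tuple[str, ...] = ("annual_mean_temp", "annual_precip", "elevation"),
    amplitudes: tuple[float, ...] = (120.0, 90.0, 70.0),
    **kwargs,
) -> TrueSurfaceSpec:
    """Three distinct smooth effects scaled to the stack's covariate ranges.

    The covariate is normalised to z in [0, 1] over the stack's non-desert
    range; the effects are a sine, a centred quadratic, and a smoothstep
    ramp, with amplitudes in grams at the reference week.
    """
    missing = [v for v in active_vars if v not in stack.var_names]
    if missing:
        raise InvalidArgumentError(f"active vars not in stack: {missing}")
    if len(amplitudes) != len(active_vars):
        raise InvalidArgumentError("one amplitude per active variable required")

    non_desert = ~stack.nodata_mask
    if DESERT_REGION in stack.region_names:
        non_desert &= stack.region_label != stack.region_names.index(DESERT_REGION)

    shapes = [
        lambda z: np.sin(2.0 * np.pi * z),
        lambda z: (z - 0.5) ** 2 * 4.0 - 1.0,
        lambda z: 3.0 * z**2 - 2.0 * z**3 - 0.5,
    ]

    funcs = {}
    for k, (v, amp) in enumerate(zip(active_vars, amplitudes)):
        layer = stack.layer(v)[non_desert]
        lo, hi = float(layer.min()), float(layer.max())
        span = hi - lo if hi > lo else 1.0
        shape = shapes[k % len(shapes)]

        def f(x, lo=lo, span=span, amp=amp, shape=shape):
            return amp * shape((x - lo) / span)

        funcs[v] = f
    return TrueSurfaceSpec(active_vars=list(active_vars), component_functions=funcs, **kwargs)


@dataclass
class Contamination:
    """How many contaminated entries to inject, per contamination class."""

    under50: int = 0
    over30_households: int = 0
    under6wk: int = 0

    @property
    def any(self) -> bool:
        return self.under50 > 0 or self.over30_households > 0 or self.under6wk > 0


@dataclass
class TruthLog:
    """Hidden ground truth for a generated record set.

    ``record_classes`` maps every record_id to one of ``ok``, ``under50``,
    ``over30_household`` or ``under6wk``; ``household_truth`` carries each
    household's true growth line (``rate`` in g/week through the common
    ``intercept``), its environmental effect and household deviation in grams
    at the reference week.
    """

    record_classes: pd.DataFrame
    household_truth: pd.DataFrame
    ref_week: float
    intercept: float

    def true_mean_weight(self, household_id, week) -> np.ndarray:
        """True expected individual weight (g) for households at a given week."""
        rates = self.household_truth.set_index("household_id")["rate"]
        return self.intercept + rates.loc[household_id].to_numpy() * np.asarray(week)


DEFAULT_PHASE_WEEKS = {
    "male": tuple(range(6, 21, 2)),
    "female": tuple(range(6, 73, 2)),
}


def gen_weight_records(
    households: pd.DataFrame,
    stack: EnvStack,
    spec: TrueSurfaceSpec,
    phase_weeks: dict | None = None,
    group_size_range: tuple[int, int] = (3, 25),
    contamination: Contamination | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, TruthLog]:
    """Generate biweekly group-weight records for every household.

    ``phase_weeks`` maps sex to the weeks at which clean group weighings
    happen (all >= 6); the default mimics males weighed to week 20 and
    females to week 72, every two weeks from delivery at week 6.  Group sizes
    are drawn uniformly from ``group_size_range`` (default 3–25, a flock of
    about 25 delivered chicks with attrition).

    When contamination is requested, the generator injects (i) records whose
    implied average weight is below 50 g, (ii) households with a weighing of
    more than 30 birds, and (iii) records at under 6 weeks of age, in the
    configured counts, each flagged in the returned :class:`TruthLog`.
    """
    if households is None or len(households) == 0:
        raise InvalidArgumentError("households must be a nonempty DataFrame")
    weeks_by_sex = dict(DEFAULT_PHASE_WEEKS if phase_weeks is None else phase_weeks)
    for sex, wk in weeks_by_sex.items():
        if any(w < 6 for w in wk):
            raise InvalidArgumentError(f"clean record weeks must be >= 6 (sex={sex})")
    lo, hi = group_size_range
    if not (1 <= lo <= hi):
        raise InvalidArgumentError("group_size_range must satisfy 1 <= lo <= hi")
    contamination = contamination or Contamination()

    rng = np.random.default_rng(seed)
    n_house = len(households)

    env = np.array(
        [spec.env_effect(stack, r, c) for r, c in zip(households["row"], households["col"])]
    )
    b = rng.normal(0.0, spec.household_sd, n_house)
    sdev = rng.normal(0.0, spec.slope_sd, n_house)
    rate = spec.slope_mean + sdev + (env + b) / spec.ref_week

    rows = []
    classes = []

    def emit(hh, week, avg, n_birds, cls):
        rows.append(
            {
                "record_id": f"R{len(rows) + 1:06d}",
                "household_id": hh["household_id"],
                "breed": hh["breed"],
                "sex": hh["_sex"],
                "region": hh["region"],
                "lon": hh["lon"],
                "lat": hh["lat"],
                "week": float(week),
                "group_weight_g": float(n_birds * avg),
                "n_birds": int(n_birds),
            }
        )
        classes.append(cls)

    house_rows = households.to_dict("records")
    for i, hh in enumerate(house_rows):
        for sex, weeks in weeks_by_sex.items():
            hh["_sex"] = sex
            for w in weeks:
                n_birds = int(rng.integers(lo, hi + 1))
                eps = rng.normal(0.0, spec.residual_sd) if spec.residual_sd > 0 else 0.0
                avg = spec.intercept + rate[i] * w + eps
                emit(hh, w, avg, n_birds, "ok")

    if contamination.any:
        _inject_contamination(
            rows, classes, house_rows, rate, spec, weeks_by_sex, (lo, hi), contamination, rng
        )

    records = pd.DataFrame(rows)
    truth = TruthLog(
        record_classes=pd.DataFrame(
            {"record_id": records["record_id"], "contamination": classes}
        ),
        household_truth=pd.DataFrame(
            {
                "household_id": households["household_id"],
                "breed": households["breed"],
                "region": households["region"],
                "row": households["row"],
                "col": households["col"],
                "env_effect": env,
                "household_effect": b,
                "rate": rate,
            }
        ),
        ref_week=spec.ref_week,
        intercept=spec.intercept,
    )
    return records, truth


def _inject_contamination(rows, classes, house_rows, rate, spec, weeks_by_sex, size_range, cont, rng):
    """Inject the three contamination classes on disjoint household sets."""
    n_house = len(house_rows)
    needed = cont.over30_households + min(1, cont.under50) + min(1, cont.under6wk)
    if cont.over30_households >= n_house:
        raise InvalidArgumentError("over30_households must leave at least one clean household")
    del needed

    over30 = set(rng.choice(n_house, size=cont.over30_households, replace=False)) if cont.over30_households else set()
    clean_pool = [i for i in range(n_house) if i not in over30]
    lo, hi = size_range

    # (ii) households reporting more than 30 birds: bump one existing record.
    over30_ids = {house_rows[i]["household_id"] for i in over30}
    for i in over30:
        hid = house_rows[i]["household_id"]
        candidates = [k for k, r in enumerate(rows) if r["household_id"] == hid]
        k = candidates[int(rng.integers(0, len(candidates)))]
        avg = rows[k]["group_weight_g"] / rows[k]["n_birds"]
        n_new = int(rng.integers(31, 41))
        rows[k]["n_birds"] = n_new
        rows[k]["group_weight_g"] = float(n_new * avg)
    # every record of an over-30 household is (to the filters) contaminated
    for k, r in enumerate(rows):
        if r["household_id"] in over30_ids:
            classes[k] = "over30_household"

    def emit_extra(i, week, avg, cls):
        hh = dict(house_rows[i])
        sex = "female" if "female" in weeks_by_sex else next(iter(weeks_by_sex))
        hh["_sex"] = sex
        n_birds = int(rng.integers(lo, min(hi, 30) + 1))
        rows.append(
            {
                "record_id": f"R{len(rows) + 1:06d}",
                "household_id": hh["household_id"],
                "breed": hh["breed"],
                "sex": sex,
                "region": hh["region"],
                "lon": hh["lon"],
                "lat": hh["lat"],
                "week": float(week),
                "group_weight_g": float(n_birds * avg),
                "n_birds": n_birds,
            }
        )
        classes.append(cls)

    # (i) implied average weight below 50 g at a valid age.
    for _ in range(cont.under50):
        i = clean_pool[int(rng.integers(0, len(clean_pool)))]
        weeks = weeks_by_sex["female" if "female" in weeks_by_sex else next(iter(weeks_by_sex))]
        week = weeks[int(rng.integers(0, len(weeks)))]
        emit_extra(i, week, float(rng.uniform(5.0, 49.0)), "under50")

    # (iii) records before 6 weeks of age, with a plausible (>= 50 g) weight.
    for _ in range(cont.under6wk):
        i = clean_pool[int(rng.integers(0, len(clean_pool)))]
        week = float(rng.integers(2, 6))
        avg = max(60.0, spec.intercept + rate[i] * week)
        emit_extra(i, week, avg, "under6wk")
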