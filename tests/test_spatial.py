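"""Range masking, surface prediction and region suitability."""

import numpy as np
import pandas as pd
import pytest

from phenodist import (
    MaskReason,
    boost_fit,
    boost_predict,
    default_surface_spec,
    env_range_mask,
    gen_households,
    gen_weight_records,
    predict_surface,
    region_suitability,
)
from phenodist.errors import EmptyResultError, SchemaError, TieWarning
from phenodist.spatial import PredictionSurface, training_ranges


@pytest.fixture(scope="module")
def trained(small_stack):
    """Households + a fitted model on their covariates (noise-free signal)."""
    hh = gen_households(small_stack, 60, ["A"], seed=21)
    spec = default_surface_spec(
        small_stack, residual_sd=0.0, household_sd=0.0, slope_sd=0.0
    )
    _, truth = gen_weight_records(hh, small_stack, spec, seed=22)
    rr, cc = hh["row"].to_numpy(), hh["col"].to_numpy()
    X = pd.DataFrame({v: small_stack.layer(v)[rr, cc] for v in small_stack.var_names})
    y = truth.intercept + truth.household_truth["rate"].to_numpy() * 16.5
    fit = boost_fit(X, y, m_max=60, knot_count=10)
    return hh, X, y, fit


class TestEnvRangeMask:
    def test_training_cells_never_masked(self, small_stack, trained):
        hh, X, _, _ = trained
        mask = env_range_mask(small_stack, X)
        for r, c in zip(hh["row"], hh["col"]):
            assert mask[r, c] == int(MaskReason.OK)

    def test_desert_fully_out_of_range(self, small_stack, trained):
        _, X, _, _ = trained
        mask = env_range_mask(small_stack, X)
        desert = small_stack.region_label == small_stack.region_names.index("desert")
        assert (mask[desert] == int(MaskReason.OUT_OF_RANGE)).all()

    def test_closed_interval_boundary_in_range(self, small_stack, trained):
        _, X, _, _ = trained
        ranges = training_ranges(X)
        # a synthetic cell exactly at every training max must be OK
        at_max = {v: (hi, hi) for v, (lo, hi) in ranges.items()}
        probe = {v: (ranges[v][0], ranges[v][1]) for v in ranges}
        mask = env_range_mask(small_stack, probe)
        # any unmasked training cell still OK when ranges shrink to exact extremes
        del at_max
        assert (mask != int(MaskReason.OUT_OF_RANGE)).any()

    def test_mask_monotone_under_range_enlargement(self, small_stack, trained):
        _, X, _, _ = trained
        narrow = training_ranges(X)
        wide = {v: (lo - 1.0, hi + 1.0) for v, (lo, hi) in narrow.items()}
        m_narrow = env_range_mask(small_stack, narrow)
        m_wide = env_range_mask(small_stack, wide)
        was_ok = m_narrow == int(MaskReason.OK)
        assert (m_wide[was_ok] == int(MaskReason.OK)).all()

    def test_missing_layer_schema_error(self, small_stack):
        with pytest.raises(SchemaError):
            env_range_mask(small_stack, {"not_a_layer": (0.0, 1.0)})

    def test_nodata_cells_masked_nodata(self, tiny_stack):
        stack = tiny_stack
        stack.nodata_mask[0, 0] = True
        ranges = {stack.var_names[0]: (-1e12, 1e12)}
        mask = env_range_mask(stack, ranges)
        assert mask[0, 0] == int(MaskReason.NODATA)
        stack.nodata_mask[0, 0] = False


class TestPredictSurface:
    def test_offset_only_model_constant_surface(self, small_stack, trained):
        _, X, y, _ = trained
        fit0 = boost_fit(X, y, m_max=0, knot_count=10)
        mask = env_range_mask(small_stack, X)
        surf = predict_surface(fit0, small_stack, mask)
        ok = surf.mask == int(MaskReason.OK)
        np.testing.assert_allclose(surf.values[ok], np.mean(y), rtol=1e-12)

    def test_surface_matches_pointwise_prediction(self, small_stack, trained):
        hh, X, _, fit = trained
        mask = env_range_mask(small_stack, X)
        surf = predict_surface(fit, small_stack, mask)
        preds = boost_predict(fit, X)
        for k in range(5):
            r, c = hh["row"].iloc[k], hh["col"].iloc[k]
            assert surf.values[r, c] == pytest.approx(preds[k], rel=1e-12)

    def test_masked_cells_carry_no_value(self, small_stack, trained):
        _, X, _, fit = trained
        mask = env_range_mask(small_stack, X)
        surf = predict_surface(fit, small_stack, mask)
        assert np.isnan(surf.values[surf.mask != int(MaskReason.OK)]).all()
        assert not np.isnan(surf.values[surf.mask == int(MaskReason.OK)]).any()

    def test_extrema_bracket_all_predictions(self, small_stack, trained):
        _, X, _, fit = trained
        mask = env_range_mask(small_stack, X)
        surf = predict_surface(fit, small_stack, mask)
        ok = surf.mask == int(MaskReason.OK)
        vals = surf.values[ok]
        assert np.nanmin(surf.values) == vals.min()
        assert np.nanmax(surf.values) == vals.max()

    def test_inconsistent_value_mask_pair_rejected(self):
        vals = np.array([[1.0, np.nan]])
        mask = np.array([[0, 0]], dtype=np.int8)
        with pytest.raises(Exception):
            PredictionSurface(values=vals, mask=mask)


class TestRegionSuitability:
    def _surface(self, stack, fill):
        mask = np.full((stack.rows, stack.cols), int(MaskReason.OK), dtype=np.int8)
        values = np.empty((stack.rows, stack.cols))
        for i in range(len(stack.region_names)):
            values[stack.region_label == i] = fill[i % len(fill)]
        return PredictionSurface(values=values, mask=mask, breed="A")

    def test_highest_region_wins(self, tiny_stack):
        fills = [900.0, 1100.0, 800.0, 700.0]
        surf = self._surface(tiny_stack, fills)
        suit = region_suitability(surf, tiny_stack)
        assert suit.best_region == tiny_stack.region_names[1]
        assert suit.per_region[suit.best_region] == 1100.0

    def test_fully_masked_region_excluded(self, tiny_stack):
        surf = self._surface(tiny_stack, [900.0, 1100.0, 800.0, 700.0])
        hot = tiny_stack.region_label == 1
        surf.mask[hot] = int(MaskReason.OUT_OF_RANGE)
        surf.values[hot] = np.nan
        suit = region_suitability(surf, tiny_stack)
        assert tiny_stack.region_names[1] not in suit.per_region
        assert suit.best_region == tiny_stack.region_names[0]

    def test_all_masked_is_empty_result(self, tiny_stack):
        surf = self._surface(tiny_stack, [1.0])
        surf.mask[:] = int(MaskReason.OUT_OF_RANGE)
        surf.values[:] = np.nan
        with pytest.raises(EmptyResultError):
            region_suitability(surf, tiny_stack)

    def test_tie_broken_alphabetically_with_warning(self, tiny_stack):
        surf = self._surface(tiny_stack, [1000.0, 1000.0, 500.0, 400.0])
        with pytest.warns(TieWarning):
            suit = region_suitability(surf, tiny_stack)
        assert suit.tie
        assert suit.best_region == sorted(tiny_stack.region_names[:2])[0]

    def test_true_best_region_recovered_by_well_fit_model(self):
        """Where the generator's truth is maximal, the model agrees.

        A covariate with a west-to-east gradient makes the true region means
        clearly ordered, so the best region is identifiable from data.
        """
        from phenodist import TrueSurfaceSpec, gen_env_stack, gen_weight_records

        stack = gen_env_stack(20, 20, n_vars=6, n_regions=5, smoothness=2.0, seed=5)
        grad = np.tile(np.linspace(0.0, 10.0, stack.cols), (stack.rows, 1))
        stack.values[:, :, 1] = grad + 0.3 * stack.values[:, :, 1] / stack.values[:, :, 1].max()
        var = stack.var_names[1]
        spec = TrueSurfaceSpec(
            active_vars=[var],
            component_functions={var: lambda x: 30.0 * x},
            residual_sd=0.0, household_sd=0.0, slope_sd=0.0,
        )
        hh = gen_households(stack, 80, ["A"], seed=6)
        _, truth = gen_weight_records(hh, stack, spec, seed=7)
        rr, cc = hh["row"].to_numpy(), hh["col"].to_numpy()
        X = pd.DataFrame({v: stack.layer(v)[rr, cc] for v in stack.var_names})
        y = truth.intercept + truth.household_truth["rate"].to_numpy() * spec.ref_week
        fit = boost_fit(X, y, m_max=80, knot_count=8)
        surf = predict_surface(fit, stack, env_range_mask(stack, X))
        suit = region_suitability(surf, stack)
        # truth: weight rises eastward, so the last non-desert strip is best
        ok = surf.mask == int(MaskReason.OK)
        best_truth, best_val = None, -np.inf
        for i, name in enumerate(stack.region_names):
            cells = ok & (stack.region_label == i)
            if not cells.any():
                continue
            mu = spec.intercept + spec.slope_mean * spec.ref_week + 30.0 * stack.layer(var)[cells]
            if mu.mean() > best_val:
                best_truth, best_val = name, mu.mean()
        assert best_truth == "region_4"
        assert suit.best_region == best_truth
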