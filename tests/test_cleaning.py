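"""Group-to-average conversion, the three filters, phases, average weeks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenodist import (
    apply_filters,
    default_surface_spec,
    gen_weight_records,
    phase_average_week,
    split_phase,
    to_average_weight,
)
from phenodist.cleaning import DISPOSITIONS, KEPT, PhaseSpec
from phenodist.errors import ConfigurationError, DataError, EmptyDatasetError

from conftest import make_avg_records


class TestToAverageWeight:
    @pytest.mark.parametrize(
        "group, n, expected",
        [(5000.0, 5, 1000.0), (49.0, 1, 49.0), (1033.5, 3, 344.5)],
    )
    def test_exact_division(self, group, n, expected):
        df = pd.DataFrame(
            {"record_id": ["R1"], "group_weight_g": [group], "n_birds": [n]}
        )
        out = to_average_weight(df)
        assert out["avg_weight_g"].iloc[0] == expected

    def test_zero_birds_rejected(self):
        df = pd.DataFrame({"record_id": ["R1"], "group_weight_g": [100.0], "n_birds": [0]})
        with pytest.raises(DataError):
            to_average_weight(df)


class TestApplyFilters:
    def test_under50_boundary_strict(self):
        df = make_avg_records(
            [
                {"group_weight_g": 45.0, "n_birds": 1},
                {"group_weight_g": 50.0, "n_birds": 1},
                {"group_weight_g": 1200.0, "n_birds": 1},
            ]
        )
        kept, log = apply_filters(df)
        assert kept["avg_weight_g"].tolist() == [50.0, 1200.0]
        assert log["disposition"].tolist() == ["removed_under50", "kept", "kept"]

    def test_over30_birds_removes_whole_household(self):
        df = make_avg_records(
            [
                {"household_id": "H1", "n_birds": 31, "group_weight_g": 31 * 500.0},
                {"household_id": "H1", "n_birds": 10, "group_weight_g": 5000.0},
                {"household_id": "H2", "n_birds": 30, "group_weight_g": 15000.0},
            ]
        )
        kept, log = apply_filters(df)
        assert kept["household_id"].tolist() == ["H2"]  # exactly 30 birds is kept
        assert log["disposition"].tolist() == [
            "removed_over30birds",
            "removed_over30birds",
            "kept",
        ]

    def test_week_boundary_strict(self):
        df = make_avg_records([{"week": 5.9}, {"week": 6.0}])
        kept, log = apply_filters(df)
        assert kept["week"].tolist() == [6.0]
        assert log["disposition"].tolist() == ["removed_under6wk", "kept"]

    def test_dispositions_partition_input(self):
        df = make_avg_records(
            [
                {"group_weight_g": 40.0, "n_birds": 1, "week": 4.0},  # doubly bad
                {"household_id": "H9", "n_birds": 35, "group_weight_g": 35 * 400.0},
                {"week": 20.0},
            ]
        )
        kept, log = apply_filters(df)
        assert len(log) == len(df)
        assert set(log["disposition"]).issubset(DISPOSITIONS)
        assert (log["disposition"] == KEPT).sum() == len(kept)
        # first-match: the doubly-bad record is attributed to the under-50 rule
        assert log["disposition"].iloc[0] == "removed_under50"

    def test_filters_idempotent(self):
        df = make_avg_records(
            [{"group_weight_g": 30.0, "n_birds": 1}, {"week": 3.0}, {"week": 10.0}]
        )
        kept1, _ = apply_filters(df)
        kept2, log2 = apply_filters(kept1)
        pd.testing.assert_frame_equal(kept1, kept2)
        assert (log2["disposition"] == KEPT).all()

    def test_kept_set_invariant_to_rule_order(self):
        # rules are independent predicates: the kept set from first-match
        # filtering equals the intersection of the three individual keeps
        df = make_avg_records(
            [
                {"group_weight_g": 40.0, "n_birds": 1, "week": 4.0},
                {"household_id": "HX", "n_birds": 32, "group_weight_g": 32 * 40.0},
                {"week": 5.0},
                {"week": 12.0},
                {"group_weight_g": 250.0, "n_birds": 5},
            ]
        )
        kept, _ = apply_filters(df)
        counts = df.groupby("household_id")["n_birds"].max()
        manual = df[
            (df["avg_weight_g"] >= 50)
            & (~df["household_id"].isin(counts.index[counts > 30]))
            & (df["week"] >= 6)
        ]
        assert kept["record_id"].tolist() == manual["record_id"].tolist()

    def test_empty_input_gives_empty_output(self):
        df = make_avg_records([]).iloc[0:0] if False else pd.DataFrame(
            columns=["record_id", "household_id", "n_birds", "week", "avg_weight_g"]
        )
        kept, log = apply_filters(df)
        assert len(kept) == 0 and len(log) == 0

    def test_removals_match_generator_truth_log(self, small_stack, households):
        from phenodist import Contamination

        spec = default_surface_spec(small_stack)
        cont = Contamination(under50=6, over30_households=3, under6wk=5)
        records, truth = gen_weight_records(
            households, small_stack, spec, contamination=cont, seed=12
        )
        avg = to_average_weight(records)
        _, log = apply_filters(avg)
        merged = log.merge(truth.record_classes, on="record_id")
        mapping = {
            "ok": "kept",
            "under50": "removed_under50",
            "over30_household": "removed_over30birds",
            "under6wk": "removed_under6wk",
        }
        assert (merged["disposition"] == merged["contamination"].map(mapping)).all()

    @given(
        weights=st.lists(st.floats(1.0, 3000.0), min_size=1, max_size=30),
        weeks=st.lists(st.floats(1.0, 80.0), min_size=1, max_size=30),
    )
    @settings(max_examples=50, deadline=None)
    def test_conservation_property(self, weights, weeks):
        n = min(len(weights), len(weeks))
        df = make_avg_records(
            [
                {"group_weight_g": weights[i], "n_birds": 1, "week": weeks[i],
                 "household_id": f"H{i % 3}"}
                for i in range(n)
            ]
        )
        kept, log = apply_filters(df)
        assert len(log) == n
        assert (log["disposition"] == KEPT).sum() + (log["disposition"] != KEPT).sum() == n
        assert len(kept) == (log["disposition"] == KEPT).sum()


class TestPhases:
    def test_inclusive_bounds_male_growing(self):
        df = make_avg_records([{"sex": "male", "week": 19.0}, {"sex": "male", "week": 13.9}])
        out = split_phase(df, "male_growing")
        assert out["week"].tolist() == [19.0]

    def test_female_week20_adult_not_growing(self):
        df = make_avg_records([{"sex": "female", "week": 20.0}])
        assert len(split_phase(df, "female_growing")) == 0
        assert len(split_phase(df, "female_adult")) == 1

    def test_sex_mismatch_excluded(self):
        df = make_avg_records([{"sex": "male", "week": 30.0}])
        assert len(split_phase(df, "female_adult")) == 0

    def test_unknown_phase_name(self):
        df = make_avg_records([{}])
        with pytest.raises(ConfigurationError):
            split_phase(df, "juvenile")

    def test_invalid_phase_bounds(self):
        with pytest.raises(ConfigurationError):
            PhaseSpec("bad", "male", 4, 10)


class TestPhaseAverageWeek:
    def test_arithmetic_mean(self):
        df = make_avg_records([{"week": 14.0}, {"week": 16.0}, {"week": 19.0}])
        assert phase_average_week(df) == pytest.approx(49.0 / 3.0)

    def test_single_record_identity(self):
        df = make_avg_records([{"week": 41.0}])
        assert phase_average_week(df) == 41.0

    def test_empty_dataset_rejected(self):
        with pytest.raises(EmptyDatasetError):
            phase_average_week(pd.DataFrame({"week": []}))
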