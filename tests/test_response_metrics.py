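import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ndrscreen import (
    NoiseModel,
    ScreenTable,
    aggregate_controls,
    estimate_start_readout,
    exclude_wells,
    fold_change,
    generate_synthetic_screen,
    gr,
    ndr,
    pi,
    scale_for_dss,
    score_screen,
)
from ndrscreen.errors import ConfigurationError, ControlError, MetricError
from tests.conftest import make_plate

# strategies for valid fold changes: growing negative, dying positive control
fc_drug_st = st.floats(0.05, 20.0)
fc_neg_st = st.floats(1.5, 16.0)
fc_pos_st = st.floats(0.1, 0.9)


class TestFoldChange:
    @pytest.mark.parametrize("start,end,expected", [(100, 400, 4.0), (100, 100, 1.0), (200, 100, 0.5)])
    def test_values(self, start, end, expected):
        assert fold_change(start, end) == expected

    def test_zero_start_rejected(self):
        with pytest.raises(MetricError, match="start"):
            fold_change(0.0, 100.0)


class TestNdr:
    @pytest.mark.parametrize(
        "fc_d,expected",
        [
            (4.0, 1.0),       # normal growth as in negative control
            (1.0, 0.0),       # complete growth inhibition
            (0.5, -1.0),      # complete killing: raw -1.333 clamped
            (2.0, 2 / 3),     # partial inhibition: (1-2^-1)/(1-2^-2)
            (8.0, 7 / 6),     # proliferative effect, > 1
        ],
    )
    def test_reference_values(self, fc_d, expected):
        assert ndr(fc_d, 4.0, 0.5) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_controls_raise(self):
        with pytest.raises(MetricError, match="positive"):
            ndr(2.0, 4.0, 1.0)
        with pytest.raises(MetricError, match="negative"):
            ndr(2.0, 1.0, 0.5)
        with pytest.raises(MetricError):
            ndr(-1.0, 4.0, 0.5)

    @settings(max_examples=300, derandomize=True)
    @given(fc_drug_st, fc_neg_st, fc_pos_st)
    def test_clamp_floor(self, fc_d, fc_n, fc_p):
        assert ndr(fc_d, fc_n, fc_p) >= -1.0

    @settings(max_examples=200, derandomize=True)
    @given(fc_neg_st, fc_pos_st)
    def test_fixed_points(self, fc_n, fc_p):
        assert ndr(fc_n, fc_n, fc_p) == pytest.approx(1.0, abs=1e-12)
        assert ndr(1.0, fc_n, fc_p) == pytest.approx(0.0, abs=1e-12)

    @settings(max_examples=200, derandomize=True)
    @given(fc_drug_st, fc_drug_st, fc_neg_st, fc_pos_st)
    def test_monotone_in_drug_fold_change(self, fc_a, fc_b, fc_n, fc_p):
        lo, hi = sorted((fc_a, fc_b))
        assert ndr(lo, fc_n, fc_p) <= ndr(hi, fc_n, fc_p) + 1e-12


class TestGrPi:
    @pytest.mark.parametrize("fc_d,expected", [(4, 1.0), (1, 0.0), (2, math.sqrt(2) - 1)])
    def test_gr_values(self, fc_d, expected):
        assert gr(fc_d, 4.0) == pytest.approx(expected, abs=1e-12)

    def test_gr_degenerate_negative_control(self):
        with pytest.raises(MetricError):
            gr(2.0, 1.0)

    @pytest.mark.parametrize(
        "end_d,end_n,end_p,expected", [(1000, 1000, 100, 0.0), (100, 1000, 100, 1.0), (550, 1000, 100, 0.5)]
    )
    def test_pi_values(self, end_d, end_n, end_p, expected):
        assert pi(end_d, end_n, end_p) == pytest.approx(expected, abs=1e-12)

    def test_pi_degenerate_controls(self):
        with pytest.raises(MetricError):
            pi(100, 500, 500)


class TestScaleForDss:
    @pytest.mark.parametrize(
        "metric,value,expected",
        [("PI", 1.0, 100.0), ("NDR", 1.0, 0.0), ("NDR", -1.0, 100.0), ("GR", 1.0, 0.0)],
    )
    def test_values(self, metric, value, expected):
        assert scale_for_dss(metric, value) == pytest.approx(expected)

    def test_unknown_metric(self):
        with pytest.raises(ConfigurationError):
            scale_for_dss("bogus", 0.5)


class TestScaleInvariance:
    @settings(max_examples=50, derandomize=True)
    @given(st.floats(0.01, 100.0))
    def test_common_readout_scaling_leaves_ndr_gr_unchanged(self, k):
        table = ScreenTable.from_records(make_plate())
        scaled = table.copy()
        scaled.wells[["start_readout", "end_readout"]] *= k
        for metric in ("NDR", "GR"):
            a = score_screen(table, metric).wells[metric].dropna()
            b = score_screen(scaled, metric).wells[metric].dropna()
            np.testing.assert_allclose(a, b, rtol=1e-10)

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(0.01, 100.0))
    def test_endpoint_scaling_leaves_pi_unchanged(self, k):
        table = ScreenTable.from_records(make_plate())
        scaled = table.copy()
        scaled.wells["end_readout"] *= k
        a = score_screen(table, "PI").wells["PI"].dropna()
        b = score_screen(scaled, "PI").wells["PI"].dropna()
        np.testing.assert_allclose(a, b, rtol=1e-10)


class TestAggregateControls:
    def test_median_of_fold_changes(self):
        records = make_plate(
            neg=((100, 390), (100, 400), (100, 420)), pos=((100, 40), (100, 50))
        )
        summary = aggregate_controls(ScreenTable.from_records(records).wells)
        assert summary.fold_change_neg == pytest.approx(4.0)
        assert summary.fold_change_pos == pytest.approx(0.45)
        assert summary.end_median_neg == 400.0

    def test_excluded_control_ignored(self):
        records = make_plate(neg=((100, 390), (100, 400), (100, 800)))
        table = ScreenTable.from_records(records)
        # re-mark the outlier control as excluded, as exclude_wells would
        table.wells.loc[table.wells["end_readout"] == 800, "role"] = "excluded"
        active = table.active()
        summary = aggregate_controls(active[active["plate_id"] == "P1"])
        assert summary.fold_change_neg == pytest.approx(3.95)

    def test_too_few_controls(self):
        records = make_plate(neg=((100, 400),))
        with pytest.raises(ControlError):
            aggregate_controls(ScreenTable.from_records(records).wells)

    def test_fold_change_of_medians_mode(self):
        records = make_plate(neg=((100, 390), (200, 820)))
        summary = aggregate_controls(
            ScreenTable.from_records(records).wells, aggregation="fold_change_of_medians"
        )
        assert summary.fold_change_neg == pytest.approx(605.0 / 150.0)


class TestScoreScreen:
    def test_drug_wells_matching_negative_controls_score_one(self):
        records = make_plate(
            drug_wells=[("d", 1e-7, 100, 400), ("d", 1e-6, 100, 400)],
            neg=((100, 400), (100, 400)),
        )
        table = ScreenTable.from_records(records)
        for metric in ("NDR", "GR"):
            vals = score_screen(table, metric).wells[metric].dropna()
            np.testing.assert_allclose(vals, 1.0, atol=1e-12)

    def test_scenario_screen_spans_wide_ndr_range(self, noise_free_screen):
        table, _ = noise_free_screen
        vals = score_screen(table, "NDR").wells["NDR"].dropna()
        assert vals.min() < 0 and vals.max() > 1

    def test_excluded_wells_not_scored(self, toy_table):
        scored = score_screen(exclude_wells(toy_table, {"drugA"}), "NDR")
        assert scored.wells["NDR"].isna().all()


class TestEstimateStartReadout:
    def test_from_neg_control_end_median(self):
        records = make_plate(neg=((1, 320), (1, 320)))
        wells = ScreenTable.from_records(records).wells
        assert estimate_start_readout(wells, 3.2) == pytest.approx(100.0)
        assert estimate_start_readout(wells, 1.0) == pytest.approx(320.0)

    def test_self_consistency_round_trip(self):
        records = make_plate(neg=((1, 320), (1, 320)))
        wells = ScreenTable.from_records(records).wells
        start = estimate_start_readout(wells, 3.2)
        assert fold_change(start, 320.0) == pytest.approx(3.2)

    def test_requires_negative_controls(self):
        wells = pd.DataFrame({"role": ["drug"], "end_readout": [100.0]})
        with pytest.raises(ControlError):
            estimate_start_readout(wells, 3.2)
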