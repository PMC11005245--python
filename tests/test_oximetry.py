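"""Hill saturation, vessel classification, layer binning and summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from plimox import (
    assign_layer,
    classify_vessel,
    compute_doe,
    layer_summary,
    po2_to_so2,
    so2_to_po2,
)
from plimox.errors import EmptyLayerWarning, UnclassifiedVesselWarning
from plimox.oximetry import (
    classify_penetrating,
    cohort_aggregate,
    compute_deltas,
)


class TestHill:
    def test_half_saturation_at_p50(self, calib):
        assert po2_to_so2(calib.hill_p50_mmhg, calib) == pytest.approx(50.0)
        assert po2_to_so2(0.0, calib) == 0.0

    def test_value_at_twice_p50(self, calib):
        # 100 * 2^h / (1 + 2^h) with h = 2.59, evaluated independently
        expected = 100.0 * 2**2.59 / (1 + 2**2.59)
        assert po2_to_so2(2 * calib.hill_p50_mmhg, calib) == pytest.approx(expected)
        assert expected == pytest.approx(85.75698827, abs=1e-6)

    def test_strictly_increasing(self, calib):
        so2 = po2_to_so2(np.linspace(0, 150, 500), calib)
        assert np.all(np.diff(so2) > 0)
        assert np.all((so2 >= 0) & (so2 < 100))

    @settings(derandomize=True, max_examples=30)
    @given(st.floats(min_value=0.1, max_value=150.0))
    def test_hill_round_trip(self, po2):
        assert so2_to_po2(po2_to_so2(po2)) == pytest.approx(po2, rel=1e-9)

    def test_negative_po2_rejected(self):
        with pytest.raises(ValueError):
            po2_to_so2(-1.0)


class TestClassification:
    @pytest.mark.parametrize(
        "po2, vclass",
        [(70.0, "arteriole"), (60.0, "venule"), (66.0, "venule"), (66.01, "arteriole")],
    )
    def test_surface_po2_rule(self, po2, vclass):
        assert classify_vessel(po2) == vclass

    def test_baseline_frozen_and_propagated(self):
        """Class comes from the day-0, 50 µm point and sticks on later days
        even if the vessel later drops below 66 mmHg."""
        rows = []
        for day, po2_surface in [(0, 75.0), (7, 55.0)]:
            for depth in (50.0, 400.0):
                rows.append(
                    dict(
                        vessel_id=f"a0_z{depth:.0f}",
                        parent_id="a0",
                        animal_id="m1",
                        day=day,
                        depth_um=depth,
                        morphology="penetrating",
                        po2_mmhg=po2_surface,
                    )
                )
        out = classify_penetrating(pd.DataFrame(rows))
        assert (out["vessel_class"] == "arteriole").all()

    def test_missing_baseline_warns(self):
        df = pd.DataFrame(
            [
                dict(
                    vessel_id="v0_z400",
                    parent_id="v0",
                    animal_id="m1",
                    day=7,
                    depth_um=400.0,
                    morphology="penetrating",
                    po2_mmhg=50.0,
                )
            ]
        )
        with pytest.warns(UnclassifiedVesselWarning):
            out = classify_penetrating(df)
        assert out["vessel_class"].isna().all()

    def test_primary_branches_excluded_from_capillary_pool(self):
        df = pd.DataFrame(
            [
                dict(
                    vessel_id=f"c{i}",
                    parent_id=f"c{i}",
                    animal_id="m1",
                    day=0,
                    depth_um=200.0,
                    morphology="capillary",
                    is_primary_branch=bool(i == 0),
                    po2_mmhg=50.0,
                )
                for i in range(3)
            ]
        )
        out = classify_penetrating(df)
        assert (out["vessel_class"] == "excluded").sum() == 1
        assert (out["vessel_class"] == "capillary").sum() == 2


class TestLayers:
    @pytest.mark.parametrize(
        "depth, layer",
        [
            (50.0, "I"),
            (100.0, "II/III"),
            (200.0, "II/III"),
            (300.0, "II/III"),
            (319.999, "II/III"),
            (320.0, "IV"),
            (400.0, "IV"),
            (450.0, "IV"),
            (0.0, "I"),
        ],
    )
    def test_boundaries(self, depth, layer):
        assert assign_layer(depth) == layer

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(min_value=0.0, max_value=450.0))
    def test_every_depth_maps_to_exactly_one_layer(self, depth):
        assert assign_layer(depth) in {"I", "II/III", "IV"}

    def test_out_of_range_rejected(self):
        for depth in (-1.0, 450.1):
            with pytest.raises(ValueError):
                assign_layer(depth)


def _records(values, vessel_class="capillary", layer="I", **kw):
    return pd.DataFrame(
        [
            dict(
                cohort="WT",
                animal_id="m1",
                day=0,
                vessel_class=vessel_class,
                layer=layer,
                po2_mmhg=v,
                **kw,
            )
            for v in values
        ]
    )


class TestLayerSummary:
    def test_hand_computed_mean_and_cv(self):
        out = layer_summary(_records([10.0, 20.0]), value_cols=("po2_mmhg",))
        row = out.iloc[0]
        assert row["mean"] == 15.0
        assert row["sd"] == pytest.approx(7.0710678, abs=1e-6)
        assert row["cv"] == pytest.approx(0.4714045, abs=1e-6)
        assert row["se"] == pytest.approx(row["sd"] / np.sqrt(2))

    def test_equal_records_give_zero_cv_and_se(self):
        out = layer_summary(_records([42.0] * 5), value_cols=("po2_mmhg",))
        assert out.iloc[0]["cv"] == 0.0 and out.iloc[0]["se"] == 0.0

    def test_cv_scale_invariance(self):
        base = _records([31.0, 47.0, 52.0, 40.0])
        scaled = base.assign(po2_mmhg=base["po2_mmhg"] * 3.7)
        cv1 = layer_summary(base, value_cols=("po2_mmhg",)).iloc[0]["cv"]
        cv2 = layer_summary(scaled, value_cols=("po2_mmhg",)).iloc[0]["cv"]
        assert cv1 == pytest.approx(cv2, rel=1e-12)


class TestDOE:
    def _df(self, art, ven):
        rows = [
            dict(cohort="WT", animal_id="m1", day=0, layer="IV",
                 vessel_class="arteriole", so2_pct=v)
            for v in art
        ] + [
            dict(cohort="WT", animal_id="m1", day=0, layer="IV",
                 vessel_class="venule", so2_pct=v)
            for v in ven
        ]
        return pd.DataFrame(rows)

    def test_arithmetic(self):
        out = compute_doe(self._df([90.0, 94.0], [60.0, 64.0]))
        assert out.iloc[0]["doe_pct"] == pytest.approx(30.0)
        assert out.iloc[0]["sao2_pct"] == 92.0 and out.iloc[0]["svo2_pct"] == 62.0

    def test_equal_means_give_zero(self):
        assert compute_doe(self._df([80.0], [80.0])).iloc[0]["doe_pct"] == 0.0

    def test_translation_invariance(self):
        a = compute_doe(self._df([90.0, 94.0], [60.0, 64.0])).iloc[0]["doe_pct"]
        b = compute_doe(self._df([95.0, 99.0], [65.0, 69.0])).iloc[0]["doe_pct"]
        assert a == pytest.approx(b)

    def test_duplication_invariance(self):
        df = self._df([90.0, 94.0], [60.0, 64.0])
        a = compute_doe(df).iloc[0]["doe_pct"]
        b = compute_doe(pd.concat([df, df])).iloc[0]["doe_pct"]
        assert a == pytest.approx(b)

    def test_missing_class_omitted_with_warning(self):
        df = self._df([90.0], [])
        with pytest.warns(EmptyLayerWarning):
            out = compute_doe(df)
        assert out.empty


class TestCohortAggregate:
    def test_single_animal_equals_its_summary(self):
        tbl = pd.DataFrame(
            [dict(cohort="WT", animal_id="m1", day=0, vessel_class="capillary",
                  layer="I", variable="po2_mmhg", mean=48.0, cv=0.2)]
        )
        out = cohort_aggregate(tbl, value_cols=["mean", "cv"])
        assert out.iloc[0]["mean_cohort"] == 48.0
        assert out.iloc[0]["n_animals"] == 1

    def test_animals_weighted_equally_regardless_of_vessel_count(self):
        """Two animals with layer means 40 and 60 -> cohort mean 50."""
        tbl = pd.DataFrame(
            [
                dict(cohort="WT", animal_id="m1", day=0, vessel_class="capillary",
                     layer="I", variable="po2_mmhg", mean=40.0, n=100),
                dict(cohort="WT", animal_id="m2", day=0, vessel_class="capillary",
                     layer="I", variable="po2_mmhg", mean=60.0, n=3),
            ]
        )
        out = cohort_aggregate(tbl, value_cols=["mean"])
        assert out.iloc[0]["mean_cohort"] == 50.0
        assert out.iloc[0]["mean_se"] == pytest.approx(10.0)


class TestDeltas:
    def test_delta_aligned_by_vessel(self):
        rows = []
        for day, shift in [(0, 0.0), (7, -10.0)]:
            for i, base in enumerate([70.0, 80.0]):
                rows.append(
                    dict(cohort="WT", animal_id="m1", vessel_id=f"c{i}",
                         vessel_class="capillary", layer="I", day=day,
                         so2_pct=base + shift)
                )
        out = compute_deltas(pd.DataFrame(rows))
        assert out["vessel"]["delta_so2_pct"].tolist() == [-10.0, -10.0]
        assert out["cohort"].iloc[0]["delta_so2_pct_cohort"] == pytest.approx(-10.0)

    def test_vessels_missing_baseline_dropped(self):
        rows = [
            dict(cohort="WT", animal_id="m1", vessel_id="c0",
                 vessel_class="capillary", layer="I", day=7, so2_pct=60.0),
            dict(cohort="WT", animal_id="m1", vessel_id="c1",
                 vessel_class="capillary", layer="I", day=0, so2_pct=70.0),
            dict(cohort="WT", animal_id="m1", vessel_id="c1",
                 vessel_class="capillary", layer="I", day=7, so2_pct=65.0),
        ]
        out = compute_deltas(pd.DataFrame(rows))
        assert out["vessel"]["vessel_id"].tolist() == ["c1"]
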