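"""Forward-model contracts: expected values, noise, determinism, truth."""

import numpy as np
import pytest

from plimox import (
    CalibrationParams,
    count_rbc,
    po2_to_lifetime,
    po2_to_so2,
)
from plimox.errors import ConfigError, UnresolvableFluxWarning
from plimox.synthetic import (
    IFGroundTruth,
    SyntheticCohortConfig,
    simulate_cohort,
    simulate_decay,
    simulate_flux_trace,
    simulate_if_stack,
)


class TestSimulateDecay:
    def test_zero_quenching_shape(self, calib, protocol):
        """At pO2 = 0 the expected-value histogram is exactly proportional
        to exp(-t/tau0) + C/A on every bin."""
        d = simulate_decay(0.0, calib, protocol, 1e6, noise=False)
        a, c = d.truth["amplitude"], d.truth["offset"]
        expected = a * (np.exp(-d.t / calib.tau0_us) + c / a)
        assert np.allclose(d.counts, expected, rtol=1e-12)
        assert d.truth["tau_us"] == calib.tau0_us

    def test_expected_counts_linear_in_budget(self, calib, protocol):
        d1 = simulate_decay(37.0, calib, protocol, 1e5, noise=False)
        d2 = simulate_decay(37.0, calib, protocol, 2e5, noise=False)
        assert np.allclose(d2.counts, 2 * d1.counts, rtol=1e-12)

    def test_photon_conservation_in_expected_value_mode(self, calib, protocol):
        for po2 in (0.0, 40.0, 120.0):
            d = simulate_decay(po2, calib, protocol, 12345.0, noise=False)
            assert d.counts.sum() == pytest.approx(12345.0, rel=1e-3)

    def test_determinism(self, calib, protocol):
        a = simulate_decay(40.0, calib, protocol, 1e5, rng=42)
        b = simulate_decay(40.0, calib, protocol, 1e5, rng=42)
        assert np.array_equal(a.counts, b.counts)

    def test_invalid_inputs_rejected(self, calib, protocol):
        with pytest.raises(ConfigError):
            simulate_decay(np.nan, calib, protocol, 1e5)
        with pytest.raises(ConfigError):
            simulate_decay(40.0, calib, protocol, -5.0)

    def test_truth_records_calibration_lifetime(self, calib, protocol):
        d = simulate_decay(40.0, calib, protocol, 1e5, rng=0)
        assert d.truth["tau_us"] == pytest.approx(po2_to_lifetime(40.0, calib))


class TestSimulateFluxTrace:
    def test_zero_flux_is_pure_baseline(self, protocol):
        tr = simulate_flux_trace(0.0, protocol=protocol, rng=1)
        assert tr.truth["n_arrivals"] == 0
        assert tr.counts.size == protocol.n_cycles

    def test_twelve_equally_spaced_events_count_as_twenty_per_s(self, protocol):
        """12 non-overlapping constructed events in 0.6 s -> 20 RBC/s."""
        arrivals = 0.025 + 0.05 * np.arange(12)
        tr = simulate_flux_trace(
            20.0, protocol=protocol, noise=False, arrival_times_s=arrivals, rng=0
        )
        # brute-force: count below-threshold runs directly
        threshold = 0.5 * tr.counts.max()
        below = tr.counts < threshold
        runs = int(np.sum(np.diff(np.concatenate(([0], below.astype(int), [0]))) == 1))
        assert runs == 12
        assert runs / tr.duration_s == pytest.approx(20.0)
        assert tr.truth["n_merged_valleys"] == 12

    def test_overlapping_events_merge(self, protocol):
        """Two arrivals inside one transit window form a single wider valley
        (the documented undercount of the raw estimator)."""
        tr = simulate_flux_trace(
            0.0,
            protocol=protocol,
            noise=False,
            arrival_times_s=[0.100, 0.101],  # 1 ms apart < 3 ms transit
            rng=0,
        )
        assert tr.truth["n_arrivals"] == 2
        assert tr.truth["n_merged_valleys"] == 1

    def test_valley_depth_and_width(self, protocol):
        tr = simulate_flux_trace(
            0.0, protocol=protocol, noise=False,
            arrival_times_s=[0.3], baseline_counts=200.0, rng=0,
        )
        assert tr.counts.min() == pytest.approx(20.0)  # (1-0.9)*200
        n_depressed = np.sum(tr.counts < 199.0)
        assert n_depressed == pytest.approx(10, abs=1)  # 3 ms / 300 µs

    def test_unresolvable_rate_warns(self, protocol):
        with pytest.warns(UnresolvableFluxWarning):
            simulate_flux_trace(5000.0, protocol=protocol, rng=0)

    def test_determinism(self, protocol):
        a = simulate_flux_trace(60.0, protocol=protocol, rng=5)
        b = simulate_flux_trace(60.0, protocol=protocol, rng=5)
        assert np.array_equal(a.counts, b.counts)
        assert np.array_equal(a.truth["arrival_times_s"], b.truth["arrival_times_s"])

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ConfigError):
            simulate_flux_trace(-1.0)
        with pytest.raises(ConfigError):
            simulate_flux_trace(10.0, valley_depth_fraction=1.5)


def small_cohort_config(**kw):
    defaults = dict(
        n_animals={"WT": 2, "AD": 2},
        n_arterioles=1,
        n_venules=1,
        n_capillaries_per_depth=1,
        n_primary_branches=1,
        n_flux_repetitions=2,
        photon_budget=2e4,
        seed=5,
    )
    defaults.update(kw)
    return SyntheticCohortConfig(**defaults)


class TestSimulateCohort:
    def test_determinism_bitwise(self):
        a = simulate_cohort(small_cohort_config())
        b = simulate_cohort(small_cohort_config())
        assert len(a.points) == len(b.points)
        for pa, pb in zip(a.points, b.points):
            assert pa.vessel_id == pb.vessel_id
            assert np.array_equal(pa.decays[0].counts, pb.decays[0].counts)
            if pa.traces:
                assert np.array_equal(pa.traces[0].counts, pb.traces[0].counts)

    def test_zero_noise_truth_equals_layer_means(self):
        cfg = small_cohort_config(
            po2_sd_between_mmhg=0.0, flux_sd_rbc_per_s=0.0, photon_noise=False
        )
        ds = simulate_cohort(cfg)
        for p in ds.points:
            if p.morphology == "capillary" and not p.is_primary_branch:
                layer = (
                    "I" if p.depth_um < 100 else "II/III" if p.depth_um < 320 else "IV"
                )
                expected = (
                    cfg.po2_mean_mmhg[p.cohort]["capillary"][layer]
                    + cfg.day_offset_mmhg[p.cohort][p.day]
                )
                assert p.truth["true_po2_mmhg"] == pytest.approx(expected)

    def test_surface_po2_respects_class_by_construction(self):
        ds = simulate_cohort(small_cohort_config(n_arterioles=3, n_venules=3))
        for p in ds.points:
            if (
                p.morphology == "penetrating"
                and p.day == 0
                and p.depth_um == 50.0
            ):
                if p.truth["true_class"] == "arteriole":
                    assert p.truth["true_po2_mmhg"] > 66.0
                else:
                    assert p.truth["true_po2_mmhg"] < 66.0

    def test_truth_table_has_one_row_per_point(self):
        ds = simulate_cohort(small_cohort_config())
        tbl = ds.truth_table()
        assert len(tbl) == len(ds.points)
        assert {"true_po2_mmhg", "cohort", "day"} <= set(tbl.columns)

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            small_cohort_config(n_animals={"WT": 0, "AD": 2})
        with pytest.raises(ConfigError):
            small_cohort_config(n_capillaries_per_depth=0)
        bad_means = SyntheticCohortConfig().po2_mean_mmhg
        bad_means["WT"]["arteriole"]["I"] = 200.0
        with pytest.raises(ConfigError):
            small_cohort_config(po2_mean_mmhg=bad_means)


class TestSimulateIFStack:
    def test_zero_blobs_zero_percent_area(self):
        truth = IFGroundTruth(pa_percent={"GFAP": 0.0})
        stack = simulate_if_stack(truth, image_shape=(64, 64), rng=0)
        assert stack.truth["achieved_pa_percent"]["GFAP"] == 0.0
        assert not stack.truth["masks"]["GFAP"].any()

    def test_achieved_fraction_close_to_target(self):
        truth = IFGroundTruth(pa_percent={"GFAP": 12.0})
        stack = simulate_if_stack(truth, image_shape=(256, 256), rng=1)
        achieved = stack.truth["achieved_pa_percent"]["GFAP"]
        assert achieved >= 12.0
        assert achieved == pytest.approx(12.0, abs=1.0)  # one-blob overshoot

    def test_determinism(self):
        t = IFGroundTruth(pa_percent={"GFAP": 5.0})
        a = simulate_if_stack(t, image_shape=(64, 64), rng=9)
        b = simulate_if_stack(t, image_shape=(64, 64), rng=9)
        assert np.array_equal(a.data, b.data)

    def test_stack_geometry(self):
        stack = simulate_if_stack(IFGroundTruth(), image_shape=(64, 64), rng=0)
        assert stack.data.shape == (2, 11, 64, 64)
        assert stack.thickness_um == pytest.approx(39.6)
        assert stack.z_step_um == 3.96

    def test_oversized_blobs_rejected(self):
        truth = IFGroundTruth(
            pa_percent={"GFAP": 10.0}, blob_radius_px_mean=100.0
        )
        with pytest.raises(ConfigError):
            simulate_if_stack(truth, image_shape=(32, 32), rng=0)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ConfigError):
            IFGroundTruth(pa_percent={"GFAP": 120.0})
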