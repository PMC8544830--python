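import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mechanonps.detect import CandidateWindow, SegmentedPulse, Subpulse
from mechanonps.geometry import GeometryError
from mechanonps.phenotype import (CellRecord, classify_recovery, compute_wcdi,
                                  delta_t_r, diameter_from_amplitude, fit_tau,
                                  flag_erroneous, flag_statistical_outliers,
                                  phenotype_pipeline, recovery_deficits,
                                  velocity)
from mechanonps.simulate import subpulse_amplitude


class TestDiameterFromAmplitude:
    @pytest.mark.parametrize("d", [9.0, 10.77, 12.0])
    def test_inverts_sizing_relation(self, d, ap_geometry):
        a = subpulse_amplitude(d, ap_geometry.pore_width_um,
                               ap_geometry.pore_length_um,
                               ap_geometry.channel_height_um)
        assert diameter_from_amplitude(a, ap_geometry) == pytest.approx(
            d, abs=1e-4)

    def test_zero_amplitude_rejected(self, ap_geometry):
        with pytest.raises(GeometryError):
            diameter_from_amplitude(0.0, ap_geometry)

    def test_out_of_range_amplitude_rejected(self, ap_geometry):
        with pytest.raises(GeometryError):
            diameter_from_amplitude(10.0, ap_geometry)


class TestVelocity:
    def test_700um_in_0p7ms_is_1000um_per_ms(self):
        assert velocity(0.7, 700.0) == pytest.approx(1000.0)

    def test_2000um_in_4ms(self):
        assert velocity(4.0, 2000.0) == pytest.approx(500.0)

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            velocity(0.0, 700.0)

    def test_multiple_pores_averaged(self):
        assert velocity([1.0, 2.0], 700.0) == pytest.approx(
            (700.0 + 350.0) / 2)


class TestWcdi:
    def test_identity_case(self):
        assert compute_wcdi(1.0, 1.0, 22.3, 22.3) == pytest.approx(1.0)

    def test_direct_arithmetic(self):
        assert compute_wcdi(1.5, 0.5, 15.0, 22.3) == pytest.approx(
            2.0179372197309418)

    def test_linear_in_contraction_velocity(self):
        assert compute_wcdi(2.0, 1.0, 10.0, 20.0) == pytest.approx(
            2 * compute_wcdi(1.0, 1.0, 10.0, 20.0))

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            compute_wcdi(0.0, 1.0, 10.0, 20.0)


def make_pulse(ap_geometry, d0=10.77, q_values=(0.1, 0.05, 0.02, 0.01, 0.0, 0.0),
               t0_s=1.0, v=10.0):
    """Hand-built segmented pulse with prescribed recovery deficits."""
    g = ap_geometry
    a_ref = subpulse_amplitude(d0, g.pore_width_um, g.pore_length_um,
                               g.channel_height_um)
    a_rec = subpulse_amplitude(d0, g.pore_width_um, g.recovery_pore_length_um,
                               g.channel_height_um)
    subs = []
    t = t0_s
    for _ in range(g.n_reference_pores):
        dur = g.pore_length_um / v / 1000.0
        subs.append(Subpulse("reference_pore", t, t + dur, a_ref, dur * 1000))
        t += dur + g.node_length_um / v / 1000.0
    dur = g.contraction_length_um / (0.5 * v) / 1000.0
    subs.append(Subpulse("contraction", t, t + dur, 1.5e-2, dur * 1000))
    t += dur
    for q in q_values:
        t += g.node_length_um / v / 1000.0
        dur = g.recovery_pore_length_um / v / 1000.0
        subs.append(Subpulse("recovery_pore", t, t + dur,
                             a_rec * (1 - q), dur * 1000))
        t += dur
    return SegmentedPulse(subs, CandidateWindow(0, 1, []))


class TestRecoveryDeficits:
    def test_fully_recovered_cell_has_zero_deficits(self, ap_geometry):
        pulse = make_pulse(ap_geometry, q_values=(0.0,) * 6)
        for _, q in recovery_deficits(pulse, ap_geometry, 10.77):
            assert q == pytest.approx(0.0, abs=1e-12)

    def test_recovers_planted_deficits(self, ap_geometry):
        planted = (0.2, 0.1, 0.05, 0.02, 0.01, 0.005)
        pulse = make_pulse(ap_geometry, q_values=planted)
        got = [q for _, q in recovery_deficits(pulse, ap_geometry, 10.77)]
        assert got == pytest.approx(list(planted), abs=1e-12)

    def test_noise_overshoot_clipped_at_zero(self, ap_geometry):
        pulse = make_pulse(ap_geometry, q_values=(-0.01, 0.0, 0.0, 0.0, 0.0, 0.0))
        (t0, q0), *_ = recovery_deficits(pulse, ap_geometry, 10.77)
        assert q0 == 0.0

    def test_times_measured_from_contraction_exit(self, ap_geometry):
        pulse = make_pulse(ap_geometry, v=10.0)
        times = [t for t, _ in recovery_deficits(pulse, ap_geometry, 10.77)]
        # first midpoint: node + half a recovery pore at 10 um/ms
        expected0 = (ap_geometry.node_length_um
                     + 0.5 * ap_geometry.recovery_pore_length_um) / 10.0
        assert times[0] == pytest.approx(expected0, rel=1e-9)
        assert all(b > a for a, b in zip(times, times[1:]))


class TestFitTau:
    def test_exact_exponential_recovered(self):
        t = np.array([5.0, 15.0, 25.0, 35.0])
        deficits = list(zip(t, 0.3 * np.exp(-t / 10.0)))
        assert fit_tau(deficits) == pytest.approx(10.0, rel=1e-9)

    def test_all_below_floor_returns_none(self):
        assert fit_tau([(5.0, 1e-4), (15.0, 5e-5)]) is None

    def test_growing_deficits_unresolvable(self):
        assert fit_tau([(5.0, 0.1), (15.0, 0.2)]) is None

    @given(c=st.floats(0.1, 10.0))
    @settings(max_examples=25, deadline=None)
    def test_scale_equivariance(self, c):
        t = np.array([5.0, 15.0, 25.0, 35.0])
        deficits = list(zip(t, 0.3 * np.exp(-t / 10.0)))
        scaled = [(c * ti, qi) for ti, qi in deficits]
        assert fit_tau(scaled) == pytest.approx(c * fit_tau(deficits),
                                                rel=1e-9)


class TestDeltaTr:
    def test_immediately_recovered(self):
        assert delta_t_r([(10.0, 0.001), (40.0, 0.0)], tolerance=0.02) == 0.0

    def test_crossing_at_third_pore(self):
        deficits = [(14.0, 0.3), (28.0, 0.05), (42.0, 0.01), (56.0, 0.0)]
        assert delta_t_r(deficits, tolerance=0.02) == pytest.approx(42.0)

    def test_never_recovering_is_prolonged(self):
        deficits = [(20.0, 0.3), (50.0, 0.25), (90.0, 0.21)]
        assert math.isinf(delta_t_r(deficits, tolerance=0.02))

    def test_recovery_beyond_window_is_prolonged(self):
        deficits = [(60.0, 0.3), (130.0, 0.001)]
        assert math.isinf(delta_t_r(deficits, tolerance=0.02, window_ms=100))

    def test_empty_deficits_rejected(self):
        with pytest.raises(ValueError):
            delta_t_r([])


class TestClassifyRecovery:
    @pytest.mark.parametrize("dtr, expected", [
        (0.0, "instantaneous"),
        (50.0, "finite"),
        (99.999, "finite"),
        (100.0, "prolonged"),       # boundary maps to prolonged (open interval)
        (150.0, "prolonged"),
        (math.inf, "prolonged"),
    ])
    def test_partition(self, dtr, expected):
        assert classify_recovery(dtr) == expected


class TestStatisticalOutliers:
    def test_single_extreme_value_flagged(self):
        mask = flag_statistical_outliers([1.0, 1.0, 1.0, 1.0, 100.0])
        assert list(mask) == [False, False, False, False, True]

    def test_all_equal_values_flag_nothing(self):
        assert not flag_statistical_outliers([2.0] * 10).any()

    def test_symmetric_data_without_extremes(self):
        assert not flag_statistical_outliers([1.0, 2.0, 3.0, 4.0, 5.0]).any()

    def test_matches_brute_force_mad_rule(self):
        rng = np.random.default_rng(31)
        x = rng.normal(10, 2, 200)
        x[[5, 50]] += 40
        med = np.median(x)
        mad = np.median(np.abs(x - med))
        expected = np.abs(x - med) > 3 * mad
        assert np.array_equal(flag_statistical_outliers(x), expected)

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            flag_statistical_outliers([1.0, 2.0])


def make_record_table(v0, vc):
    return pd.DataFrame({"v0_um_per_ms": v0, "vc_um_per_ms": vc})


class TestFlagErroneous:
    def test_planted_velocity_aberrations_flagged_exactly(self):
        rng = np.random.default_rng(32)
        v0 = rng.normal(10, 0.5, 20)
        vc = rng.normal(5, 0.3, 20)
        v0[3] = 40.0      # aberrant reference velocity
        vc[17] = 0.2      # aberrant contraction velocity
        mask = flag_erroneous(make_record_table(v0, vc))
        assert set(np.flatnonzero(mask)) == {3, 17}

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(33)
        v0 = rng.normal(10, 1.0, 50)
        vc = rng.normal(5, 0.8, 50)
        v0[[2, 9]] = [35.0, 0.5]
        mask = flag_erroneous(make_record_table(v0, vc))
        expected = np.zeros(50, dtype=bool)
        for v in (v0, vc):
            med, mad = np.median(v), np.median(np.abs(v - np.median(v)))
            inl = v[np.abs(v - med) <= 3 * mad]
            med2 = np.median(inl)
            mad2 = np.median(np.abs(inl - med2))
            expected |= np.abs(v - med2) > 4 * mad2
        assert np.array_equal(mask, expected)

    def test_order_invariance(self):
        rng = np.random.default_rng(34)
        v0 = rng.normal(10, 1.0, 30)
        vc = rng.normal(5, 0.5, 30)
        v0[4] = 50.0
        base = flag_erroneous(make_record_table(v0, vc))
        perm = rng.permutation(30)
        permuted = flag_erroneous(make_record_table(v0[perm], vc[perm]))
        assert np.array_equal(permuted, base[perm])

    def test_two_records_rejected(self):
        with pytest.raises(ValueError):
            flag_erroneous(make_record_table([1.0, 2.0], [1.0, 2.0]))


class TestPhenotypePipeline:
    def test_noiseless_roundtrip(self, noiseless_processed, ap_geometry):
        """Estimated phenotypes reproduce the simulator's ground truth."""
        records, detection, manifest = noiseless_processed
        truth = manifest.to_dataframe()
        assert len(records) == len(truth)
        for i in range(len(records)):
            assert abs(records.d0_um[i] - truth.d0_um[i]) < 0.05
            rel = abs(records.wcdi[i] - truth.true_wcdi[i]) / truth.true_wcdi[i]
            assert rel < 1e-3

    def test_categories_consistent_with_delta_t_r(self, noiseless_processed):
        records, _, _ = noiseless_processed
        for _, r in records.iterrows():
            assert r.recovery_category == classify_recovery(r.delta_t_r_ms)

    def test_pipeline_is_deterministic(self, noiseless_processed,
                                       noiseless_recording, ap_geometry):
        from mechanonps import process_trace
        records, _, _ = noiseless_processed
        trace, _ = noiseless_recording
        again, _ = process_trace(trace, ap_geometry)
        pd.testing.assert_frame_equal(records, again)
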