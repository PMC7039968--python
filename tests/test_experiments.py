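"""Tests for the experiment runners: determinism, controls, variants."""

import numpy as np
import pandas as pd
import pytest

from mbstereo import (NetworkParams, drive_difference_analysis, fit_hill,
                      hill_curve, run_convergence_randomness_grid,
                      run_fixed_drive, run_learning, run_parameter_sweep,
                      run_simulation)
from mbstereo.experiments import apply_learning_event, partition_spikes


class TestRunSimulation:
    def test_same_seed_bit_identical(self, small_params):
        a = run_simulation(small_params, 3, seed=7)
        b = run_simulation(small_params, 3, seed=7)
        pd.testing.assert_frame_equal(a.per_iteration, b.per_iteration)
        pd.testing.assert_frame_equal(a.auxiliaries, b.auxiliaries)

    def test_different_seeds_differ(self, small_params):
        a = run_simulation(small_params, 3, seed=7)
        b = run_simulation(small_params, 3, seed=8)
        assert not a.per_iteration["value"].equals(b.per_iteration["value"])

    def test_identical_connectivity_control_is_perfect(self, small_params):
        rep = run_simulation(small_params, 5, control="identical_connectivity",
                             seed=1)
        preds = rep.per_iteration[
            (rep.per_iteration["metric"] == "pred")
            & (rep.per_iteration["quantity"] != "individual_kc")]
        assert np.allclose(preds["value"], 1.0)
        # identical networks: every qualifying KC's vectors coincide exactly
        ikc_corr = rep.per_iteration.query(
            "quantity == 'individual_kc' and metric == 'correlation'")
        assert np.allclose(ikc_corr["value"], 1.0)

    def test_aggregates_recomputable_from_rows(self, small_params):
        rep = run_simulation(small_params, 6, seed=2)
        sub = rep.per_iteration[(rep.per_iteration["quantity"] == "mbon")
                                & (rep.per_iteration["metric"] == "pred")]
        assert rep.mean("mbon", "pred") == pytest.approx(sub["value"].mean())
        agg = rep.aggregates.set_index(["quantity", "metric"])
        assert agg.loc[("mbon", "pred"), "n"] == 6

    def test_unknown_control_rejected(self, small_params):
        with pytest.raises(ValueError, match="control"):
            run_simulation(small_params, 1, control="bogus")

    def test_normalized_weights_collapse_stereotypy(self):
        p = NetworkParams(n_odors=20)
        base = run_simulation(p, 5, seed=3, compute_kc_metrics=False)
        norm = run_simulation(p, 5, seed=3, normalize_mbon_weights=True,
                              compute_kc_metrics=False)
        assert abs(norm.mean("mbon")) < 0.3 * base.mean("mbon")

    def test_noise_reduces_stereotypy(self):
        p = NetworkParams(n_odors=20)
        quiet = run_simulation(p, 5, seed=4, compute_kc_metrics=False)
        noisy = run_simulation(p.with_(noise_sd=40.0), 5, seed=4,
                               compute_kc_metrics=False)
        assert noisy.mean("mbon") < quiet.mean("mbon")


class TestLearning:
    def test_zero_rate_matches_reference_run(self):
        p = NetworkParams(n_odors=10)
        base = run_simulation(p, 3, seed=11, compute_kc_metrics=False)
        learned = run_learning(p, 3, learning_rate=0.0, seed=11)
        for metric in ("pred", "correlation"):
            b = base.per_iteration.query(
                "quantity == 'mbon' and metric == @metric")["value"]
            l = learned.per_iteration.query(
                "quantity == 'mbon' and metric == @metric")["value"]
            assert np.allclose(b.to_numpy(), l.to_numpy())

    def test_stereotypy_decreases_with_learning_rate(self):
        p = NetworkParams(n_odors=20)
        means = [run_learning(p, 15, learning_rate=lr, seed=12).mean("mbon")
                 for lr in (0.0, 0.5, 1.0)]
        assert means[0] > means[1] > means[2]

    def test_invalid_rate_rejected(self, small_params):
        with pytest.raises(ValueError, match="learning_rate"):
            run_learning(small_params, 1, learning_rate=1.5)

    def test_full_rate_increase_event_connects_all_active(self, rng):
        connected = np.zeros(30, dtype=bool)
        connected[:10] = True
        active = rng.random(30) < 0.4
        apply_learning_event(connected, active, increase=True,
                             learning_rate=1.0, rng=rng)
        assert connected[active].all()
        # inactive KCs untouched
        assert np.array_equal(connected[~active & (np.arange(30) >= 10)],
                              np.zeros((~active & (np.arange(30) >= 10)).sum(),
                                       dtype=bool))

    def test_half_rate_event_changes_rounded_count(self, rng):
        connected = np.zeros(20, dtype=bool)
        active = np.ones(20, dtype=bool)
        changed = apply_learning_event(connected, active, increase=True,
                                       learning_rate=0.5, rng=rng)
        assert changed == 10
        assert connected.sum() == 10


class TestPartition:
    @pytest.mark.parametrize("total, n, lo, hi", [
        (500, 25, 10, 30), (500, 45, 10, 30), (500, 25, 5, 35), (100, 10, 10, 10),
    ])
    def test_partition_sums_and_bounds(self, total, n, lo, hi, rng):
        for _ in range(20):
            parts = partition_spikes(total, n, lo, hi, rng)
            assert parts.sum() == total
            assert parts.min() >= lo and parts.max() <= hi
            assert parts.size == n

    def test_infeasible_partition_rejected(self, rng):
        with pytest.raises(ValueError, match="cannot split"):
            partition_spikes(500, 10, 10, 30, rng)  # 10*30 < 500

    def test_parts_are_exchangeable(self, rng):
        """The final permutation removes the sequential-order bias."""
        draws = np.stack([partition_spikes(60, 3, 10, 30, rng)
                          for _ in range(3000)])
        means = draws.mean(axis=0)
        assert np.allclose(means, 20.0, atol=0.5)


class TestFixedDrive:
    def test_total_drive_pinned(self):
        rep = run_fixed_drive(NetworkParams(), 3, "base", seed=1)
        assert rep.meta["total_drive"] == 500
        assert (rep.auxiliaries["drive_diff"] == 0).all()

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            run_fixed_drive(NetworkParams(), 1, "bogus")

    def test_infeasible_variant_fails_fast(self):
        with pytest.raises(ValueError, match="infeasible"):
            run_fixed_drive(NetworkParams(), 1, "nactive_one_odor",
                            {"n_active": 10})

    def test_nactive_difference_creates_stereotypy(self):
        p = NetworkParams()
        diff = run_fixed_drive(p, 30, "nactive_one_odor",
                               {"n_active": 45}, seed=5)
        same = run_fixed_drive(p, 30, "nactive_both_odors",
                               {"n_active": 45}, seed=5)
        assert diff.mean("total_kc_response") > 0.5
        assert abs(same.mean("total_kc_response")) < 0.25

    def test_range_difference_creates_stereotypy(self):
        p = NetworkParams()
        diff = run_fixed_drive(p, 30, "range_one_odor",
                               {"spike_range": (19, 21)}, seed=6)
        assert diff.mean("total_kc_response") > 0.3

    def test_linear_transfer_abolishes_stereotypy(self):
        p = NetworkParams()
        rep = run_fixed_drive(p, 30, "linear_nactive", {"n_active": 45},
                              seed=7)
        assert abs(rep.mean("total_kc_response")) < 0.2

    def test_shuffled_labels_null(self):
        rep = run_fixed_drive(NetworkParams(), 30, "shuffled_labels", seed=8)
        assert abs(rep.mean("total_kc_response")) < 0.2


class TestSweeps:
    def test_unknown_parameter_rejected(self, small_params):
        with pytest.raises(ValueError, match="swept parameter"):
            run_parameter_sweep(small_params, 1, "bogus", [1])

    def test_mean_rate_sweep_increases_stereotypy(self):
        p = NetworkParams(n_odors=2)
        tab = run_parameter_sweep(p, 20, "pn_mean_rate", [14, 20, 26], seed=9)
        s = tab["pred_total_kc_response"].to_numpy()
        assert s[0] < s[1] < s[2]
        # more drive -> both more active KCs and higher active rates
        assert tab["n_active_kcs"].is_monotonic_increasing

    def test_n_kcs_sweep_changes_count_not_rate(self):
        p = NetworkParams(n_odors=2)
        tab = run_parameter_sweep(p, 20, "n_kcs", [500, 2000, 8000], seed=10)
        assert tab["n_active_kcs"].is_monotonic_increasing
        rates = tab["mean_active_rate"].to_numpy()
        assert np.ptp(rates) / rates.mean() < 0.05  # flat
        s = tab["pred_total_kc_response"].to_numpy()
        assert s[0] < s[2]

    def test_threshold_sweep_decreases_stereotypy(self):
        p = NetworkParams(n_odors=2)
        tab = run_parameter_sweep(p, 20, "kc_threshold", [90, 119, 160],
                                  seed=11)
        s = tab["pred_total_kc_response"].to_numpy()
        assert s[0] > s[2]


class TestDriveDifference:
    def test_positive_correlations(self):
        tab, r_in, r_resp = drive_difference_analysis(NetworkParams(), 50,
                                                      seed=12)
        assert len(tab) == 50
        assert r_in > 0.2
        assert r_resp > 0.2

    def test_columns_present(self):
        tab, _, _ = drive_difference_analysis(NetworkParams(), 5, seed=13)
        assert {"drive_diff", "pred_total_kc_input",
                "pred_total_kc_response"} <= set(tab.columns)


class TestGrid:
    def test_grid_shape_and_determinism(self):
        p = NetworkParams(n_odors=2)
        a = run_convergence_randomness_grid(p, 5, grid_size=3, seed=14)
        b = run_convergence_randomness_grid(p, 5, grid_size=3, seed=14)
        assert len(a) == 9
        pd.testing.assert_frame_equal(a, b)

    def test_convergence_beats_randomness(self):
        p = NetworkParams(n_odors=2)
        tab = run_convergence_randomness_grid(p, 20, grid_size=3, seed=15)
        tab = tab.set_index(["convergence", "randomness"])
        high = tab.loc[(1.0, 0.01), "mean_pred"]
        low = tab.loc[(0.01, 1.0), "mean_pred"]
        assert high > 0.8
        assert high > low + 0.3

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError, match="grid values"):
            run_convergence_randomness_grid(NetworkParams(n_odors=2), 1,
                                            value_range=(0.0, 1.0))


class TestHillFit:
    def test_exact_recovery(self):
        r = np.logspace(-2, 0, 30)
        fit = fit_hill(r, hill_curve(r, 1.0, 1.0))
        assert fit.a == pytest.approx(1.0, abs=1e-6)
        assert fit.b == pytest.approx(1.0, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_noisy_recovery_near_truth(self, rng):
        r = np.logspace(-2, 0, 200)
        s = hill_curve(r, 0.65, 0.48) + rng.normal(0, 0.02, size=r.size)
        fit = fit_hill(r, s)
        assert fit.a == pytest.approx(0.65, abs=0.1)
        assert fit.b == pytest.approx(0.48, abs=0.1)

    def test_constant_values_degenerate(self):
        fit = fit_hill([0.1, 0.5, 1.0], [0.4, 0.4, 0.4])
        assert fit.degenerate
        assert fit.r_squared == 0.0

    def test_input_validation(self):
        with pytest.raises(ValueError, match="3 points"):
            fit_hill([0.1, 1.0], [0.2, 0.4])
        with pytest.raises(ValueError, match="positive"):
            fit_hill([-0.1, 0.5, 1.0], [0.1, 0.2, 0.3])
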