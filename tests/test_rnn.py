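"""Dynamics oracles, Dale structure, training sanity, decoding and lesions."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from neurocue import rnn
from neurocue.rnn import (RNNParams, TaskTiming, TrialBatch, connection_graph,
                          contrast_levels, decode_batch, ei_groups,
                          fit_psychometric, init_network, lesion_params,
                          lesion_experiment, make_inputs, make_trial_batch,
                          make_training_targets, permutation_pvalue_greater,
                          project_dale, simulate_batch, train_network)


def _tiny_params(n=2, **kw):
    p = init_network(16, seed=0)   # smallest supported; then shrink by hand
    W_in = np.array([[0.1, -0.2], [0.3, 0.05]])
    W_rec = np.array([[0.0, -0.5], [0.4, 0.0]])
    W_out = np.array([[0.2, 0.1], [0.0, 0.3]])
    return RNNParams(W_in, W_rec, W_out, b_rec=np.array([0.05, -0.1]),
                     b_out=np.zeros(2), sign_vector=np.array([1.0, -1.0]),
                     **kw)


class TestInitAndDale:
    def test_fifty_units_gives_forty_excitatory(self):
        p = init_network(50, seed=0)
        assert p.n_excitatory == 40
        assert int((p.sign_vector < 0).sum()) == 10

    def test_same_seed_identical_parameters(self):
        a, b = init_network(50, seed=3), init_network(50, seed=3)
        assert np.array_equal(a.W_rec, b.W_rec)
        assert np.array_equal(a.W_in, b.W_in)

    def test_no_dale_violation_after_projection(self):
        p = init_network(50, seed=1)
        assert p.dale_violation() == 0.0
        # exhaustive check of the constraint, column by column
        for j in range(p.n_units):
            col = p.W_rec[:, j]
            if p.sign_vector[j] > 0:
                assert np.all(col >= 0)
            else:
                assert np.all(col <= 0)
        assert np.all(np.diag(p.W_rec) == 0)

    def test_init_weights_within_truncation(self):
        p = init_network(50, seed=2)
        assert np.abs(p.W_in).max() <= 1.0

    def test_too_small_network_rejected(self):
        with pytest.raises(ValueError):
            init_network(1)
        with pytest.warns(UserWarning, match="16 units"):
            init_network(8, seed=0)


class TestDynamicsOracles:
    def test_single_euler_step_matches_hand_computation(self):
        """One step on an N=2 network against explicit arithmetic, 1e-12."""
        p = _tiny_params()
        batch = TrialBatch(np.array([0]), np.array([0]), np.array([0.1]))
        u, X, R, Y = simulate_batch(p, batch, seed=0, noise_on=False)
        alpha = p.dt_ms / p.tau_ms
        x = np.zeros(2)
        r = np.zeros(2)
        for t in range(3):
            drive = p.W_rec @ r + p.b_rec + p.W_in @ u[t, :, 0]
            x = (1 - alpha) * x + alpha * np.maximum(drive, 0.0)
            r = np.maximum(x, 0.0)
            assert np.allclose(X[t, :, 0], x, atol=1e-12)
            assert np.allclose(R[t, :, 0], r, atol=1e-12)
            z = p.W_out @ r + p.b_out
            assert np.allclose(Y[t, :, 0], expit(z), atol=1e-12)

    def test_relaxation_to_fixed_point_follows_exponential(self):
        """Zero weights, noise off, b_rec = c >= 0: x_t follows the discrete
        exponential relaxation toward the fixed point f(c) = c."""
        c = 0.7
        N = 2
        p = RNNParams(np.zeros((N, 2)), np.zeros((N, N)), np.zeros((2, N)),
                      b_rec=np.full(N, c), b_out=np.zeros(2),
                      sign_vector=np.array([1.0, -1.0]))
        batch = TrialBatch(np.array([0]), np.array([-1]), np.array([0.0]))
        _, X, _, _ = simulate_batch(p, batch, seed=0, noise_on=False)
        alpha = p.dt_ms / p.tau_ms
        T = X.shape[0]
        t = np.arange(1, T + 1)
        analytic = c * (1 - (1 - alpha) ** t)
        assert np.allclose(X[:, 0, 0], analytic, atol=1e-12)
        assert abs(X[-1, 0, 0] - c) < 1e-4

    def test_background_input_noise_sd(self):
        p = init_network(50, seed=0)
        batch = make_trial_batch(np.random.default_rng(0), 200)
        u = make_inputs(p, batch, np.random.default_rng(1))
        fix = u[:15]                       # fixation period, no pulses
        assert fix.std() == pytest.approx(0.05, rel=0.05)
        assert abs(fix.mean()) < 0.005

    def test_halving_dt_changes_outputs_below_5pct_rms(self):
        """Discretization consistency on noise-free trials."""
        outs = {}
        for dt in (10.0, 5.0):
            p = init_network(50, seed=4, dt_ms=dt)
            batch = TrialBatch(np.array([0, 1]), np.array([0, 0]),
                               np.array([0.1, 0.1]))
            _, _, _, Y = simulate_batch(p, batch, seed=0, noise_on=False)
            _, _, _, _, w0, w1 = p.timing.steps(dt)
            outs[dt] = Y[w0:w1:int(10 / dt) if dt < 10 else 1].mean(axis=0)
        rms = np.sqrt(np.mean((outs[10.0] - outs[5.0]) ** 2))
        assert rms / np.sqrt(np.mean(outs[10.0] ** 2)) < 0.05

    def test_bounded_rates_without_input(self):
        """Energy sanity: trained-style weights, no noise/input, rates stay
        bounded over 10 simulated seconds."""
        p = init_network(50, seed=5)
        timing = TaskTiming(fixation_ms=10000.0, cue_ms=0.0,
                            cue_target_soa_ms=0.0, target_ms=0.0,
                            resp_delay_ms=0.0, resp_window_ms=0.0)
        p.timing = timing
        batch = TrialBatch(np.array([0]), np.array([-1]), np.array([0.0]))
        u = np.zeros((timing.n_steps(p.dt_ms), 2, 1))
        from neurocue.rnn import _forward_full
        X, R, _, _ = _forward_full(p, u, np.zeros((u.shape[0], 50, 1)))
        assert np.abs(R).max() < 1e3


class TestTargetsAndDecoding:
    def test_catch_trial_targets_all_zero(self):
        p = init_network(50, seed=0)
        batch = TrialBatch(np.array([0]), np.array([-1]), np.array([0.0]))
        target, mask = make_training_targets(p, batch)
        assert np.all(target == 0)

    def test_left_target_sets_left_channel(self):
        p = init_network(50, seed=0)
        batch = TrialBatch(np.array([0]), np.array([0]), np.array([0.1]))
        target, mask = make_training_targets(p, batch)
        _, _, _, _, w0, w1 = p.timing.steps(p.dt_ms)
        assert np.all(target[w0:w1, 0, 0] == 1)
        assert np.all(target[:, 1, 0] == 0)

    def test_mask_sums_to_window_length_times_channels(self):
        p = init_network(50, seed=0)
        batch = TrialBatch(np.array([0, 1]), np.array([0, -1]),
                           np.array([0.1, 0.0]))
        _, mask = make_training_targets(p, batch)
        _, _, _, _, w0, w1 = p.timing.steps(p.dt_ms)
        assert mask.sum() == (w1 - w0) * 2 * 2

    def test_decode_detection_identity_on_catch(self):
        """On catch trials detection is correct exactly when not 'seen'."""
        p = init_network(50, seed=0)
        batch = make_trial_batch(np.random.default_rng(2), 200, catch_frac=1.0)
        _, _, _, Y = simulate_batch(p, batch, seed=2)
        df = decode_batch(p, batch, Y)
        assert (df.detection_correct == ~df.seen).all()


class TestTraining:
    def test_zero_learning_rate_leaves_parameters_unchanged(self):
        p = init_network(50, seed=0)
        res = train_network(p, n_iterations=3, lr=0.0, seed=0)
        assert np.array_equal(res.params.W_rec, p.W_rec)
        assert np.array_equal(res.params.W_out, p.W_out)

    def test_loss_decreases_over_short_training(self):
        """Median final/initial loss over 3 seeds falls."""
        drops = []
        for seed in range(3):
            p = init_network(50, seed=seed)
            res = train_network(p, n_iterations=500, lr=1e-2, seed=seed,
                                record_every=50)
            drops.append(res.loss_curve[-1, 1] < res.loss_curve[0, 1])
        assert sum(drops) >= 2

    def test_dale_constraint_audited_every_step(self):
        p = init_network(50, seed=1)
        res = train_network(p, n_iterations=50, lr=1e-2, seed=1,
                            audit_dale=True)
        assert res.dale_audited
        assert res.params.dale_violation() == 0.0


class TestPsychometric:
    def test_parameter_recovery_from_binomial_data(self):
        """Logistic with midpoint 0.06, slope 80 recovered within 0.01 from
        binomial rates at n=2500/level."""
        rng = np.random.default_rng(0)
        c = np.linspace(0.0, 0.13, 12)
        p_true = expit(80.0 * (c - 0.06))
        rates = rng.binomial(2500, p_true) / 2500
        fit = fit_psychometric(c, rates)
        assert abs(fit.midpoint - 0.06) < 0.01
        assert not fit.degenerate

    def test_flat_rates_flagged_degenerate(self):
        c = np.linspace(0, 0.13, 8)
        with pytest.warns(UserWarning, match="degenerate"):
            fit = fit_psychometric(c, np.full(8, 0.5))
        assert fit.degenerate

    def test_exact_logistic_interpolated(self):
        c = np.linspace(0, 0.13, 10)
        r = 0.1 + 0.8 * expit(60 * (c - 0.07))
        fit = fit_psychometric(c, r)
        assert np.abs(fit.residuals).max() < 1e-4

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError):
            fit_psychometric([0.1, 0.2, 0.3], [0.2, 0.5, 0.9])


class TestConnectionGraph:
    def test_constant_weights_give_constant_edges(self):
        p = init_network(50, seed=0)
        p.W_rec[:] = 0.02
        np.fill_diagonal(p.W_rec, 0.0)
        groups = {"a": np.arange(0, 5), "b": np.arange(5, 10)}
        g = connection_graph(p, groups)
        for _, row in g.edges.iterrows():
            assert row.mean_weight == pytest.approx(0.02)

    def test_three_unit_toy_hand_means(self):
        """Printed 3-unit weights give hand-computed group means."""
        W = np.array([[0.0, 0.5, -0.3],
                      [0.2, 0.0, -0.1],
                      [0.4, 0.6, 0.0]])
        p = RNNParams(np.zeros((3, 2)), W, np.zeros((2, 3)),
                      b_rec=np.zeros(3), b_out=np.zeros(2),
                      sign_vector=np.array([1.0, 1.0, -1.0]))
        g = connection_graph(p, {"e": np.array([0, 1]), "i": np.array([2])})
        edges = g.edges.set_index(["pre", "post"])
        # e->e: off-diagonal entries W[0,1], W[1,0] -> (0.5 + 0.2)/2
        assert edges.loc[("e", "e")].mean_weight == pytest.approx(0.35)
        # e->i: W[2, 0], W[2, 1] -> (0.4 + 0.6)/2
        assert edges.loc[("e", "i")].mean_weight == pytest.approx(0.5)
        # i->e: W[0, 2], W[1, 2] -> (-0.3 - 0.1)/2
        assert edges.loc[("i", "e")].mean_weight == pytest.approx(-0.2)

    def test_edges_from_excitatory_groups_nonnegative(self):
        p = init_network(50, seed=6)
        sol_groups = {"A_E": np.arange(0, 8), "B_E": np.arange(8, 16),
                      "C_I": np.arange(40, 45)}
        g = connection_graph(p, sol_groups)
        for _, row in g.edges.iterrows():
            if row.pre.endswith("_E"):
                assert row.mean_weight >= 0
            else:
                assert row.mean_weight <= 0


class TestLesions:
    def test_empty_lesion_bitwise_identical(self):
        p = init_network(50, seed=0)
        lp = lesion_params(p, np.array([], dtype=int))
        batch = make_trial_batch(np.random.default_rng(0), 20)
        _, _, _, Y1 = simulate_batch(p, batch, seed=7)
        _, _, _, Y2 = simulate_batch(lp, batch, seed=7)
        assert np.array_equal(Y1, Y2)

    def test_full_lesion_forces_output_to_bias(self):
        p = init_network(50, seed=0)
        p.b_out = np.array([0.3, -0.2])
        lp = lesion_params(p, np.arange(50))
        batch = make_trial_batch(np.random.default_rng(1), 10)
        _, _, _, Y = simulate_batch(lp, batch, seed=8)
        assert np.allclose(Y[:, 0, :], expit(0.3), atol=1e-12)
        assert np.allclose(Y[:, 1, :], expit(-0.2), atol=1e-12)

    def test_lesion_table_has_intact_control_with_zero_deltas(self):
        p = init_network(50, seed=2)
        table = lesion_experiment(p, {"g": np.arange(5)},
                                  contrasts=[0.05, 0.13],
                                  n_batches=3, batch=30, seed=0)
        intact = table[(table.lesion == "intact")
                       & (table.validity != "valid_vs_invalid")]
        assert len(intact) > 0
        assert np.allclose(intact.detection_delta, 0.0)


class TestPermutationTest:
    def test_hand_pearson_on_four_point_series(self):
        a = np.array([1.0, 2.0, 3.0, 5.0])
        b = np.array([2.0, 1.0, 4.0, 6.0])
        r = np.corrcoef(a, b)[0, 1]
        # hand computation via covariance/std
        r_hand = (((a - a.mean()) * (b - b.mean())).mean()
                  / (a.std() * b.std()))
        assert r == pytest.approx(r_hand, abs=1e-12)

    def test_identical_trajectories_correlate_perfectly(self):
        a = np.sin(np.linspace(0, 3, 40))
        assert np.corrcoef(a, a)[0, 1] == pytest.approx(1.0)

    def test_shifted_distribution_detected(self):
        rng = np.random.default_rng(0)
        a = rng.normal(1.0, 1.0, 200)
        b = rng.normal(0.0, 1.0, 200)
        p = permutation_pvalue_greater(a, b, n_perm=500,
                                       rng=np.random.default_rng(1))
        assert p < 0.01

    def test_null_pvalues_roughly_uniform(self):
        """p-values under a shared-noise null are uniform (KS test)."""
        from scipy.stats import kstest
        rng = np.random.default_rng(2)
        ps = []
        for _ in range(100):
            a = rng.normal(0, 1, 40)
            b = rng.normal(0, 1, 40)
            ps.append(permutation_pvalue_greater(a, b, n_perm=200, rng=rng))
        stat, p = kstest(ps, "uniform")
        assert p > 0.01
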