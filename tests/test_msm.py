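import itertools

import numpy as np
import pytest

from casdyn.msm import (
    CountMatrix,
    bayesian_sample,
    ck_test,
    count_matrix,
    estimate_msm,
    frame_weights,
    free_energy_surface,
    implied_timescales,
    kmeans,
    macrostate_transition_times,
    mfpt,
    pcca,
)
from casdyn.synthetic import (
    MarkovChainSpec,
    block_transition_matrix,
    simulate_markov_chain,
)


def model_from_counts(counts, lag=1):
    return estimate_msm(CountMatrix(np.asarray(counts), lag))


class TestKmeans:
    def test_single_center_is_global_mean(self, rng):
        pts = rng.standard_normal((200, 2))
        d = kmeans(pts, k=1, seed=0)
        assert np.allclose(d.centers[0], pts.mean(axis=0), atol=1e-9)

    def test_k_equals_points_gives_zero_inertia(self, rng):
        pts = rng.standard_normal((7, 2)) * 10
        d = kmeans(pts, k=7, seed=0)
        assert d.inertia == pytest.approx(0.0, abs=1e-9)

    def test_two_separated_clouds_recovered(self, rng):
        a = rng.standard_normal((500, 2)) + [0, 0]
        b = rng.standard_normal((500, 2)) + [20, 0]
        d = kmeans(np.vstack([a, b]), k=2, seed=1)
        centers = d.centers[np.argsort(d.centers[:, 0])]
        se = 3 / np.sqrt(500)
        assert np.allclose(centers[0], a.mean(axis=0), atol=3 * se)
        assert np.allclose(centers[1], b.mean(axis=0), atol=3 * se)

    def test_k_larger_than_points_rejected(self, rng):
        with pytest.raises(ValueError):
            kmeans(rng.standard_normal((5, 2)), k=6)


class TestCountMatrix:
    def test_hand_counted_example(self):
        cm = count_matrix([0, 0, 1], lag=1)
        assert np.array_equal(cm.counts, [[1, 1], [0, 0]])

    def test_constant_trajectory(self):
        cm = count_matrix([3] * 10, lag=1)
        assert cm.counts[3, 3] == 9
        assert cm.counts.sum() == 9

    def test_lag_equal_to_length_warns_and_zeroes(self):
        with pytest.warns(UserWarning):
            cm = count_matrix([0, 1, 0], lag=3)
        assert cm.counts.sum() == 0

    def test_multiple_trajectories_do_not_cross_boundaries(self):
        cm = count_matrix([[0, 1], [1, 0]], lag=1)
        assert cm.counts[0, 1] == 1 and cm.counts[1, 0] == 1
        assert cm.counts.sum() == 2


class TestEstimate:
    def test_symmetric_counts_give_symmetric_model(self):
        m = model_from_counts([[8, 2], [2, 8]])
        assert np.allclose(m.transition_matrix, [[0.8, 0.2], [0.2, 0.8]], atol=1e-9)
        assert np.allclose(m.stationary, [0.5, 0.5], atol=1e-9)

    def test_diagonal_counts_give_identity_and_infinite_timescale(self):
        # two disconnected absorbing states: the larger component is kept
        m = model_from_counts([[10, 0], [0, 4]])
        assert m.transition_matrix.shape == (1, 1)
        assert m.transition_matrix[0, 0] == 1.0

    def test_recovery_from_simulated_chain(self, block_chain):
        t_true, seq = block_chain
        m = estimate_msm(count_matrix(seq, 1))
        n = len(seq)
        for i in range(4):
            row_visits = np.sum(seq[:-1] == i)
            se = np.sqrt(t_true[i] * (1 - t_true[i]) / row_visits)
            assert np.all(np.abs(m.transition_matrix[i] - t_true[i]) <= 3 * se + 1e-3)

    def test_detailed_balance_holds(self, block_chain):
        _, seq = block_chain
        m = estimate_msm(count_matrix(seq, 1))
        flux = m.stationary[:, None] * m.transition_matrix
        assert np.allclose(flux, flux.T, atol=1e-10)

    def test_ergodic_flow_conservation(self, block_chain):
        _, seq = block_chain
        m = estimate_msm(count_matrix(seq, 1))
        assert np.max(np.abs(m.stationary @ m.transition_matrix - m.stationary)) < 1e-8

    def test_empty_connected_set_rejected(self):
        with pytest.raises(ValueError):
            model_from_counts(np.zeros((3, 3)))


class TestImpliedTimescales:
    def test_two_state_closed_form(self):
        # T with λ2 = 0.7 → t = −1/ln 0.7
        t = np.array([[0.85, 0.15], [0.15, 0.85]])
        counts = (t * 1000).astype(int)
        m = model_from_counts(counts)
        assert m.timescales(1)[0] == pytest.approx(-1 / np.log(0.7), abs=1e-6)

    def test_identity_chain_has_infinite_timescale(self):
        m = model_from_counts([[10, 0], [0, 4]])
        # single absorbing state: only the stationary eigenvalue remains
        assert m.eigenvalues[0] == pytest.approx(1.0)

    def test_flat_in_lag_for_markovian_chain(self, block_chain):
        _, seq = block_chain
        its = implied_timescales(seq, lags=[1, 2, 5, 10], n_its=1,
                                 n_bayes_samples=50, seed=3)
        t_ref = its[0]["timescales"][0]
        for row in its[1:]:
            lo, hi = row["ci"][0]
            assert lo <= t_ref <= hi

    def test_frame_stride_converts_to_ns(self):
        t = np.array([[0.85, 0.15], [0.15, 0.85]])
        counts = CountMatrix((t * 1000).astype(int), lag=2)
        m = estimate_msm(counts, frame_stride_ns=0.5)
        assert m.timescales(1)[0] == pytest.approx(-1.0 / np.log(0.7), abs=1e-6)


class TestBayesian:
    def test_ci_width_shrinks_with_counts(self):
        base = np.array([[90, 10], [20, 80]])
        widths = []
        for scale in (1, 1000):
            ens = bayesian_sample(CountMatrix(base * scale, 1), 200, seed=0)
            lam2 = [np.sort(np.linalg.eigvals(t).real)[0] for t in ens.samples]
            widths.append(np.quantile(lam2, 0.975) - np.quantile(lam2, 0.025))
        ratio = widths[0] / widths[1]
        assert ratio == pytest.approx(np.sqrt(1000), rel=0.5)

    def test_single_state_chain_is_degenerate(self):
        ens = bayesian_sample(CountMatrix(np.array([[5]]), 1), 10, seed=0)
        assert all(np.allclose(t, [[1.0]]) for t in ens.samples)

    def test_lambda2_ci_covers_truth(self):
        t_true = np.array([[0.9, 0.1], [0.2, 0.8]])
        lam2_true = np.sort(np.linalg.eigvals(t_true).real)[0]
        covered = 0
        reps = 20
        for rep in range(reps):
            seq = simulate_markov_chain(MarkovChainSpec(t_true, 0, seed=100 + rep), 2000)
            ens = bayesian_sample(count_matrix(seq, 1), 200, seed=rep)
            lam2 = [np.sort(np.linalg.eigvals(t).real)[0] for t in ens.samples]
            if np.quantile(lam2, 0.025) <= lam2_true <= np.quantile(lam2, 0.975):
                covered += 1
        # 95% nominal coverage; 20 Bernoulli reps ⇒ allow 15–20
        assert covered >= 15


class TestCkTest:
    def test_markovian_chain_passes(self, block_chain):
        _, seq = block_chain
        cm = count_matrix(seq, 1)
        model = estimate_msm(cm)
        ens = bayesian_sample(cm, 100, seed=2)
        grouping = pcca(model, 2)
        result = ck_test(model, ens, seq, grouping)
        assert result["passed"]

    def test_non_markovian_projection_fails(self):
        # hidden 4-state cycle observed through a 2-symbol projection:
        # the observed process has period-4 memory a lag-1 MSM cannot carry
        eps = 0.02
        t_hidden = np.array([
            [eps, 1 - eps, 0, 0],
            [0, eps, 1 - eps, 0],
            [0, 0, eps, 1 - eps],
            [1 - eps, 0, 0, eps],
        ])
        hidden = simulate_markov_chain(MarkovChainSpec(t_hidden, 0, seed=6), 20_000)
        observed = hidden // 2
        cm = count_matrix(observed, 1)
        model = estimate_msm(cm)
        ens = bayesian_sample(cm, 100, seed=7)
        grouping = pcca(model, 2)
        result = ck_test(model, ens, observed, grouping)
        assert not result["passed"]

    def test_exact_model_agrees_with_itself(self):
        t = np.array([[0.9, 0.1], [0.2, 0.8]])
        counts = (t * 100000).astype(int)
        cm = CountMatrix(counts, 1)
        model = estimate_msm(cm)
        ens = bayesian_sample(cm, 50, seed=1)
        grouping = pcca(model, 2)
        seq = simulate_markov_chain(MarkovChainSpec(t, 0, seed=9), 200_000)
        result = ck_test(model, ens, seq, grouping, factors=(2, 3))
        for pred, est in zip(result["predicted"], result["estimated"]):
            assert np.allclose(pred, est, atol=0.01)


class TestPcca:
    def test_single_macrostate_is_trivial(self, block_chain):
        _, seq = block_chain
        model = estimate_msm(count_matrix(seq, 1))
        g = pcca(model, 1)
        assert np.array_equal(g.assignments, np.zeros(4, dtype=int))
        assert np.allclose(g.memberships, 1.0)

    def test_weakly_coupled_blocks_recovered(self, block_chain):
        _, seq = block_chain
        model = estimate_msm(count_matrix(seq, 1))
        g = pcca(model, 2)
        assert g.assignments[0] == g.assignments[1]
        assert g.assignments[2] == g.assignments[3]
        assert g.assignments[0] != g.assignments[2]

    def test_block_permutation_gives_same_partition(self):
        t = block_transition_matrix(2, 2, 0.1, 1e-3)
        perm = [2, 3, 0, 1]
        t_perm = t[np.ix_(perm, perm)]
        counts = (t * 10000).astype(int)
        counts_perm = (t_perm * 10000).astype(int)
        g1 = pcca(model_from_counts(counts), 2)
        g2 = pcca(model_from_counts(counts_perm), 2)
        # partition {0,1}|{2,3} must map to {2,3}|{0,1} after permutation
        part1 = frozenset(frozenset(np.flatnonzero(g1.assignments == a))
                          for a in range(2))
        part2 = frozenset(frozenset(perm[i] for i in np.flatnonzero(g2.assignments == a))
                          for a in range(2))
        assert part1 == part2

    def test_nonreversible_model_rejected(self):
        counts = CountMatrix(np.array([[5, 5], [1, 9]]), 1)
        model = estimate_msm(counts, reversible=False)
        with pytest.raises(ValueError, match="reversible"):
            pcca(model, 2)

    def test_memberships_are_row_stochastic(self, block_chain):
        _, seq = block_chain
        model = estimate_msm(count_matrix(seq, 1))
        g = pcca(model, 2)
        assert np.allclose(g.memberships.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(g.memberships >= -1e-12)


def brute_force_mfpt(t, target, source, pi, horizon=100_000):
    """First-step recursion h = 1 + T h solved by value iteration."""
    n = t.shape[0]
    h = np.zeros(n)
    free = np.setdiff1d(np.arange(n), target)
    for _ in range(horizon):
        h_new = h.copy()
        h_new[free] = 1 + t[free] @ h
        if np.max(np.abs(h_new - h)) < 1e-12:
            h = h_new
            break
        h = h_new
    w = pi[source] / pi[source].sum()
    return float(w @ h[source])


class TestMfpt:
    def test_two_state_hand_solution(self):
        t = np.array([[0.9, 0.1], [0.2, 0.8]])
        counts = (t * 100000).astype(int)
        m = model_from_counts(counts)
        assert mfpt(m, np.array([1]), np.array([0])) == pytest.approx(10.0, abs=1e-3)
        assert mfpt(m, np.array([0]), np.array([1])) == pytest.approx(5.0, abs=1e-3)

    def test_source_inside_target_is_zero(self):
        t = np.array([[0.9, 0.1], [0.2, 0.8]])
        m = model_from_counts((t * 1000).astype(int))
        assert mfpt(m, np.array([0, 1]), np.array([0])) == 0.0

    @pytest.mark.parametrize("n_states,seed", [(3, 0), (4, 1), (5, 2), (6, 3)])
    def test_linear_solver_matches_value_iteration(self, n_states, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(1, 50, size=(n_states, n_states))
        m = model_from_counts(counts)
        t = m.transition_matrix
        for tgt in range(n_states):
            target = np.array([tgt])
            source = np.setdiff1d(np.arange(n_states), target)
            expected = brute_force_mfpt(t, target, source, m.stationary)
            assert mfpt(m, target, source) == pytest.approx(expected, abs=1e-6)

    def test_macrostate_table_diagonal_is_zero(self, block_chain):
        _, seq = block_chain
        model = estimate_msm(count_matrix(seq, 1))
        g = pcca(model, 2)
        times, rates = macrostate_transition_times(model, g)
        assert np.all(np.diag(times) == 0)
        assert times[0, 1] > 0 and times[1, 0] > 0
        assert rates[0, 1] == pytest.approx(1 / times[0, 1])


class TestFes:
    def test_single_occupied_bin_is_zero(self):
        proj = np.zeros((10, 2))
        grid = free_energy_surface(proj, np.full(10, 0.1), bins=5)
        occupied = np.isfinite(grid.free_energy)
        assert occupied.sum() == 1
        assert grid.free_energy[occupied][0] == 0.0

    def test_equal_weights_give_zero_difference(self):
        proj = np.array([[0.0, 0.0], [1.0, 1.0]])
        grid = free_energy_surface(proj, np.array([0.5, 0.5]), bins=2)
        vals = grid.free_energy[np.isfinite(grid.free_energy)]
        assert np.allclose(vals, 0.0)

    def test_asymmetric_weights_closed_form(self):
        proj = np.array([[0.0, 0.0], [1.0, 1.0]])
        grid = free_energy_surface(proj, np.array([0.73, 0.27]), bins=2)
        vals = np.sort(grid.free_energy[np.isfinite(grid.free_energy)])
        assert vals[0] == 0.0
        assert vals[1] == pytest.approx(np.log(0.73 / 0.27), abs=1e-6)

    def test_empty_projection_rejected(self):
        with pytest.raises(ValueError):
            free_energy_surface(np.zeros((0, 2)), np.zeros(0))

    def test_frame_weights_follow_stationary_distribution(self, block_chain):
        _, seq = block_chain
        model = estimate_msm(count_matrix(seq, 1))
        w = frame_weights(seq, model)
        assert w.sum() == pytest.approx(1.0)
        for i, s in enumerate(model.active_set):
            assert w[seq == s].sum() == pytest.approx(model.stationary[i], abs=1e-10)


class TestEndToEndRecovery:
    def test_chain_to_msm_to_pcca_pipeline(self, block_chain):
        t_true, seq = block_chain
        eig_true = np.sort(np.linalg.eigvals(t_true).real)[::-1]
        # one-hot featurization → k-means with k = 4 recovers the states
        onehot = np.eye(4)[seq] + 0.0
        disc = kmeans(onehot, k=4, seed=0)
        cm = count_matrix(disc.assignments, 1)
        model = estimate_msm(cm)
        assert np.allclose(model.eigenvalues[:2], eig_true[:2], atol=0.01)
        g = pcca(model, 2)
        # microstate ↔ original state mapping via the k-means centers
        state_of_center = np.argmax(disc.centers, axis=1)
        blocks = state_of_center // 2
        macro_of_block0 = g.assignments[np.flatnonzero(blocks == 0)]
        macro_of_block1 = g.assignments[np.flatnonzero(blocks == 1)]
        assert len(set(macro_of_block0)) == 1
        assert len(set(macro_of_block1)) == 1
        assert macro_of_block0[0] != macro_of_block1[0]
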