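"""Off-policy evaluation: WIS/ESS, FQE, approximate model, WDR, bootstrap."""
import numpy as np
import pytest

from proprl.behavior import estimate_behavior_policy
from proprl.ope import (
    approximate_model,
    bootstrap_compare,
    effective_sample_size,
    fqe,
    importance_weights,
    wdr,
    wis,
)
from proprl.synthetic import (
    exact_policy_value,
    sample_ground_truth_mdp,
    simulate_cohort,
)
from proprl.data import TrajectorySet


def latent_trajectory_set(cohort, mdp):
    return TrajectorySet.from_table(
        cohort.table, states=cohort.latent["latent_state"].to_numpy(), n_states=mdp.K
    )


class TestWIS:
    def test_equal_policies_give_empirical_mean_and_full_ess(self, traj_builder):
        """pi_e = pi_b: returns [100, -100, 100] -> J = 33.33, ESS = 3."""
        ts = traj_builder(
            [([0], [0], 100.0), ([0], [1], -100.0), ([1], [0], 100.0)], n_states=2
        )
        pi = np.array([[0.7, 0.3], [0.2, 0.8]])
        est = wis(ts, pi, pi, gamma=1.0)
        assert est.value == pytest.approx(100.0 / 3)
        assert est.ess == pytest.approx(3.0)
        np.testing.assert_array_equal(est.weights, 1.0)

    def test_two_trajectory_hand_example(self, traj_builder):
        """Weight ratios 2 and 1/3 with returns +100/-100:
        J = (2*100 - 100/3)/(2 + 1/3) = 500/7, ESS = 49/37."""
        ts = traj_builder([([0], [1], 100.0), ([1], [0], -100.0)], n_states=2)
        pi_b = np.array([[0.75, 0.25], [0.75, 0.25]])
        pi_e = np.array([[0.50, 0.50], [0.25, 0.75]])
        est = wis(ts, pi_e, pi_b, gamma=1.0)
        assert est.value == pytest.approx(500.0 / 7, abs=1e-9)
        assert est.ess == pytest.approx(49.0 / 37, abs=1e-9)

    def test_single_support_trajectory(self, traj_builder):
        """If pi_e puts zero mass on every observed action except one
        trajectory's, the estimate is that trajectory's return with ESS 1."""
        ts = traj_builder(
            [([0], [1], 100.0), ([0], [0], -100.0), ([0], [0], -100.0)], n_states=1
        )
        pi_b = np.array([[0.5, 0.5]])
        pi_e = np.array([[0.0, 1.0]])
        est = wis(ts, pi_e, pi_b, gamma=1.0)
        assert est.value == pytest.approx(100.0)
        assert est.ess == pytest.approx(1.0)

    def test_behavior_on_own_fitting_set_is_empirical_mean(self, traj_builder):
        rng = np.random.default_rng(0)
        trajs = [
            (
                rng.integers(0, 4, rng.integers(1, 6)).tolist(),
                rng.integers(0, 2, 6).tolist()[: rng.integers(1, 6)],
                -100.0 if rng.random() < 0.3 else 100.0,
            )
            for _ in range(50)
        ]
        trajs = [(s, (a + [0] * 6)[: len(s)], r) for s, a, r in trajs]
        ts = traj_builder(trajs, n_states=4)
        pi_b = estimate_behavior_policy(ts)
        est = wis(ts, pi_b, pi_b)
        assert est.value == pytest.approx(ts.returns(0.99).mean())
        assert est.mortality_pct == pytest.approx(ts.death.mean() * 100.0)
        assert est.ess == pytest.approx(ts.n)

    def test_undefined_behavior_probability_raises(self, traj_builder):
        ts = traj_builder([([0], [1], 100.0)], n_states=1)
        pi_b = np.array([[1.0, 0.0]])  # observed action has probability 0
        pi_e = np.array([[0.5, 0.5]])
        with pytest.raises(ValueError, match="zero probability"):
            wis(ts, pi_e, pi_b)

    def test_all_zero_weights_reported_as_failure(self, traj_builder):
        ts = traj_builder([([0], [1], 100.0)], n_states=1)
        pi_b = np.array([[0.5, 0.5]])
        pi_e = np.array([[1.0, 0.0]])
        est = wis(ts, pi_e, pi_b)
        assert est.failed and est.ess == 0.0

    def test_ess_upper_bound_and_equality_condition(self):
        rng = np.random.default_rng(1)
        w = rng.exponential(size=200)
        assert effective_sample_size(w) < 200
        assert effective_sample_size(np.full(200, 3.7)) == pytest.approx(200)

    def test_consistency_on_simulated_mdp(self):
        """WIS converges to the oracle value as the cohort grows."""
        mdp = sample_ground_truth_mdp(K=5, d=4, seed=0, effect_size=0.05)
        pi_e = 0.75 * mdp.behavior_probs + 0.25 * 0.5  # overlapping target policy
        truth = exact_policy_value(mdp, pi_e).value
        mean_errs = []
        for n in (500, 5000):
            errs = []
            for rep in range(6):
                cohort = simulate_cohort(mdp, n, seed=10 * n + rep)
                ts = latent_trajectory_set(cohort, mdp)
                est = wis(ts, pi_e, mdp.behavior_probs)
                errs.append(abs(est.value - truth))
            mean_errs.append(np.mean(errs))
        assert mean_errs[1] < mean_errs[0]
        assert mean_errs[1] < 1.5


class TestModelBasedEstimators:
    def test_fqe_one_step_cohort(self, traj_builder):
        """Deterministic one-step cohort, all alive: value = gamma * 100."""
        ts = traj_builder([([0], [0], 100.0)] * 5, n_states=1)
        pi = np.array([[1.0, 0.0]])
        assert fqe(ts, pi, gamma=0.99) == pytest.approx(99.0)
        assert fqe(ts, pi, gamma=0.0) == pytest.approx(0.0)

    def test_fqe_matches_monte_carlo_for_behavior_policy(self):
        mdp = sample_ground_truth_mdp(K=5, d=4, seed=1)
        cohort = simulate_cohort(mdp, 3000, seed=2)
        ts = latent_trajectory_set(cohort, mdp)
        pi_b_hat = estimate_behavior_policy(ts)
        val = fqe(ts, pi_b_hat)
        assert val == pytest.approx(ts.returns().mean(), abs=2.0)

    def test_approximate_model_equals_fqe_when_model_complete(self, traj_builder):
        rng = np.random.default_rng(5)
        trajs = [
            (
                rng.integers(0, 3, rng.integers(1, 5)).tolist(),
                rng.integers(0, 2, 5).tolist()[: rng.integers(1, 5)],
                -100.0 if rng.random() < 0.4 else 100.0,
            )
            for _ in range(200)
        ]
        trajs = [(s, (a + [0] * 5)[: len(s)], r) for s, a, r in trajs]
        ts = traj_builder(trajs, n_states=3)
        pi = np.full((3, 2), 0.5)
        assert approximate_model(ts, pi) == pytest.approx(fqe(ts, pi), abs=1e-6)

    def test_two_state_chain_linear_solve_by_hand(self, traj_builder):
        """s0 -> s1 -> alive deterministic under action 0: V(s0) = gamma^2*100."""
        ts = traj_builder([([0, 1], [0, 0], 100.0)] * 4, n_states=2)
        pi = np.array([[1.0, 0.0], [1.0, 0.0]])
        assert approximate_model(ts, pi, gamma=0.99) == pytest.approx(98.01)

    def test_empty_dataset_is_an_error(self, traj_builder):
        ts = traj_builder([([0], [0], 100.0)], n_states=1).subset(np.array([], int))
        with pytest.raises(ValueError):
            approximate_model(ts, np.array([[1.0, 0.0]]))

    def test_unvisited_pair_warns(self, traj_builder):
        ts = traj_builder([([0], [0], 100.0)] * 3, n_states=1)
        pi = np.array([[0.0, 1.0]])  # requires the never-tried action
        with pytest.warns(UserWarning):
            fqe(ts, pi)


def stepwise_wis_reference(ts, pi_e, pi_b, gamma):
    """Independent loop-based stepwise-WIS implementation."""
    n, T = ts.n, ts.t_max
    rho = np.ones((n, T))
    for i in range(n):
        r = 1.0
        for t in range(T):
            if t < ts.lengths[i]:
                s, a = ts.states[i, t], ts.actions[i, t]
                r *= pi_e[s, a] / pi_b[s, a]
            rho[i, t] = r
    total = 0.0
    for t in range(T):
        w = rho[:, t] / rho[:, t].sum()
        total += (gamma ** (t + 1)) * (w * ts.rewards[:, t] * ts.mask[:, t]).sum()
    return total


class TestWDR:
    def _random_cohort(self, seed, n=60):
        rng = np.random.default_rng(seed)
        trajs = []
        for _ in range(n):
            ln = int(rng.integers(1, 5))
            trajs.append(
                (
                    rng.integers(0, 3, ln).tolist(),
                    rng.integers(0, 2, ln).tolist(),
                    -100.0 if rng.random() < 0.3 else 100.0,
                )
            )
        from tests.conftest import make_trajectory_set

        return make_trajectory_set(trajs, 3)

    def test_zero_q_hat_reduces_to_stepwise_wis(self):
        ts = self._random_cohort(0)
        pi_b = np.full((3, 2), 0.5)
        rng = np.random.default_rng(1)
        p = rng.uniform(0.2, 0.8, size=3)
        pi_e = np.column_stack([1 - p, p])
        got = wdr(ts, pi_e, pi_b, np.zeros((3, 2)), gamma=0.99)
        expected = stepwise_wis_reference(ts, pi_e, pi_b, 0.99)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_single_trajectory_telescopes_to_return(self, traj_builder):
        """With weights 1 and a Bellman-consistent q_hat along the path, WDR
        returns the trajectory's return exactly."""
        ts = traj_builder([([0, 1, 2], [0, 0, 0], 100.0)], n_states=3)
        pi = np.array([[1.0, 0.0]] * 3)
        g = 0.9
        # backward Bellman recursion along the deterministic path
        q_hat = np.zeros((3, 2))
        q_hat[2, 0] = g * 100.0
        q_hat[1, 0] = g * q_hat[2, 0]
        q_hat[0, 0] = g * q_hat[1, 0]
        got = wdr(ts, pi, pi, q_hat, gamma=g)
        assert got == pytest.approx(ts.returns(g)[0], abs=1e-10)

    def test_variance_no_worse_than_wis_with_good_q(self):
        """With an accurate value model, WDR varies less than plain WIS over
        replicated small cohorts (20% slack on the variance ratio)."""
        mdp = sample_ground_truth_mdp(K=4, d=4, seed=3, effect_size=0.05)
        pi_e = 0.6 * mdp.behavior_probs + 0.4 * 0.5
        big = simulate_cohort(mdp, 5000, seed=99)
        ts_big = latent_trajectory_set(big, mdp)
        from proprl.policy_learning import estimate_mdp
        from proprl.ope import _policy_q_fixed_point

        q_hat, _, _ = _policy_q_fixed_point(ts_big, pi_e, 0.99, 1e-8, 10_000, -100.0)
        wis_vals, wdr_vals = [], []
        for rep in range(25):
            c = simulate_cohort(mdp, 300, seed=1000 + rep)
            ts = latent_trajectory_set(c, mdp)
            wis_vals.append(wis(ts, pi_e, mdp.behavior_probs).value)
            wdr_vals.append(wdr(ts, pi_e, mdp.behavior_probs, q_hat))
        assert np.var(wdr_vals) <= 1.2 * np.var(wis_vals)


class TestBootstrapCompare:
    def test_policy_against_itself_is_exact_null(self, traj_builder):
        rng = np.random.default_rng(0)
        trajs = [
            ([int(rng.integers(0, 2))], [int(rng.integers(0, 2))],
             -100.0 if rng.random() < 0.4 else 100.0)
            for _ in range(40)
        ]
        ts = traj_builder(trajs, n_states=2)
        pi_b = estimate_behavior_policy(ts)
        res = bootstrap_compare(ts, pi_b, pi_b, B=500, seed=1)
        assert res.p_value == pytest.approx(0.5)
        assert res.value_improvement == 0.0
        assert res.pct_outperformed == 0.0
        assert res.mortality_behavior_pct == pytest.approx(ts.death.mean() * 100.0)

    def test_dominant_policy_drives_p_to_zero(self, traj_builder):
        """Treated trajectories all survive, untreated all die; an always-treat
        policy then outperforms in essentially every replicate."""
        trajs = [([0], [1], 100.0)] * 20 + [([0], [0], -100.0)] * 20
        ts = traj_builder(trajs, n_states=1)
        pi_b = estimate_behavior_policy(ts)
        pi_e = np.array([[0.0, 1.0]])
        res = bootstrap_compare(ts, pi_e, pi_b, B=1000, seed=2)
        assert res.p_value < 0.01
        assert res.pct_outperformed > 95.0
        # J_e = 99 (all weight on survivors, one discount step); J_b = 0
        assert res.value_improvement == pytest.approx(99.0)

    def test_pct_outperformed_consistent_with_p(self, traj_builder):
        rng = np.random.default_rng(3)
        trajs = [
            ([int(rng.integers(0, 3))], [int(rng.integers(0, 2))],
             -100.0 if rng.random() < 0.3 else 100.0)
            for _ in range(60)
        ]
        ts = traj_builder(trajs, n_states=3)
        pi_b = estimate_behavior_policy(ts)
        pi_e = np.clip(pi_b.probs * [[0.9, 1.1]] * 1.0, 0.01, None)
        pi_e = pi_e / pi_e.sum(axis=1, keepdims=True)
        res = bootstrap_compare(ts, pi_e, pi_b, B=400, seed=4)
        n_better = res.pct_outperformed / 100.0
        n_worse_or_tied = np.mean(res.improvements <= 0)
        assert n_better + n_worse_or_tied == pytest.approx(1.0)
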