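"""Tabular MDP estimation, constrained value iteration, relaxation."""
import numpy as np
import pytest

from proprl.behavior import BehaviorPolicy, estimate_behavior_policy
from proprl.policy_learning import (
    TERMINAL_UTILITY,
    bcq_allowed,
    constrained_value_iteration,
    estimate_mdp,
    find_divergent_states,
    relax_unimportant,
    value_iteration_batch,
)


def behavior_from_p(p_treat):
    p = np.asarray(p_treat, dtype=float)
    return BehaviorPolicy(
        p_treat=p, n_state=np.full(len(p), 100.0), n_treat=100 * p, alpha=0.0
    )


def uniform_behavior(k):
    return behavior_from_p(np.full(k, 0.5))


class TestEstimateMDP:
    def test_frequency_estimate(self, traj_builder):
        """8 transitions to one successor, 2 to another -> P = (0.8, 0.2)."""
        trajs = [([0, 1], [0, 0], 100.0)] * 8 + [([0, 2], [0, 0], 100.0)] * 2
        ts = traj_builder(trajs, n_states=3)
        model = estimate_mdp(ts)
        np.testing.assert_allclose(model.transitions[0, 0, [1, 2]], [0.8, 0.2])

    def test_all_alive_makes_death_unreachable(self, traj_builder):
        trajs = [([0, 1], [1, 0], 100.0), ([1], [1], 100.0)]
        model = estimate_mdp(traj_builder(trajs, n_states=2))
        obs = model.observed
        assert model.counts_sas[obs][:, model.death_state].sum() == 0

    def test_matches_brute_force_tally(self, traj_builder):
        rng = np.random.default_rng(0)
        trajs = [
            (
                rng.integers(0, 4, rng.integers(1, 6)).tolist(),
                rng.integers(0, 2, 5).tolist()[: rng.integers(1, 6)],
                -100.0 if rng.random() < 0.5 else 100.0,
            )
            for _ in range(30)
        ]
        trajs = [(s, (a + [0] * 6)[: len(s)], r) for s, a, r in trajs]
        ts = traj_builder(trajs, n_states=4)
        model = estimate_mdp(ts)
        counts = np.zeros((4, 2, 6), dtype=int)
        for s, a, r in trajs:
            for t in range(len(s) - 1):
                counts[s[t], a[t], s[t + 1]] += 1
            counts[s[-1], a[-1], 4 if r > 0 else 5] += 1
        np.testing.assert_array_equal(model.counts_sas, counts)


class TestValueIteration:
    def test_deterministic_chain_hand_values(self, traj_builder):
        """Chain s0 -> s1 -> alive with terminal +100 and gamma 0.99:
        V(s1) = 99, V(s0) = 98.01 (geometric discounting by hand)."""
        trajs = [([0, 1], [0, 0], 100.0)] * 5
        model = estimate_mdp(traj_builder(trajs, n_states=2))
        qt = constrained_value_iteration(model, uniform_behavior(2), tau_bcq=0.0, n_min=0)
        assert qt.v[1] == pytest.approx(99.0, abs=1e-6)
        assert qt.v[0] == pytest.approx(98.01, abs=1e-6)

    def test_unconstrained_matches_linear_solve_oracle(self):
        """tau = 0, n_min = 0 reduces to plain value iteration: on random
        10-state MDPs the result must match exact policy iteration done with
        direct linear solves on the same transition table."""
        rng = np.random.default_rng(42)
        for trial in range(50):
            k = 10
            counts = rng.integers(0, 30, size=(k, 2, k + 2))
            counts[:, :, k:] += 1  # ensure some absorption
            model_counts_sa = counts.sum(axis=2)
            from proprl.policy_learning import TabularMDPModel

            model = TabularMDPModel(
                n_states=k, counts_sa=model_counts_sa, counts_sas=counts, gamma=0.99
            )
            qt = constrained_value_iteration(
                model, uniform_behavior(k), tau_bcq=0.0, n_min=0, tol=1e-10
            )
            # oracle: policy iteration with exact evaluation
            P = model.transitions
            policy = np.zeros(k, dtype=int)
            for _ in range(60):
                P_pi = P[np.arange(k), policy]
                A = np.eye(k) - 0.99 * P_pi[:, :k]
                b = 0.99 * P_pi[:, k:] @ TERMINAL_UTILITY
                V = np.linalg.solve(A, b)
                Q = 0.99 * (P[:, :, :k] @ V + P[:, :, k:] @ TERMINAL_UTILITY)
                new_policy = Q.argmax(axis=1)
                if (new_policy == policy).all():
                    break
                policy = new_policy
            np.testing.assert_allclose(qt.q, Q, atol=1e-6)

    def test_bcq_mask_thresholds(self):
        pi = behavior_from_p([0.1])  # pi_b(.|s) = (0.9, 0.1)
        assert bcq_allowed(pi, 0.3).tolist() == [[True, False]]
        assert bcq_allowed(pi, 0.05).tolist() == [[True, True]]

    def test_tau_one_only_allows_majority(self, traj_builder):
        rng = np.random.default_rng(1)
        trajs = [
            (
                rng.integers(0, 5, rng.integers(1, 5)).tolist(),
                rng.integers(0, 2, 4).tolist()[: rng.integers(1, 5)],
                100.0,
            )
            for _ in range(60)
        ]
        trajs = [(s, (a + [0] * 5)[: len(s)], r) for s, a, r in trajs]
        ts = traj_builder(trajs, n_states=5)
        pi_b = estimate_behavior_policy(ts)
        model = estimate_mdp(ts)
        qt = constrained_value_iteration(model, pi_b, tau_bcq=1.0, n_min=0)
        majority = pi_b.majority_action()
        ties = pi_b.p_treat == 0.5
        assert (qt.greedy()[~ties] == majority[~ties]).all()

    def test_pessimistic_routing_of_unseen_pair(self, traj_builder):
        """n(s,1) = 0 with n_min = 1: the untried action is valued as a direct
        transition to death, Q(s,1) = gamma * (-100)."""
        trajs = [([0], [0], 100.0)] * 10
        model = estimate_mdp(traj_builder(trajs, n_states=1))
        qt = constrained_value_iteration(model, uniform_behavior(1), n_min=1)
        assert qt.q[0, 1] == pytest.approx(-99.0, abs=1e-6)
        assert qt.q[0, 0] == pytest.approx(99.0, abs=1e-6)

    def test_pessimism_is_monotone(self, traj_builder):
        """Raising n_min never increases any Q(s,a)."""
        rng = np.random.default_rng(2)
        trajs = [
            (
                rng.integers(0, 6, rng.integers(1, 7)).tolist(),
                rng.integers(0, 2, 6).tolist()[: rng.integers(1, 7)],
                -100.0 if rng.random() < 0.2 else 100.0,
            )
            for _ in range(80)
        ]
        trajs = [(s, (a + [0] * 7)[: len(s)], r) for s, a, r in trajs]
        ts = traj_builder(trajs, n_states=6)
        pi_b = estimate_behavior_policy(ts)
        model = estimate_mdp(ts)
        prev = None
        for n_min in (0, 2, 5, 10, 50):
            qt = constrained_value_iteration(model, pi_b, n_min=n_min)
            assert np.abs(qt.q).max() <= 100.0 + 1e-9
            if prev is not None:
                assert (qt.q <= prev + 1e-9).all()
            prev = qt.q

    def test_residuals_nonincreasing_and_bounded(self, traj_builder):
        trajs = [([0, 1, 0], [0, 1, 0], -100.0), ([1, 0], [1, 1], 100.0)] * 3
        model = estimate_mdp(traj_builder(trajs, n_states=2))
        hist = []
        value_iteration_batch(
            model.transitions[None], np.ones((1, 2, 2), bool), 0.99,
            residual_history=hist,
        )
        res = np.array([h[0] for h in hist])
        assert (np.diff(res) <= 1e-12).all()

    def test_penalty_pessimism_also_monotone(self, traj_builder):
        trajs = [([0, 1], [0, 1], 100.0), ([1, 0], [1, 0], -100.0)] * 4
        model = estimate_mdp(traj_builder(trajs, n_states=2))
        pi_b = uniform_behavior(2)
        q0 = constrained_value_iteration(model, pi_b, n_min=0, pessimism="penalty").q
        q5 = constrained_value_iteration(model, pi_b, n_min=5, pessimism="penalty").q
        assert (q5 <= q0 + 1e-9).all()


class TestRelaxation:
    def _qtable(self, q, allowed=None):
        from proprl.policy_learning import QTable

        q = np.asarray(q, dtype=float)
        allowed = np.ones_like(q, bool) if allowed is None else allowed
        return QTable(q=q, allowed=allowed, iterations=1, residual=0.0, gamma=0.99)

    def test_threshold_definition(self):
        qt = self._qtable([[50.0, 50.4]])
        pi_b = behavior_from_p([0.5])
        assert relax_unimportant(qt, pi_b, delta=1.0).defer[0]
        pol = relax_unimportant(qt, pi_b, delta=0.1)
        assert not pol.defer[0]
        assert pol.recommended[0] == 1

    def test_full_relaxation_is_behavior_policy(self, traj_builder):
        """delta = inf: every state defers, so the policy's disagreement rate
        equals the behavior policy's."""
        from proprl.behavior import disagreement_rate

        rng = np.random.default_rng(3)
        trajs = [
            (rng.integers(0, 3, 3).tolist(), rng.integers(0, 2, 3).tolist(), 100.0)
            for _ in range(40)
        ]
        ts = traj_builder(trajs, n_states=3)
        pi_b = estimate_behavior_policy(ts)
        model = estimate_mdp(ts)
        qt = constrained_value_iteration(model, pi_b)
        pol = relax_unimportant(qt, pi_b, delta=np.inf)
        assert pol.defer.all()
        np.testing.assert_allclose(pol.probs, pi_b.probs)
        assert disagreement_rate(pol, ts).rate == pytest.approx(
            disagreement_rate(pi_b, ts).rate
        )

    def test_no_relaxation_is_greedy(self):
        qt = self._qtable([[10.0, 20.0], [5.0, 1.0], [3.0, 3.0]])
        pi_b = behavior_from_p([0.9, 0.1, 0.5])
        pol = relax_unimportant(qt, pi_b, delta=0.0)
        assert not pol.defer.any()
        assert pol.recommended.tolist() == [1, 0, 0]  # exact tie -> no treatment

    def test_divergence_by_agreement_likelihood(self):
        qt = self._qtable([[0.0, 10.0], [0.0, 10.0], [0.0, 10.0]])
        pi_b = behavior_from_p([0.34, 0.9, 0.2])
        pol = relax_unimportant(qt, pi_b, delta=0.0)
        pol.defer[2] = True  # force a deferring state
        div = find_divergent_states(pol, pi_b)
        assert bool(div.loc[0, "divergent"])  # recommended 1, clinicians 34%
        assert div.loc[0, "agreement_likelihood"] == pytest.approx(0.34)
        assert not bool(div.loc[1, "divergent"])  # clinicians already agree
        assert not bool(div.loc[2, "divergent"])  # deferring states never diverge
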