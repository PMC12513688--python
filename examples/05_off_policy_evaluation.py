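"""Off-policy evaluation with WIS, ESS, auxiliary estimators, and bootstrap.

Evaluates a target policy on logged data generated by a different (behavior)
policy, compares four estimators, and runs the one-sided bootstrap test
against the behavior policy, with the simulator's exact oracle as ground
truth.
"""
import numpy as np

from proprl.data import TrajectorySet
from proprl.ope import approximate_model, bootstrap_compare, fqe, wdr, wis
from proprl.synthetic import exact_policy_value, sample_ground_truth_mdp, simulate_cohort

mdp = sample_ground_truth_mdp(K=8, d=10, seed=0)
cohort = simulate_cohort(mdp, n_stays=3000, seed=1)
ts = TrajectorySet.from_table(
    cohort.table, states=cohort.latent["latent_state"].to_numpy(), n_states=mdp.K
)

# target policy: lean toward the truly better action, keep support overlap
pi_e = 0.5 * mdp.behavior_probs + 0.5 * np.eye(2)[mdp.q_true.argmax(axis=1)]
pi_e = pi_e / pi_e.sum(axis=1, keepdims=True)
truth = exact_policy_value(mdp, pi_e)

est = wis(ts, pi_e, mdp.behavior_probs, n_boot=1000, seed=2)
print(f"oracle truth:        J = {truth.value:.2f}, mortality {truth.mortality_pct:.2f}%")
print(f"WIS estimate:        J = {est.value:.2f} "
      f"(95% CI {est.ci[0]:.2f}-{est.ci[1]:.2f}), mortality {est.mortality_pct:.2f}%")
print(f"effective sample size: {est.ess:.0f} of n = {est.n}")

q_hat_value = fqe(ts, pi_e)
print(f"FQE estimate:        J = {q_hat_value:.2f}")
print(f"approximate model:   J = {approximate_model(ts, pi_e):.2f}")
from proprl.ope import _policy_q_fixed_point

q_hat, _, _ = _policy_q_fixed_point(ts, pi_e, 0.99, 1e-8, 10_000, -100.0)
print(f"weighted doubly robust: J = {wdr(ts, pi_e, mdp.behavior_probs, q_hat):.2f}")

res = bootstrap_compare(ts, pi_e, mdp.behavior_probs, B=1000, seed=3)
print(f"\nimprovement over behavior: {res.value_improvement:.2f} "
      f"(95% CI {res.value_improvement_ci[0]:.2f} to {res.value_improvement_ci[1]:.2f}, "
      f"one-sided P = {res.p_value:.3f})")
print(f"outperformed the behavior policy in {res.pct_outperformed:.1f}% of "
      f"{res.B} bootstrap replicates")
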