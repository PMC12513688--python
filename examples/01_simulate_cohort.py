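"""Simulate a synthetic inpatient cohort from a known ground-truth MDP.

Builds an environment with 10 latent health states (4 of them responsive to
treatment), samples 1,000 hospitalizations under a clinician-like behavior
policy, and prints the cohort shape next to the exact values the environment
oracle assigns to the clinician and optimal policies.
"""
import numpy as np

from proprl.synthetic import (
    exact_policy_value,
    optimal_policy,
    sample_ground_truth_mdp,
    simulate_cohort,
)

mdp = sample_ground_truth_mdp(K=10, d=20, seed=0, responsive_fraction=0.4)
cohort = simulate_cohort(mdp, n_stays=1000, seed=1)

deaths = cohort.table.groupby("stay_id")["reward"].min() < 0
steps = cohort.table.groupby("stay_id").size()
print(f"cohort: {cohort.n_stays} stays, {len(cohort.table)} decision steps")
print(f"mean decision steps per stay: {steps.mean():.2f} (max {steps.max()})")
print(f"observed in-hospital mortality: {100 * deaths.mean():.1f}%")

behavior = exact_policy_value(mdp)
best = exact_policy_value(mdp, optimal_policy(mdp))
print(f"clinician policy true value J = {behavior.value:.2f}, "
      f"true mortality {behavior.mortality_pct:.2f}%")
print(f"optimal policy   true value J = {best.value:.2f}, "
      f"true mortality {best.mortality_pct:.2f}%")
print("the gap between those two lines is what policy learning can recover")
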