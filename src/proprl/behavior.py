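"""Clinician behavior-policy estimation and validation.

The behavior policy is the per-state average observed action: a stochastic
mapping from discrete state to a Bernoulli probability of treatment. It is
used three ways downstream — as the importance-sampling denominator in
off-policy evaluation, as the constraint set for batch-constrained policy
learning, and as the fallback action distribution in deferred (unimportant)
states.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._util import policy_matrix, rng_from
from .data import TrajectorySet


@dataclass
class BehaviorPolicy:
    """Per-state treatment probabilities with the counts behind them."""

    p_treat: np.ndarray  # (k,) P(a=1 | s)
    n_state: np.ndarray  # (k,) windows observed per state
    n_treat: np.ndarray  # (k,) treated windows per state
    alpha: float  # Beta(alpha, alpha)-style smoothing pseudo-count

    @property
    def k(self) -> int:
        return len(self.p_treat)

    @property
    def probs(self) -> np.ndarray:
        """(k, 2) action-probability matrix."""
        return np.column_stack([1.0 - self.p_treat, self.p_treat])

    def majority_action(self) -> np.ndarray:
        """(k,) most frequent observed action; exact ties break to action 0."""
        return (self.p_treat > 0.5).astype(int)


def estimate_behavior_policy(trajs: TrajectorySet, alpha: float = 0.0) -> BehaviorPolicy:
    """Average observed action per state, with optional symmetric smoothing.

    ``p(1|s) = (n(s,1) + alpha) / (n(s) + 2 alpha)``; a state never observed
    gets 0.5 (the symmetric prior), regardless of ``alpha``.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    s, a = trajs.flat()
    k = trajs.n_states
    n_state = np.bincount(s, minlength=k).astype(float)
    n_treat = np.bincount(s, weights=a, minlength=k)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (n_treat + alpha) / (n_state + 2 * alpha)
    p[n_state == 0] = 0.5  # unseen state: symmetric prior (also the alpha>0 limit)
    return BehaviorPolicy(p_treat=p, n_state=n_state, n_treat=n_treat, alpha=alpha)


@dataclass
class DisagreementResult:
    rate: float
    ci_low: float
    ci_high: float
    n_windows: int


def disagreement_rate(
    policy,
    trajs: TrajectorySet,
    n_boot: int = 1000,
    seed: int = 0,
) -> DisagreementResult:
    """Mean over windows of ``1 - pi(a_observed | s)`` with a bootstrap CI.

    For a stochastic policy this is the expected rate at which an action drawn
    from the policy would mismatch the observed one; applied to the behavior
    policy itself it measures disagreement among clinicians. The CI resamples
    trajectories (not windows) with replacement.
    """
    probs = policy_matrix(policy, trajs.n_states)
    s, a = trajs.flat()
    if (s < 0).any():
        raise ValueError("trajectory contains unassigned states")
    per_window = 1.0 - probs[s, a]
    # per-trajectory sums so the bootstrap resamples whole stays
    m = trajs.mask
    pw = np.zeros_like(trajs.rewards)
    pw[m] = per_window
    traj_sum = pw.sum(axis=1)
    traj_n = trajs.lengths.astype(float)
    rate = float(traj_sum.sum() / traj_n.sum())
    rng = rng_from(seed)
    idx = rng.integers(0, trajs.n, size=(n_boot, trajs.n))
    reps = traj_sum[idx].sum(axis=1) / traj_n[idx].sum(axis=1)
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return DisagreementResult(rate=rate, ci_low=float(lo), ci_high=float(hi), n_windows=len(s))


def behavior_sanity_check(
    pi_b: BehaviorPolicy,
    held_out: TrajectorySet,
    state_aggregates=None,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Validate the fitted behavior policy on held-out data.

    Compares the importance-sampling estimate of the behavior policy's
    mortality on the held-out set against the empirical death fraction (both
    with bootstrap CIs); when the two diverge, either clinician behavior
    shifted between the splits or the states fail to encode it. Optionally
    returns per-state trend tables of the treatment probability against named
    state-aggregate features (pass a DataFrame indexed by state, e.g. the
    ``aggregates`` from :func:`proprl.states.diagnose_states`).
    """
    from .ope import wis  # local import to avoid a cycle

    if held_out.n == 0:
        raise ValueError("held-out set is empty")
    est = wis(
        held_out, pi_b, pi_b, return_kind="death_indicator", n_boot=n_boot, seed=seed
    )
    death = held_out.death
    rng = rng_from(seed)
    idx = rng.integers(0, held_out.n, size=(n_boot, held_out.n))
    emp_reps = death[idx].mean(axis=1) * 100.0
    report = {
        "estimated_mortality_pct": est.mortality_pct,
        "estimated_mortality_ci": est.ci,
        "empirical_mortality_pct": float(death.mean() * 100.0),
        "empirical_mortality_ci": (
            float(np.percentile(emp_reps, 2.5)),
            float(np.percentile(emp_reps, 97.5)),
        ),
        "ess": est.ess,
        "n": held_out.n,
    }
    if state_aggregates is not None:
        trend = state_aggregates.copy()
        trend["p_treat"] = pi_b.p_treat[: len(trend)]
        report["trend_table"] = trend
    return report
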