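"""Ground-truth validation studies of the full pipeline.

These are the package's own end-to-end checks: cohorts are simulated from a
known MDP, the complete pipeline (partitioning, state learning, behavior
estimation, constrained policy learning, SSR selection, held-out WIS
evaluation) is run on them, and the resulting policies are scored against
the exact-evaluation oracle. Problem sizes are deliberately modest — 10
latent states, 20 features, 2,000 development and 2,000 test stays, a k grid
of {5, 10, 20} over 5 partitions — so that a replicate runs in seconds while
still exercising every pipeline stage.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from ._util import child_seeds
from .behavior import estimate_behavior_policy
from .data import TrajectorySet
from .ope import bootstrap_compare
from .pipeline import PipelineConfig, run_pipeline
from .synthetic import (
    compose_policy,
    exact_policy_value,
    sample_ground_truth_mdp,
    simulate_cohort,
)

#: study conditions for the policy-recovery experiment
STUDY_ENV = dict(K=10, d=20, responsive_fraction=0.4, effect_size=0.05, epsilon=0.3)
STUDY_N_DEV = 2000
STUDY_N_TEST = 2000
STUDY_KS = (5, 10, 20)
STUDY_N_PARTITIONS = 5


def study_config(seed: int, B: int = 1000) -> PipelineConfig:
    """Reduced-grid pipeline configuration used by the recovery study."""
    return PipelineConfig(
        ks=STUDY_KS,
        n_partitions=STUDY_N_PARTITIONS,
        ensemble_runs=3,
        subsample_cap=1000,
        embedding_dim=8,
        B=B,
        seed=seed,
    )


@dataclass
class RecoveryResult:
    """Oracle-scored outcome of one pipeline replicate."""

    seed: int
    status: str
    true_value_behavior: float = np.nan
    true_value_learned: float = np.nan
    true_improvement: float = np.nan
    true_mortality_behavior_pct: float = np.nan
    true_mortality_learned_pct: float = np.nan
    wis_value_learned: float = np.nan
    wis_ci: tuple | None = None
    ci_covers_oracle: bool = False
    ess_fraction: float = np.nan
    unimportant_fraction: float = np.nan
    pct_outperformed: float = np.nan
    selected: dict | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def run_recovery_replicate(
    seed: int,
    effect_size: float = STUDY_ENV["effect_size"],
    n_dev: int = STUDY_N_DEV,
    n_test: int = STUDY_N_TEST,
    B: int = 1000,
) -> RecoveryResult:
    """Simulate a cohort, run the full pipeline, score it against the oracle.

    Returns the true (oracle) values of the behavior and final learned
    policies, whether the learned policy's 95% bootstrap WIS interval covers
    its oracle value, and the fraction of states the final policy defers in.
    """
    s_mdp, s_dev, s_test, s_pipe, s_comp = child_seeds(seed, 5)
    env = {**STUDY_ENV, "effect_size": effect_size}
    mdp = sample_ground_truth_mdp(seed=s_mdp, **env)
    dev = simulate_cohort(mdp, n_dev, seed=s_dev)
    test = simulate_cohort(mdp, n_test, seed=s_test)

    result = run_pipeline(study_config(s_pipe, B=B), dev.table, test.table)
    if result.status != "ok":
        return RecoveryResult(seed=seed, status=result.status)

    final = result.final
    composed = compose_policy(
        mdp, final.state_definition, final.policy.probs, n_samples=4000, seed=s_comp
    )
    oracle_learned = exact_policy_value(mdp, composed)
    oracle_behavior = exact_policy_value(mdp)  # true clinician policy
    ev = result.evaluation
    ci = ev["value_learned_ci"]
    covers = ci is not None and ci[0] <= oracle_learned.value <= ci[1]
    return RecoveryResult(
        seed=seed,
        status="ok",
        true_value_behavior=oracle_behavior.value,
        true_value_learned=oracle_learned.value,
        true_improvement=oracle_learned.value - oracle_behavior.value,
        true_mortality_behavior_pct=oracle_behavior.mortality_pct,
        true_mortality_learned_pct=oracle_learned.mortality_pct,
        wis_value_learned=ev["value_learned"],
        wis_ci=ci,
        ci_covers_oracle=bool(covers),
        ess_fraction=ev["ess_learned"] / ev["n_test"],
        unimportant_fraction=float(final.policy.defer.mean()),
        pct_outperformed=ev["pct_outperformed"],
        selected=final.provenance["point"],
    )


def recovery_study(seeds, effect_size: float = STUDY_ENV["effect_size"], **kw):
    """Run :func:`run_recovery_replicate` over a list of seeds."""
    return [run_recovery_replicate(s, effect_size=effect_size, **kw) for s in seeds]


def bootstrap_null_calibration(seed: int, n_stays: int = 500, B: int = 1000) -> float:
    """One-sided bootstrap P for a policy compared against itself.

    Simulates a cohort, estimates the behavior policy on the latent states,
    and runs the paired bootstrap test of that policy against itself — the
    exact null of 'no improvement'. With ties split, the P value sits at 0.5.
    """
    s_mdp, s_cohort, s_boot = child_seeds(seed, 3)
    mdp = sample_ground_truth_mdp(seed=s_mdp, **STUDY_ENV)
    cohort = simulate_cohort(mdp, n_stays, seed=s_cohort)
    ts = TrajectorySet.from_table(
        cohort.table, states=cohort.latent["latent_state"].to_numpy(), n_states=mdp.K
    )
    pi_b = estimate_behavior_policy(ts)
    res = bootstrap_compare(ts, pi_b, pi_b, B=B, seed=s_boot)
    return res.p_value
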