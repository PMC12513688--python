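"""Ground-truth MDP cohort simulator and exact-evaluation oracle.

The simulator emulates the structure of an inpatient cohort used for offline
policy learning: a latent-state Markov process with absorbing discharge/death
outcomes, a binary daily treatment whose only causal effect is on the death
hazard of "responsive" states, Gaussian feature emissions per latent state,
and a stochastic clinician-like behavior policy (an epsilon-mixture of a
softmax over true action values and uniform noise, giving full support
overlap for importance sampling). Horizons are capped at 10 decision points;
a patient still hospitalized at the cap is scored as discharged alive.

Because the generating MDP is known, any policy over the latent states can be
evaluated *exactly* by backward induction (:func:`exact_policy_value`), and a
policy defined on learned discrete states can be mapped onto the latent
states through the feature emissions (:func:`compose_policy`). Together these
provide the ground truth that the learning pipeline is tested against.

Default hazards are calibrated to the cohort shape the pipeline targets:
~5-6% in-hospital mortality and mean stays of ~5 decision points under the
clinician-like behavior policy.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import child_seeds, rng_from

DEFAULT_HORIZON = 10


@dataclass
class GroundTruthMDP:
    """Known latent-state environment generating synthetic cohorts."""

    K: int
    d: int
    transitions: np.ndarray  # (K, K) continuation kernel (action-independent)
    death_hazard: np.ndarray  # (K, 2)
    discharge_hazard: np.ndarray  # (K, 2)
    emission_means: np.ndarray  # (K, d)
    emission_sd: np.ndarray  # (K,)
    initial_dist: np.ndarray  # (K,)
    behavior_probs: np.ndarray  # (K, 2)
    responsive: np.ndarray  # (K,) bool
    good_action: np.ndarray  # (K,) int
    epsilon: float
    temperature: float
    horizon: int = DEFAULT_HORIZON
    carryover: float = 0.0
    carryover_direction: np.ndarray | None = None
    seed: int = 0
    q_true: np.ndarray | None = field(default=None, repr=False)

    def continue_prob(self) -> np.ndarray:
        return 1.0 - self.death_hazard - self.discharge_hazard


def _true_q(
    transitions: np.ndarray,
    death: np.ndarray,
    discharge: np.ndarray,
    gamma: float = 0.99,
    tol: float = 1e-10,
) -> np.ndarray:
    """Stationary optimal action values (used to shape the behavior policy)."""
    K = transitions.shape[0]
    cont = 1.0 - death - discharge
    Q = np.zeros((K, 2))
    for _ in range(100_000):
        V = Q.max(axis=1)
        Q_new = gamma * (100.0 * discharge - 100.0 * death + cont * (transitions @ V)[:, None])
        if np.abs(Q_new - Q).max() < tol:
            return Q_new
        Q = Q_new
    raise RuntimeError("true-Q value iteration failed to converge")


def sample_ground_truth_mdp(
    K: int = 10,
    d: int = 20,
    seed: int = 0,
    responsive_fraction: float = 0.4,
    effect_size: float = 0.05,
    base_death_range: tuple[float, float] = (0.004, 0.02),
    discharge_range: tuple[float, float] = (0.10, 0.25),
    epsilon: float = 0.3,
    temperature: float = 5.0,
    emission_separation: float = 6.0,
    emission_sd: float = 1.0,
    carryover: float = 0.0,
    transition_concentration: float = 1.5,
    horizon: int = DEFAULT_HORIZON,
) -> GroundTruthMDP:
    """Draw a random but reproducible ground-truth environment.

    ``effect_size`` is the per-step death-hazard difference between the worse
    and better action in responsive states (0 gives a null environment where
    no action has any effect); ``responsive_fraction`` controls how many
    states respond to treatment at all. Emission centers are rescaled so the
    closest pair sits ``emission_separation`` standard deviations apart.
    """
    if K < 2 or d < 2:
        raise ValueError("need K >= 2 latent states and d >= 2 features")
    if not 0.0 <= responsive_fraction <= 1.0:
        raise ValueError("responsive_fraction must lie in [0, 1]")
    if effect_size < 0:
        raise ValueError("effect_size must be >= 0")
    rng = rng_from(seed)

    transitions = rng.dirichlet(np.full(K, transition_concentration), size=K)
    base_death = rng.uniform(*base_death_range, size=K)
    discharge = rng.uniform(*discharge_range, size=K)

    n_resp = int(round(responsive_fraction * K)) if effect_size > 0 else 0
    responsive = np.zeros(K, dtype=bool)
    responsive[rng.choice(K, size=n_resp, replace=False)] = True
    good_action = rng.integers(0, 2, size=K)

    death = np.repeat(base_death[:, None], 2, axis=1)
    bad = 1 - good_action
    death[responsive, bad[responsive]] += effect_size
    discharge_h = np.repeat(discharge[:, None], 2, axis=1)
    if (death + discharge_h).max() >= 1.0:
        raise ValueError("hazards sum to >= 1 for some state-action pair")

    means = rng.normal(size=(K, d))
    pd2 = ((means[:, None] - means[None, :]) ** 2).sum(axis=2)
    np.fill_diagonal(pd2, np.inf)
    min_dist = np.sqrt(pd2.min())
    means *= emission_separation * emission_sd / min_dist
    sds = np.full(K, emission_sd)

    q_true = _true_q(transitions, death, discharge_h)
    if temperature > 0:
        z = (q_true - q_true.max(axis=1, keepdims=True)) / temperature
        soft = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
    else:
        soft = np.eye(2)[q_true.argmax(axis=1)]
    behavior = epsilon * 0.5 + (1.0 - epsilon) * soft

    initial = rng.dirichlet(np.full(K, 5.0))
    direction = rng.normal(size=d)
    direction /= np.linalg.norm(direction)
    return GroundTruthMDP(
        K=K, d=d, transitions=transitions, death_hazard=death,
        discharge_hazard=discharge_h, emission_means=means, emission_sd=sds,
        initial_dist=initial, behavior_probs=behavior, responsive=responsive,
        good_action=good_action, epsilon=epsilon, temperature=temperature,
        horizon=horizon, carryover=carryover, carryover_direction=direction,
        seed=seed if isinstance(seed, int) else 0, q_true=q_true,
    )


@dataclass
class SyntheticCohort:
    """Simulated cohort in the canonical decision-step table format."""

    table: pd.DataFrame  # stay_id, t, f0..f{d-1}, action, reward, terminal_flag
    latent: pd.DataFrame  # stay_id, t, latent_state (diagnostics only)
    seed: int
    n_stays: int

    def to_files(self, table_path, latent_path=None) -> None:
        from .windows import write_table

        write_table(self.table, table_path)
        if latent_path is not None:
            write_table(self.latent, latent_path)


def simulate_cohort(
    mdp: GroundTruthMDP,
    n_stays: int,
    seed: int = 0,
    policy: np.ndarray | None = None,
) -> SyntheticCohort:
    """Sample hospitalizations from the environment under a latent-state policy.

    The default policy is the environment's clinician-like behavior policy.
    Each decision step emits a feature vector from the current latent state's
    Gaussian, an action drawn from the policy, and a terminal reward of +100
    (discharge, or still in hospital at the horizon cap) or -100 (death).
    """
    if n_stays < 1:
        raise ValueError("n_stays must be >= 1")
    rng = rng_from(seed)
    probs = mdp.behavior_probs if policy is None else np.asarray(policy, dtype=float)
    H, K, d = mdp.horizon, mdp.K, mdp.d
    cum_T = np.cumsum(mdp.transitions, axis=1)

    state = rng.choice(K, size=n_stays, p=mdp.initial_dist)
    prev_action = np.zeros(n_stays, dtype=int)
    active = np.ones(n_stays, dtype=bool)
    cols_stay, cols_t, cols_s, cols_a, cols_r, cols_x = [], [], [], [], [], []
    outcome_death = np.zeros(n_stays, dtype=bool)
    last_step = np.zeros(n_stays, dtype=int)

    for t in range(H):
        idx = np.flatnonzero(active)
        if len(idx) == 0:
            break
        s = state[idx]
        x = mdp.emission_means[s] + mdp.emission_sd[s][:, None] * rng.normal(
            size=(len(idx), d)
        )
        if mdp.carryover:
            x += mdp.carryover * prev_action[idx][:, None] * mdp.carryover_direction
        a = (rng.random(len(idx)) < probs[s, 1]).astype(int)
        u = rng.random(len(idx))
        death = u < mdp.death_hazard[s, a]
        disch = (~death) & (u < mdp.death_hazard[s, a] + mdp.discharge_hazard[s, a])
        cont = ~(death | disch)
        if t == H - 1:
            disch = disch | cont  # horizon cap: survivors scored alive
            cont[:] = False

        cols_stay.append(idx)
        cols_t.append(np.full(len(idx), t))
        cols_s.append(s)
        cols_a.append(a)
        r = np.where(death, -100.0, np.where(disch, 100.0, 0.0))
        cols_r.append(r)
        cols_x.append(x)

        outcome_death[idx[death]] = True
        last_step[idx] = t
        active[idx[death | disch]] = False
        nxt = idx[cont]
        if len(nxt):
            rdraw = rng.random(len(nxt))
            state[nxt] = (rdraw[:, None] > cum_T[state[nxt]]).sum(axis=1)
        prev_action[idx] = a

    stay = np.concatenate(cols_stay)
    tt = np.concatenate(cols_t)
    feats = np.concatenate(cols_x, axis=0)
    df = pd.DataFrame(feats, columns=[f"f{j}" for j in range(d)])
    df.insert(0, "t", tt)
    df.insert(0, "stay_id", stay)
    df["action"] = np.concatenate(cols_a)
    df["reward"] = np.concatenate(cols_r)
    df = df.sort_values(["stay_id", "t"], kind="stable").reset_index(drop=True)
    df["terminal_flag"] = (df["t"] == df.groupby("stay_id")["t"].transform("max")).astype(int)
    latent = pd.DataFrame(
        {"stay_id": stay, "t": tt, "latent_state": np.concatenate(cols_s)}
    ).sort_values(["stay_id", "t"], kind="stable").reset_index(drop=True)
    return SyntheticCohort(
        table=df, latent=latent,
        seed=seed if isinstance(seed, int) else 0, n_stays=n_stays,
    )


@dataclass
class ExactValue:
    value: float
    mortality_pct: float


def exact_policy_value(
    mdp: GroundTruthMDP, policy: np.ndarray | None = None, gamma: float = 0.99
) -> ExactValue:
    """Exact finite-horizon evaluation of a latent-state policy.

    Backward induction over the horizon: terminal rewards are received on
    arrival at the absorbing outcome (a certain one-step discharge is worth
    ``gamma * 100``), and survivors at the horizon cap count as discharged
    alive. Also returns the exact probability of absorption into death, as a
    percentage.
    """
    probs = mdp.behavior_probs if policy is None else np.asarray(policy, dtype=float)
    if probs.shape != (mdp.K, 2):
        raise ValueError(f"policy must have shape ({mdp.K}, 2)")
    d, q = mdp.death_hazard, mdp.discharge_hazard
    c = mdp.continue_prob()
    W = None  # value-to-go after the last step
    M = None
    for t in range(mdp.horizon - 1, -1, -1):
        if W is None:
            cont_val = np.full(mdp.K, 100.0)  # horizon cap: alive
            cont_mort = np.zeros(mdp.K)
        else:
            cont_val = mdp.transitions @ W
            cont_mort = mdp.transitions @ M
        W_sa = gamma * (100.0 * q - 100.0 * d + c * cont_val[:, None])
        M_sa = d + c * cont_mort[:, None]
        W = (probs * W_sa).sum(axis=1)
        M = (probs * M_sa).sum(axis=1)
    return ExactValue(
        value=float(mdp.initial_dist @ W),
        mortality_pct=float(mdp.initial_dist @ M * 100.0),
    )


def compose_policy(
    mdp: GroundTruthMDP,
    state_definition,
    probs: np.ndarray,
    n_samples: int = 4000,
    seed: int = 0,
) -> np.ndarray:
    """Marginalize a learned-state policy onto the latent states.

    For each latent state, samples feature emissions, maps them through the
    state definition, and averages the policy's action distribution over the
    induced learned-state distribution. Exact up to Monte-Carlo error when
    emissions depend only on the current latent state (no carryover).
    """
    from ._util import policy_matrix

    pmat = policy_matrix(probs)
    rng = rng_from(seed)
    out = np.empty((mdp.K, 2))
    for s in range(mdp.K):
        x = mdp.emission_means[s] + mdp.emission_sd[s] * rng.normal(
            size=(n_samples, mdp.d)
        )
        learned = state_definition.assign(x)
        out[s] = pmat[learned].mean(axis=0)
    return out


def optimal_policy(mdp: GroundTruthMDP) -> np.ndarray:
    """Greedy one-hot policy on the environment's true action values."""
    return np.eye(2)[mdp.q_true.argmax(axis=1)]
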