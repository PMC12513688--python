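"""Tabular MDP estimation and constrained policy learning.

The patient environment is a finite MDP over ``k`` learned states plus two
absorbing terminal states (discharged-alive, died). Transition probabilities
are maximum-likelihood frequencies of observed (state, action, next-state)
tuples; the terminal reward (+100 alive / -100 death) is received on arrival
at the absorbing state, so backups take the form
``Q(s,a) = gamma * sum_s' P(s'|s,a) * (R(s') + V(s'))`` with ``V`` zero at
terminals.

Policy learning is value iteration with two offline-RL safeguards against
extrapolation error:

* batch-constrained Q-learning (BCQ): only actions with behavior probability
  at least ``tau_bcq`` times the state's most likely behavior action may be
  selected or backed up;
* pessimism (pMDP): state-action pairs visited fewer than ``n_min`` times are
  treated as leading straight to the death terminal (or, alternatively,
  penalized proportionally to ``1/sqrt(n(s,a))``).

A learned policy is then *relaxed*: in states where the spread of Q over the
allowed actions is below a threshold ``delta`` no action materially changes
the outcome, so the policy defers to the clinician (acts as the behavior
policy) there and only issues recommendations in the remaining states.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import policy_matrix
from .data import TrajectorySet

TERMINAL_UTILITY = np.array([100.0, -100.0])  # arrival reward at (alive, death)


@dataclass
class TabularMDPModel:
    """Counts and ML transition estimates over k states + 2 terminals."""

    n_states: int
    counts_sa: np.ndarray  # (k, 2)
    counts_sas: np.ndarray  # (k, 2, k+2); columns k, k+1 are alive, death
    gamma: float = 0.99

    @property
    def alive_state(self) -> int:
        return self.n_states

    @property
    def death_state(self) -> int:
        return self.n_states + 1

    @property
    def observed(self) -> np.ndarray:
        """(k, 2) bool: was this state-action pair ever visited?"""
        return self.counts_sa > 0

    @property
    def transitions(self) -> np.ndarray:
        """(k, 2, k+2) ML transition probabilities.

        Rows of never-observed pairs are undefined under maximum likelihood;
        they are completed by routing to the death terminal, which is what the
        pessimism constraint prescribes for unknown regions.
        """
        P = np.zeros_like(self.counts_sas, dtype=float)
        obs = self.observed
        P[obs] = self.counts_sas[obs] / self.counts_sa[obs][:, None]
        P[~obs, self.death_state] = 1.0
        return P


def estimate_mdp(trajs: TrajectorySet, gamma: float = 0.99) -> TabularMDPModel:
    """Maximum-likelihood tabular MDP from decision-step trajectories.

    Within-stay transitions feed ``(s_t, a_t) -> s_{t+1}``; the final step of
    every trajectory transitions into the alive or death absorbing state
    according to its terminal reward.
    """
    k = trajs.n_states
    counts = np.zeros((k, 2, k + 2), dtype=np.int64)
    S, A, L = trajs.states, trajs.actions, trajs.lengths
    m = trajs.mask
    inner = m & (np.arange(trajs.t_max)[None, :] < (L - 1)[:, None])
    np.add.at(counts, (S[inner], A[inner], S[np.roll(inner, 1, axis=1)]), 1)
    last = np.arange(trajs.n), L - 1
    terminal_idx = np.where(trajs.terminal_reward > 0, k, k + 1)
    np.add.at(counts, (S[last], A[last], terminal_idx), 1)
    return TabularMDPModel(
        n_states=k, counts_sa=counts.sum(axis=2), counts_sas=counts, gamma=gamma
    )


def bcq_allowed(pi_b, tau_bcq: float) -> np.ndarray:
    """(k, 2) BCQ mask: a allowed iff pi_b(a|s) >= tau * max_a' pi_b(a'|s)."""
    probs = policy_matrix(pi_b)
    if not 0.0 <= tau_bcq <= 1.0:
        raise ValueError("tau_bcq must lie in [0, 1]")
    allowed = probs >= tau_bcq * probs.max(axis=1, keepdims=True)
    assert allowed.any(axis=1).all()  # the behavior-majority action always qualifies
    return allowed


@dataclass
class QTable:
    """Converged state-action values with the mask they were optimized under."""

    q: np.ndarray  # (k, 2)
    allowed: np.ndarray  # (k, 2) bool
    iterations: int
    residual: float
    gamma: float

    @property
    def v(self) -> np.ndarray:
        return np.where(self.allowed, self.q, -np.inf).max(axis=1)

    def greedy(self) -> np.ndarray:
        """(k,) argmax over allowed actions; ties break to action 0."""
        qa = np.where(self.allowed, self.q, -np.inf)
        return (qa[:, 1] > qa[:, 0]).astype(int)

    def spread(self) -> np.ndarray:
        """(k,) max-min gap of Q over allowed actions (0 if one action allowed)."""
        qa = np.where(self.allowed, self.q, np.nan)
        return np.nan_to_num(np.nanmax(qa, axis=1) - np.nanmin(qa, axis=1))


def _effective_transitions(model: TabularMDPModel, n_min: int) -> np.ndarray:
    """Transitions with under-visited pairs routed to the death terminal."""
    P = model.transitions
    weak = model.counts_sa < n_min
    if weak.any():
        P = P.copy()
        P[weak] = 0.0
        P[weak, model.death_state] = 1.0
    return P


def value_iteration_batch(
    P: np.ndarray,
    allowed: np.ndarray,
    gamma: float,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    penalty: np.ndarray | None = None,
    q_init: np.ndarray | None = None,
    residual_history: list | None = None,
) -> tuple[np.ndarray, int, np.ndarray]:
    """Masked value iteration over a stacked batch of tabular problems.

    ``P`` has shape (B, k, 2, k+2) with the last two next-state columns being
    the alive/death terminals; ``allowed`` is (B, k, 2). Returns (Q, iterations,
    final residual per batch member). A single problem is just a batch of one.
    """
    B, k = P.shape[0], P.shape[1]
    U_term = TERMINAL_UTILITY
    Q = np.zeros((B, k, 2)) if q_init is None else q_init.copy()
    pen = 0.0 if penalty is None else penalty
    U = np.empty((B, k + 2))
    U[:, k:] = U_term[None, :]
    residual = np.full(B, np.inf)
    for it in range(1, max_iter + 1):
        V = np.where(allowed, Q, -np.inf).max(axis=2)
        U[:, :k] = V
        Q_new = gamma * np.einsum("bkas,bs->bka", P, U) - pen
        residual = np.abs(Q_new - Q).reshape(B, -1).max(axis=1)
        if residual_history is not None:
            residual_history.append(residual.copy())
        Q = Q_new
        if (residual < tol).all():
            return Q, it, residual
    raise RuntimeError(
        f"value iteration did not converge in {max_iter} iterations "
        f"(max residual {residual.max():.3g})"
    )


def constrained_value_iteration(
    model: TabularMDPModel,
    pi_b,
    tau_bcq: float = 0.0,
    n_min: int = 0,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    pessimism: str = "route",
) -> QTable:
    """Value iteration under BCQ action masking and count-based pessimism.

    ``pessimism='route'`` (default) sends state-action pairs with fewer than
    ``n_min`` visits to the death terminal; ``pessimism='penalty'`` instead
    subtracts ``n_min / sqrt(n(s,a))`` from the backup (same knob, softer
    form). Iterates until the sup-norm change in Q falls below ``tol``.
    """
    if n_min < 0:
        raise ValueError("n_min must be >= 0")
    allowed = bcq_allowed(pi_b, tau_bcq)
    if pessimism == "route":
        P = _effective_transitions(model, n_min)
        penalty = None
    elif pessimism == "penalty":
        P = model.transitions
        penalty = (n_min / np.sqrt(np.maximum(model.counts_sa, 1)))[None]
    else:
        raise ValueError("pessimism must be 'route' or 'penalty'")
    Q, iters, residual = value_iteration_batch(
        P[None], allowed[None], model.gamma, tol=tol, max_iter=max_iter, penalty=penalty
    )
    return QTable(
        q=Q[0], allowed=allowed, iterations=iters, residual=float(residual[0]),
        gamma=model.gamma,
    )


@dataclass
class LearnedPolicy:
    """Recommended action per state, with a defer mask over unimportant states."""

    recommended: np.ndarray  # (k,) int
    defer: np.ndarray  # (k,) bool
    allowed: np.ndarray  # (k, 2) bool
    behavior_probs: np.ndarray  # (k, 2)
    qtable: QTable | None = None
    hyperparams: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.recommended)

    @property
    def probs(self) -> np.ndarray:
        """(k, 2) effective action distribution: one-hot, or pi_b where deferring."""
        onehot = np.eye(2)[self.recommended]
        return np.where(self.defer[:, None], self.behavior_probs, onehot)

    def to_frame(self) -> pd.DataFrame:
        div = find_divergent_states(self, self.behavior_probs)
        return div

    def save(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def relax_unimportant(qtable: QTable, pi_b, delta: float) -> LearnedPolicy:
    """Defer to clinicians in states where no allowed action matters.

    A state is unimportant iff the spread of Q over its allowed actions is
    strictly below ``delta``: ``delta=0`` relaxes nothing, ``delta=inf``
    defers everywhere (the policy becomes the behavior policy).
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    probs = policy_matrix(pi_b)
    defer = qtable.spread() < delta
    return LearnedPolicy(
        recommended=qtable.greedy(),
        defer=defer,
        allowed=qtable.allowed,
        behavior_probs=probs,
        qtable=qtable,
        hyperparams={"delta": delta},
    )


def find_divergent_states(policy: LearnedPolicy, pi_b) -> pd.DataFrame:
    """Non-deferring states whose recommendation opposes the behavior majority.

    A state is divergent iff the policy does not defer there and the behavior
    policy takes the recommended action less than half the time (agreement
    likelihood ``pi_b(recommended | s) < 0.5``). Deferring states are never
    divergent. Returns one row per state with the agreement likelihood.
    """
    probs = policy_matrix(pi_b, policy.k)
    agree = probs[np.arange(policy.k), policy.recommended]
    divergent = (~policy.defer) & (agree < 0.5)
    return pd.DataFrame(
        {
            "state": np.arange(policy.k),
            "recommended": policy.recommended,
            "defer": policy.defer,
            "agreement_likelihood": agree,
            "divergent": divergent,
        }
    )
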