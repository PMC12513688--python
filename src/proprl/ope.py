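"""Off-policy evaluation of discrete-state treatment policies.

The workhorse estimator is weighted (self-normalized) importance sampling:
each trajectory gets the weight ``w_i = prod_t pi_e(a_t|s_t) / pi_b(a_t|s_t)``
and the policy value is the weighted mean of trajectory returns. The same
weights applied to the in-hospital death indicator give the policy's
estimated mortality, so evaluating the behavior policy on its own fitting
data reproduces the empirical mortality exactly. The effective sample size
``ESS = (sum w)^2 / sum w^2`` measures how much data actually supports the
estimate.

Three auxiliary estimators are provided for robustness checks: fitted Q
evaluation (FQE), an approximate-model (plug-in) estimate, and the weighted
doubly robust (WDR) combination of stepwise importance weights with a
value-function control variate. Policy comparisons use a one-sided bootstrap
resampling test over whole trajectories.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._util import policy_matrix, rng_from
from .data import TrajectorySet
from .policy_learning import estimate_mdp, TERMINAL_UTILITY

logger = logging.getLogger(__name__)


@dataclass
class OPEEstimate:
    """One policy-value estimate with its weights and confidence summary."""

    value: float
    mortality_pct: float
    weights: np.ndarray
    ess: float
    n: int
    estimator: str
    ci: tuple[float, float] | None = None
    mortality_ci: tuple[float, float] | None = None
    failed: bool = False


def importance_weights(trajs: TrajectorySet, pi_e, pi_b) -> np.ndarray:
    """Per-trajectory products of per-step probability ratios.

    A step where the evaluated policy puts zero mass on the observed action
    zeroes the whole trajectory weight. A step where the *behavior* policy has
    zero estimated probability for an action it demonstrably took (possible
    only off the fitting set) is an error, since the ratio is undefined.
    """
    pe = policy_matrix(pi_e, trajs.n_states)
    pb = policy_matrix(pi_b, trajs.n_states)
    if np.array_equal(pe, pb):  # equal policies: every ratio is identically 1
        return np.ones(trajs.n)
    m = trajs.mask
    s = np.where(m, trajs.states, 0)
    a = trajs.actions
    num, den = pe[s, a], pb[s, a]
    bad = m & (den <= 0.0) & (num > 0.0)
    if bad.any():
        raise ValueError(
            "behavior policy assigns zero probability to an observed action; "
            "refit with smoothing (alpha > 0) to evaluate this policy"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(num == 0.0, 0.0, num / np.where(den > 0, den, 1.0))
    ratio = np.where(m, ratio, 1.0)
    return ratio.prod(axis=1)


def effective_sample_size(weights: np.ndarray) -> float:
    w = np.asarray(weights, dtype=float)
    denom = (w**2).sum()
    return float(w.sum() ** 2 / denom) if denom > 0 else 0.0


def wis(
    trajs: TrajectorySet,
    pi_e,
    pi_b,
    gamma: float = 0.99,
    return_kind: str = "discounted_reward",
    n_boot: int = 0,
    seed: int = 0,
) -> OPEEstimate:
    """Weighted importance sampling estimate of a policy's value.

    ``return_kind='discounted_reward'`` evaluates the discounted terminal
    reward; ``'death_indicator'`` evaluates the mortality probability (the
    reported ``value`` is then the death fraction, and ``mortality_pct`` is
    100x it). The optional bootstrap CI resamples trajectories.
    """
    if return_kind not in ("discounted_reward", "death_indicator"):
        raise ValueError("return_kind must be 'discounted_reward' or 'death_indicator'")
    w = importance_weights(trajs, pi_e, pi_b)
    death = trajs.death
    G = trajs.returns(gamma) if return_kind == "discounted_reward" else death
    wsum = w.sum()
    if wsum <= 0:
        logger.warning("all importance weights are zero; WIS estimate undefined")
        return OPEEstimate(
            value=np.nan, mortality_pct=np.nan, weights=w, ess=0.0, n=trajs.n,
            estimator="wis", failed=True,
        )
    value = float((w * G).sum() / wsum)
    mortality = float((w * death).sum() / wsum * 100.0)
    ci = mci = None
    if n_boot > 0:
        rng = rng_from(seed)
        idx = rng.integers(0, trajs.n, size=(n_boot, trajs.n))
        with np.errstate(invalid="ignore"):
            reps = (w[idx] * G[idx]).sum(axis=1) / w[idx].sum(axis=1)
            mreps = (w[idx] * death[idx]).sum(axis=1) / w[idx].sum(axis=1) * 100.0
        reps, mreps = reps[~np.isnan(reps)], mreps[~np.isnan(mreps)]
        ci = tuple(float(x) for x in np.percentile(reps, [2.5, 97.5]))
        mci = tuple(float(x) for x in np.percentile(mreps, [2.5, 97.5]))
    return OPEEstimate(
        value=value, mortality_pct=mortality, weights=w,
        ess=effective_sample_size(w), n=trajs.n, estimator="wis", ci=ci,
        mortality_ci=mci,
    )


def _policy_q_fixed_point(
    trajs: TrajectorySet,
    pi_e,
    gamma: float,
    tol: float,
    max_iter: int,
    default_q: float,
) -> tuple[np.ndarray, np.ndarray, "np.ndarray"]:
    """Iterative solve of Q^{pi_e} on the empirical transition table."""
    pe = policy_matrix(pi_e, trajs.n_states)
    model = estimate_mdp(trajs, gamma)
    k = trajs.n_states
    P = model.transitions
    unvisited_needed = (~model.observed) & (pe > 0)
    if unvisited_needed.any():
        warnings.warn(
            f"{int(unvisited_needed.sum())} state-action pairs required by the "
            f"evaluated policy were never observed; using pessimistic default "
            f"Q = {default_q}",
            stacklevel=3,
        )
    Q = np.zeros((k, 2))
    U = np.empty(k + 2)
    U[k:] = TERMINAL_UTILITY
    for _ in range(max_iter):
        V = (pe * Q).sum(axis=1)
        U[:k] = V
        Q_new = gamma * P @ U
        Q_new[~model.observed] = default_q
        if np.abs(Q_new - Q).max() < tol:
            Q = Q_new
            break
        Q = Q_new
    else:
        raise RuntimeError("policy evaluation did not converge")
    return Q, pe, model


def _initial_state_value(trajs: TrajectorySet, values: np.ndarray) -> float:
    s0 = trajs.states[:, 0]
    return float(values[s0].mean())


def fqe(
    trajs: TrajectorySet,
    pi_e,
    gamma: float = 0.99,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    default_q: float = -100.0,
) -> float:
    """Fitted Q evaluation: iterative Bellman backups for Q^{pi_e}.

    Solves the evaluation policy's fixed point on the empirical transition
    table of the evaluation set and averages the policy's initial-state value
    over the observed initial states. Pairs never observed default to a
    pessimistic value.
    """
    if trajs.n == 0:
        raise ValueError("empty dataset")
    Q, pe, _ = _policy_q_fixed_point(trajs, pi_e, gamma, tol, max_iter, default_q)
    return _initial_state_value(trajs, (pe * Q).sum(axis=1))


def approximate_model(
    trajs: TrajectorySet,
    pi_e,
    gamma: float = 0.99,
    default_q: float = -100.0,
) -> float:
    """Plug-in model-based estimate: exact linear solve on the estimated MDP.

    Builds the tabular MDP from the evaluation set and evaluates ``pi_e``
    exactly by solving the linear Bellman system, averaging over the
    empirical initial-state distribution. On a dataset where all transitions
    required by the policy are observed this equals FQE up to tolerance.
    """
    if trajs.n == 0:
        raise ValueError("empty dataset")
    pe = policy_matrix(pi_e, trajs.n_states)
    model = estimate_mdp(trajs, gamma)
    k = trajs.n_states
    P = model.transitions
    unvisited_needed = (~model.observed) & (pe > 0)
    if unvisited_needed.any():
        warnings.warn(
            f"{int(unvisited_needed.sum())} state-action pairs required by the "
            "evaluated policy were never observed; the model routes them to the "
            "death terminal",
            stacklevel=2,
        )
    # V = gamma * (M V + b), M marginalizes actions under pi_e
    M = np.einsum("ka,kas->ks", pe, P[:, :, :k])
    b = np.einsum("ka,kas,s->k", pe, P[:, :, k:], TERMINAL_UTILITY)
    V = np.linalg.solve(np.eye(k) - gamma * M, gamma * b)
    return _initial_state_value(trajs, V)


def wdr(
    trajs: TrajectorySet,
    pi_e,
    pi_b,
    q_hat: np.ndarray,
    gamma: float = 0.99,
) -> float:
    """Weighted doubly robust estimate with stepwise-normalized weights.

    Combines per-step importance weights (normalized across trajectories at
    each time step; weights persist past a trajectory's end) with the control
    variate built from ``q_hat`` (a (k, 2) state-action value table, e.g. from
    :func:`fqe` or :func:`approximate_model`). With ``q_hat = 0`` this reduces
    to stepwise WIS.
    """
    pe = policy_matrix(pi_e, trajs.n_states)
    pb = policy_matrix(pi_b, trajs.n_states)
    q_hat = np.asarray(q_hat, dtype=float)
    m = trajs.mask
    s = np.where(m, trajs.states, 0)
    a = trajs.actions
    num, den = pe[s, a], pb[s, a]
    if (m & (den <= 0) & (num > 0)).any():
        raise ValueError("behavior policy assigns zero probability to an observed action")
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(num == 0.0, 0.0, num / np.where(den > 0, den, 1.0))
    ratio = np.where(m, ratio, 1.0)
    rho = np.cumprod(ratio, axis=1)  # (n, T); constant after trajectory end
    col_sum = rho.sum(axis=0)
    if np.any(col_sum <= 0):
        raise ValueError("all stepwise importance weights are zero at some step")
    w = rho / col_sum  # (n, T) normalized per time step
    n, T = w.shape
    w_prev = np.hstack([np.full((n, 1), 1.0 / n), w[:, :-1]])

    q_sa = np.where(m, q_hat[s, a], 0.0)
    v_s = np.where(m, (pe[s] * q_hat[s]).sum(axis=2), 0.0)
    t_idx = np.arange(T)[None, :]
    reward_term = (gamma ** (t_idx + 1)) * w * trajs.rewards
    correction = (gamma**t_idx) * (w * q_sa - w_prev * v_s)
    return float((reward_term - correction).sum())


@dataclass
class BootstrapResult:
    """Paired bootstrap comparison of an evaluated policy vs the behavior policy."""

    B: int
    seed: int
    value_improvement: float
    value_improvement_ci: tuple[float, float]
    p_value: float
    pct_outperformed: float
    mortality_decrease_pct: float
    mortality_decrease_ci: tuple[float, float]
    mortality_p_value: float
    value_eval: float
    value_behavior: float
    mortality_eval_pct: float
    mortality_behavior_pct: float
    n_dropped: int = 0
    improvements: np.ndarray = field(default=None, repr=False)


def _one_sided_p(improvements: np.ndarray) -> float:
    """One-sided bootstrap P for 'no improvement', with ties split (mid-P)."""
    return float(np.mean(improvements < 0) + 0.5 * np.mean(improvements == 0))


def bootstrap_compare(
    trajs: TrajectorySet,
    pi_e,
    pi_b,
    B: int = 1000,
    seed: int = 0,
    gamma: float = 0.99,
) -> BootstrapResult:
    """One-sided bootstrap resampling test of ``pi_e`` against ``pi_b``.

    Resamples trajectories with replacement; each replicate computes paired
    WIS estimates (value and mortality) for both policies on the same
    resample. ``p_value`` is the fraction of replicates in which the
    evaluated policy failed to improve on the behavior policy (ties counted
    half). Replicates with an undefined estimate are dropped and counted.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    w_e = importance_weights(trajs, pi_e, pi_b)
    w_b = importance_weights(trajs, pi_b, pi_b)
    G = trajs.returns(gamma)
    D = trajs.death
    rng = rng_from(seed)
    idx = rng.integers(0, trajs.n, size=(B, trajs.n))
    we, wb = w_e[idx], w_b[idx]
    with np.errstate(invalid="ignore", divide="ignore"):
        J_e = (we * G[idx]).sum(axis=1) / we.sum(axis=1)
        J_b = (wb * G[idx]).sum(axis=1) / wb.sum(axis=1)
        M_e = (we * D[idx]).sum(axis=1) / we.sum(axis=1) * 100.0
        M_b = (wb * D[idx]).sum(axis=1) / wb.sum(axis=1) * 100.0
    ok = ~(np.isnan(J_e) | np.isnan(J_b))
    n_dropped = int(B - ok.sum())
    if ok.sum() == 0:
        raise ValueError("every bootstrap replicate produced an undefined estimate")
    imp = J_e[ok] - J_b[ok]
    mdec = M_b[ok] - M_e[ok]
    full_e = wis(trajs, pi_e, pi_b, gamma=gamma)
    full_b = wis(trajs, pi_b, pi_b, gamma=gamma)
    return BootstrapResult(
        B=B,
        seed=seed,
        value_improvement=float(full_e.value - full_b.value),
        value_improvement_ci=tuple(float(x) for x in np.percentile(imp, [2.5, 97.5])),
        p_value=_one_sided_p(imp),
        pct_outperformed=float(100.0 * np.mean(imp > 0)),
        mortality_decrease_pct=float(full_b.mortality_pct - full_e.mortality_pct),
        mortality_decrease_ci=tuple(float(x) for x in np.percentile(mdec, [2.5, 97.5])),
        mortality_p_value=_one_sided_p(mdec),
        value_eval=full_e.value,
        value_behavior=full_b.value,
        mortality_eval_pct=full_e.mortality_pct,
        mortality_behavior_pct=full_b.mortality_pct,
        n_dropped=n_dropped,
        improvements=imp,
    )
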