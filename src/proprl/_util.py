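"""Shared helpers: seeding and policy-matrix coercion."""
from __future__ import annotations

import numpy as np

MAX_SEED = 2**31 - 1


def child_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent integer seeds (< 2**31) from one base seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % MAX_SEED for s in ss.generate_state(n, dtype=np.uint64)]


def rng_from(seed) -> np.random.Generator:
    """Accept an int seed or an existing Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def policy_matrix(policy, n_states: int | None = None) -> np.ndarray:
    """Coerce a policy-like object to an (k, 2) array of action probabilities.

    Accepts a raw array, or any object exposing a ``probs`` attribute
    (BehaviorPolicy, LearnedPolicy).
    """
    probs = getattr(policy, "probs", policy)
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 2 or probs.shape[1] != 2:
        raise ValueError(f"policy matrix must have shape (k, 2), got {probs.shape}")
    if n_states is not None and probs.shape[0] != n_states:
        raise ValueError(
            f"policy defined on {probs.shape[0]} states, expected {n_states}"
        )
    if np.any(probs < -1e-12) or np.any(np.abs(probs.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError("policy rows must be probability distributions")
    return probs
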