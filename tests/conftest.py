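import numpy as np
import pandas as pd
import pytest

from proprl.data import TrajectorySet


def make_trajectory_set(trajectories, n_states):
    """Build a TrajectorySet from [(states, actions, terminal_reward), ...]."""
    n = len(trajectories)
    t_max = max(len(s) for s, _, _ in trajectories)
    S = np.full((n, t_max), -1, dtype=np.int64)
    A = np.zeros((n, t_max), dtype=np.int64)
    R = np.zeros((n, t_max))
    L = np.zeros(n, dtype=np.int64)
    for i, (s, a, term) in enumerate(trajectories):
        ln = len(s)
        S[i, :ln] = s
        A[i, :ln] = a
        R[i, ln - 1] = term
        L[i] = ln
    return TrajectorySet(
        states=S, actions=A, rewards=R, lengths=L, n_states=n_states,
        stay_ids=np.arange(n),
    )


@pytest.fixture
def traj_builder():
    return make_trajectory_set


@pytest.fixture
def random_cohort_table():
    """Small random decision-step table factory (no structure, for bookkeeping tests)."""

    def _make(n_stays=30, n_features=4, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for sid in range(n_stays):
            T = rng.integers(1, 6)
            died = rng.random() < 0.2
            for t in range(T):
                rows.append(
                    {
                        "stay_id": sid,
                        "t": t,
                        **{f"f{j}": rng.normal() for j in range(n_features)},
                        "action": int(rng.random() < 0.5),
                        "reward": (
                            0.0 if t < T - 1 else (-100.0 if died else 100.0)
                        ),
                        "terminal_flag": int(t == T - 1),
                    }
                )
        return pd.DataFrame(rows)

    return _make
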