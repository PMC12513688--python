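"""Array-backed container for discrete-state decision trajectories.

Downstream modules (behavior estimation, tabular MDP fitting, off-policy
evaluation) all consume the same structure: per-trajectory sequences of
(state id, binary action, reward), padded to a common horizon. Rewards are 0
on every step except the last, which carries the terminal +-100; the return
of a trajectory with T steps is ``sum_t gamma^(t+1) r_t`` (the terminal
reward is received on arrival at the absorbing outcome).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .windows import feature_columns


@dataclass
class TrajectorySet:
    """Padded trajectories over a discrete state space of size ``n_states``."""

    states: np.ndarray  # (n, Tmax) int, padded with -1
    actions: np.ndarray  # (n, Tmax) int, padded with 0
    rewards: np.ndarray  # (n, Tmax) float, padded with 0
    lengths: np.ndarray  # (n,) int
    n_states: int
    stay_ids: np.ndarray | None = None

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.int64)
        self.actions = np.asarray(self.actions, dtype=np.int64)
        self.rewards = np.asarray(self.rewards, dtype=float)
        self.lengths = np.asarray(self.lengths, dtype=np.int64)
        if self.lengths.min(initial=1) < 1:
            raise ValueError("every trajectory needs at least one decision step")

    @property
    def n(self) -> int:
        return len(self.lengths)

    @property
    def t_max(self) -> int:
        return self.states.shape[1]

    @property
    def mask(self) -> np.ndarray:
        """(n, Tmax) bool mask of valid steps."""
        return np.arange(self.t_max)[None, :] < self.lengths[:, None]

    @property
    def terminal_reward(self) -> np.ndarray:
        return self.rewards[np.arange(self.n), self.lengths - 1]

    @property
    def death(self) -> np.ndarray:
        """Binary in-hospital death indicator per trajectory."""
        return (self.terminal_reward < 0).astype(float)

    def returns(self, gamma: float = 0.99) -> np.ndarray:
        """Discounted return per trajectory: sum_t gamma^(t+1) r_t."""
        disc = gamma ** (np.arange(1, self.t_max + 1))
        return (self.rewards * disc[None, :] * self.mask).sum(axis=1)

    def subset(self, idx) -> "TrajectorySet":
        """Trajectory-level subset/resample (bootstrap replicates, partitions)."""
        idx = np.asarray(idx)
        return TrajectorySet(
            states=self.states[idx],
            actions=self.actions[idx],
            rewards=self.rewards[idx],
            lengths=self.lengths[idx],
            n_states=self.n_states,
            stay_ids=self.stay_ids[idx] if self.stay_ids is not None else None,
        )

    def flat(self) -> tuple[np.ndarray, np.ndarray]:
        """All valid (state, action) pairs, concatenated."""
        m = self.mask
        return self.states[m], self.actions[m]

    @classmethod
    def from_table(
        cls,
        decision_table: pd.DataFrame,
        state_definition=None,
        states: np.ndarray | None = None,
        n_states: int | None = None,
    ) -> "TrajectorySet":
        """Build from a canonical decision-step table.

        States come either from ``state_definition.assign`` on the feature
        columns or from a precomputed ``states`` vector aligned with the
        table's rows.
        """
        df = decision_table.reset_index(drop=True)
        order = df.sort_values(["stay_id", "t"], kind="stable").index.to_numpy()
        df = df.iloc[order]
        if states is None:
            if state_definition is None:
                raise ValueError("provide a state definition or a states vector")
            states = state_definition.assign(df[feature_columns(df)].to_numpy(dtype=float))
            n_states = state_definition.k
        else:
            states = np.asarray(states)[order]  # aligned with the table as given
            if n_states is None:
                raise ValueError("n_states required with a precomputed states vector")

        sid = df["stay_id"].to_numpy()
        boundaries = np.flatnonzero(np.r_[True, sid[1:] != sid[:-1]])
        lengths = np.diff(np.r_[boundaries, len(sid)])
        n, t_max = len(lengths), int(lengths.max())
        S = np.full((n, t_max), -1, dtype=np.int64)
        A = np.zeros((n, t_max), dtype=np.int64)
        R = np.zeros((n, t_max), dtype=float)
        actions = df["action"].to_numpy(dtype=np.int64)
        rewards = df["reward"].to_numpy(dtype=float)
        for i, (b, ln) in enumerate(zip(boundaries, lengths)):
            S[i, :ln] = states[b : b + ln]
            A[i, :ln] = actions[b : b + ln]
            R[i, :ln] = rewards[b : b + ln]
        return cls(
            states=S,
            actions=A,
            rewards=R,
            lengths=lengths,
            n_states=int(n_states),
            stay_ids=sid[boundaries],
        )
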