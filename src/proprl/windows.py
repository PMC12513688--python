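"""Decision windows and reward-annotated trajectories.

Hospitalization records are split into chronological decision windows: the
first window covers the first 24 hours after admission, the second runs to the
next boundary hour (6 AM by default) strictly after that, and every later
window is a full boundary-to-boundary day. Analysis is truncated to the first
``max_days`` days of the stay. A binary action is attached to each window
(whether treatment was administered in it), intermediate rewards are 0, and a
terminal reward of +100 (discharged alive) or -100 (died) is attached to the
final emitted window.

The reinforcement-learning convention that treatment decisions in a window are
based on the patient's state in the *previous* window is applied in exactly one
place, :func:`decision_view`, which turns a window-level table into the
decision-step table consumed by every downstream module: decision step ``i``
pairs the features of window ``i`` with the action of window ``i + 1``.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Columns of the canonical tables that are not feature columns.
META_COLUMNS = ("stay_id", "t", "start", "end", "action", "reward", "terminal_flag")

ALIVE, DEATH = "alive", "death"
TERMINAL_REWARD = 100.0
MAX_HORIZON = 10  # decision points t = 0..9


class StayTooShortError(ValueError):
    """Stay spans fewer than two decision windows and is excluded."""


@dataclass
class RawStay:
    """One hospitalization as delivered by the source tables."""

    stay_id: object
    admit_time: pd.Timestamp
    end_time: pd.Timestamp
    outcome: str  # "alive" or "death"
    feature_rows: pd.DataFrame | None = None  # columns: timestamp, feature_*
    action_events: Sequence[pd.Timestamp] = field(default_factory=list)

    def __post_init__(self):
        self.admit_time = pd.Timestamp(self.admit_time)
        self.end_time = pd.Timestamp(self.end_time)
        if not self.admit_time < self.end_time:
            raise ValueError(f"stay {self.stay_id}: admit_time must precede end_time")
        if self.outcome not in (ALIVE, DEATH):
            raise ValueError(f"stay {self.stay_id}: outcome must be 'alive' or 'death'")


@dataclass
class Window:
    """One decision window within a stay."""

    t: int
    start: pd.Timestamp
    end: pd.Timestamp
    features: np.ndarray | None = None
    action: int = 0
    reward: float = 0.0


@dataclass
class Trajectory:
    """Ordered windows of one stay with actions and terminal reward."""

    stay_id: object
    windows: list[Window]
    terminal_reward: float
    outcome: str

    @property
    def horizon(self) -> int:
        return len(self.windows)


def assign_windows(
    stay: RawStay, boundary_hour: int = 6, max_days: int = 8
) -> list[Window]:
    """Split a stay into contiguous decision windows.

    Window 1 is ``[admit, admit + 24 h)``; window 2 runs to the first
    ``boundary_hour`` o'clock strictly after that; windows 3+ are full
    24-hour boundary-to-boundary windows. The stay is truncated at
    ``admit + max_days`` days, and the last window is clipped to the stay
    (or truncation) end.

    Raises
    ------
    StayTooShortError
        If the stay spans fewer than two windows.
    """
    if not (0 <= boundary_hour < 24):
        raise ValueError("boundary_hour must be in [0, 24)")
    admit, end = stay.admit_time, stay.end_time
    stop = min(end, admit + pd.Timedelta(days=max_days))

    first_end = admit + pd.Timedelta(hours=24)
    if first_end >= stop:
        raise StayTooShortError(
            f"stay {stay.stay_id} spans fewer than 2 windows; flagged for exclusion"
        )
    bounds = [admit, first_end]
    # first boundary_hour strictly after the end of window 1
    nxt = first_end.normalize() + pd.Timedelta(hours=boundary_hour)
    while nxt <= first_end:
        nxt += pd.Timedelta(days=1)
    while bounds[-1] < stop:
        bounds.append(min(nxt, stop))
        nxt += pd.Timedelta(days=1)
    return [Window(t=i, start=a, end=b) for i, (a, b) in enumerate(zip(bounds, bounds[1:]))]


def build_trajectory(
    windows: list[Window],
    action_events: Iterable[pd.Timestamp],
    outcome: str,
) -> Trajectory:
    """Attach binary actions and the terminal reward to a window sequence.

    ``a_t = 1`` iff at least one action event falls inside window ``t``
    (half-open ``[start, end)``). All non-terminal rewards are 0; the terminal
    reward (+100 alive, -100 death) is attached to the final window. Action
    events outside every window are ignored with a logged warning.
    """
    if not windows:
        raise ValueError("windows must be nonempty")
    if outcome not in (ALIVE, DEATH):
        raise ValueError("outcome must be 'alive' or 'death'")
    if len(windows) > MAX_HORIZON:
        raise ValueError(
            f"trajectory horizon {len(windows)} exceeds the maximum of {MAX_HORIZON}"
        )
    for w in windows:
        w.action = 0
        w.reward = 0.0
    for ev in action_events:
        ev = pd.Timestamp(ev)
        hit = False
        for w in windows:
            if w.start <= ev < w.end:
                w.action = 1
                hit = True
                break
        if not hit:
            logger.warning("action event at %s falls outside all windows; ignored", ev)
    terminal = TERMINAL_REWARD if outcome == ALIVE else -TERMINAL_REWARD
    windows[-1].reward = terminal
    return Trajectory(
        stay_id=None, windows=windows, terminal_reward=terminal, outcome=outcome
    )


def _aggregate_features(
    windows: list[Window], feature_rows: pd.DataFrame, feature_cols: list[str]
) -> None:
    """Per-window mean of sub-window feature rows; gaps forward/back-filled."""
    ts = pd.to_datetime(feature_rows["timestamp"]).to_numpy()
    vals = feature_rows[feature_cols].to_numpy(dtype=float)
    agg = np.full((len(windows), len(feature_cols)), np.nan)
    for i, w in enumerate(windows):
        mask = (ts >= w.start.to_datetime64()) & (ts < w.end.to_datetime64())
        if mask.any():
            agg[i] = vals[mask].mean(axis=0)
    agg = pd.DataFrame(agg).ffill().bfill().to_numpy()
    if np.isnan(agg).any():
        raise ValueError("stay has no feature rows inside any window")
    for i, w in enumerate(windows):
        w.features = agg[i]


def build_cohort(
    events: pd.DataFrame,
    actions: pd.DataFrame,
    outcomes: pd.DataFrame,
    boundary_hour: int = 6,
    max_days: int = 8,
    truncated_as_alive: bool = False,
) -> tuple[pd.DataFrame, list]:
    """Convert source tables into the canonical window-level trajectory table.

    Parameters
    ----------
    events : table with columns ``stay_id``, ``timestamp``, ``feature_*``.
    actions : table with columns ``stay_id``, ``timestamp``.
    outcomes : table with columns ``stay_id``, ``admit_time``, ``end_time``,
        ``outcome``.
    truncated_as_alive : if True, stays truncated at ``max_days`` are scored
        as discharged alive instead of using the eventual in-hospital outcome.

    Returns
    -------
    (table, excluded) : the window table plus the ids of stays excluded for
        spanning fewer than two windows.
    """
    feature_cols = [c for c in events.columns if c not in ("stay_id", "timestamp")]
    action_map = {
        sid: pd.to_datetime(grp["timestamp"]).tolist()
        for sid, grp in actions.groupby("stay_id")
    }
    rows, excluded = [], []
    for rec in outcomes.itertuples(index=False):
        stay = RawStay(
            stay_id=rec.stay_id,
            admit_time=rec.admit_time,
            end_time=rec.end_time,
            outcome=rec.outcome,
        )
        try:
            windows = assign_windows(stay, boundary_hour, max_days)
        except StayTooShortError:
            excluded.append(stay.stay_id)
            continue
        outcome = stay.outcome
        truncated = stay.end_time > stay.admit_time + pd.Timedelta(days=max_days)
        if truncated and truncated_as_alive:
            outcome = ALIVE
        feats = events.loc[events["stay_id"] == stay.stay_id]
        if feats.empty:
            raise ValueError(f"stay {stay.stay_id} has no feature rows")
        _aggregate_features(windows, feats, feature_cols)
        traj = build_trajectory(windows, action_map.get(stay.stay_id, []), outcome)
        for w in traj.windows:
            rows.append(
                {
                    "stay_id": stay.stay_id,
                    "t": w.t,
                    "start": w.start,
                    "end": w.end,
                    **dict(zip(feature_cols, w.features)),
                    "action": w.action,
                    "reward": w.reward,
                    "terminal_flag": int(w.t == len(traj.windows) - 1),
                }
            )
    cols = ["stay_id", "t", "start", "end", *feature_cols, "action", "reward", "terminal_flag"]
    return pd.DataFrame(rows, columns=cols), excluded


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Feature columns of a canonical (window- or decision-level) table."""
    return [c for c in table.columns if c not in META_COLUMNS]


def decision_view(window_table: pd.DataFrame) -> pd.DataFrame:
    """Apply the decision-timing shift once: window table -> decision steps.

    Decision step ``i`` of a stay with ``T`` windows (``i = 0..T-2``) carries
    the features of window ``i`` (the state the decision was based on) and the
    action of window ``i + 1`` (the decision then taken). The terminal reward
    of the final window becomes the reward of the final decision step; all
    other step rewards are 0.
    """
    df = window_table.sort_values(["stay_id", "t"], kind="stable").reset_index(drop=True)
    grp = df.groupby("stay_id", sort=False)
    nxt_action = grp["action"].shift(-1)
    nxt_reward = grp["reward"].shift(-1)
    keep = nxt_action.notna()
    out = df.loc[keep, ["stay_id"] + feature_columns(df)].copy()
    out["action"] = nxt_action[keep].astype(int).to_numpy()
    out["reward"] = nxt_reward[keep].to_numpy()
    out["t"] = out.groupby("stay_id", sort=False).cumcount()
    last = out.groupby("stay_id", sort=False)["t"].transform("max")
    out["terminal_flag"] = (out["t"] == last).astype(int)
    cols = ["stay_id", "t", *feature_columns(df), "action", "reward", "terminal_flag"]
    return out[cols].reset_index(drop=True)


def write_table(table: pd.DataFrame, path) -> None:
    """Write a canonical table as CSV or parquet based on the extension."""
    path = Path(path)
    if path.suffix == ".parquet":
        table.to_parquet(path, index=False)
    else:
        table.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".parquet":
        return pd.read_parquet(path)
    return pd.read_csv(path)
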