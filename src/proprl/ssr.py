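"""Split-Select-Retrain hyperparameter search.

Offline-RL performance estimates are sensitive to how the development set is
split, so hyperparameters are selected by *aggregating* validation
performance across several independent train/validation partitions rather
than a single hold-out: for every combination of state definition (fitting
partition ``j`` and state count ``k``) and policy-learning knobs (BCQ
threshold, pessimism count, unimportance threshold), a policy is trained on
each partition's training split and scored by WIS on its validation split.
Points whose effective sample size falls below a cutoff fraction of the
validation set on any partition are marked unreliable and excluded. The
winning point is then retrained on the entire development set with its state
definition kept fixed.

The ablation harness reruns the pipeline with each robustness element
(unimportant-state relaxation, multiple splits, multiple state definitions)
switched off, reporting worst-case performance per configuration.
"""
from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import child_seeds
from .behavior import estimate_behavior_policy
from .data import TrajectorySet
from .ope import effective_sample_size, importance_weights
from .policy_learning import (
    LearnedPolicy,
    QTable,
    bcq_allowed,
    estimate_mdp,
    relax_unimportant,
    value_iteration_batch,
    _effective_transitions,
)
from .states import StateDefinition, fit_embedding, fit_state_definition
from .windows import feature_columns


class NoViablePolicyError(RuntimeError):
    """Every hyperparameter point was unreliable: no viable policy exists."""


@dataclass
class Partition:
    """One random stay-level train/validation split of the development set."""

    id: int
    train_ids: np.ndarray
    val_ids: np.ndarray
    seed: int

    def __post_init__(self):
        if np.intersect1d(self.train_ids, self.val_ids).size:
            raise ValueError("training and validation stays must be disjoint")


def make_partitions(
    stay_ids, n_partitions: int = 10, val_frac: float = 0.25, seed: int = 0
) -> list[Partition]:
    """Independent random stay-level splits, deterministic under the seed."""
    ids = np.unique(np.asarray(stay_ids))
    if len(ids) < 2:
        raise ValueError("need at least 2 stays to partition")
    if not 0.0 < val_frac < 1.0:
        raise ValueError("val_frac must lie in (0, 1)")
    n_val = min(max(int(round(val_frac * len(ids))), 1), len(ids) - 1)
    parts = []
    for i, s in enumerate(child_seeds(seed, n_partitions)):
        perm = np.random.default_rng(s).permutation(ids)
        parts.append(
            Partition(id=i, train_ids=np.sort(perm[n_val:]), val_ids=np.sort(perm[:n_val]), seed=s)
        )
    return parts


@dataclass(frozen=True)
class HyperparameterPoint:
    """One cell of the search grid: state definition (j, k) + policy knobs."""

    j: int
    k: int
    tau_bcq: float
    n_min: int
    delta: float


@dataclass
class SearchGrid:
    ks: tuple = (20, 40, 60, 80, 100, 120, 140, 160)
    taus: tuple = (0.0, 0.1, 0.3)
    n_mins: tuple = (0, 5, 20)
    deltas: tuple = (0.0, 1.0, 5.0, np.inf)


@dataclass
class SSRReport:
    """Full results table of the search plus everything needed to retrain."""

    results: pd.DataFrame  # partition x point -> wis, ess, reliable
    state_definitions: dict  # (j, k) -> StateDefinition
    partitions: list[Partition]
    grid: SearchGrid
    ess_cutoff: float
    seed: int
    fit_audit: dict = field(default_factory=dict)

    POINT_COLS = ["j", "k", "tau_bcq", "n_min", "delta"]

    def aggregate(self) -> pd.DataFrame:
        """Per-point mean validation WIS/ESS and an all-partitions reliability flag."""
        g = self.results.groupby(self.POINT_COLS, sort=True)
        out = g.agg(
            mean_wis=("wis_value", "mean"),
            mean_ess=("ess", "mean"),
            reliable_all=("reliable", "all"),
            n_partitions=("partition", "nunique"),
        ).reset_index()
        return out

    def select(self) -> HyperparameterPoint:
        """Argmax of mean WIS among points reliable on every partition.

        Ties break toward larger mean ESS, then smaller k, then the row order
        of the (sorted) aggregate table, so selection is deterministic given
        the results table.
        """
        agg = self.aggregate()
        viable = agg[agg["reliable_all"]]
        if viable.empty:
            raise NoViablePolicyError(
                "no hyperparameter point was reliable on all partitions"
            )
        ranked = viable.sort_values(
            by=["mean_wis", "mean_ess", "k"],
            ascending=[False, False, True],
            kind="stable",
        )
        row = ranked.iloc[0]
        return HyperparameterPoint(
            j=int(row["j"]), k=int(row["k"]), tau_bcq=float(row["tau_bcq"]),
            n_min=int(row["n_min"]), delta=float(row["delta"]),
        )

    def to_csv(self, path) -> None:
        self.results.to_csv(path, index=False)


def fit_state_definitions(
    dev_table: pd.DataFrame,
    partitions: list[Partition],
    ks,
    embedding_dim: int = 8,
    runs: int = 10,
    seed: int = 0,
    embedding_method: str = "pca",
    subsample_cap: int = 2000,
) -> tuple[dict, dict, dict]:
    """Fit a state definition per (partition j, k) on that partition's training split.

    Returns (state_definitions, assignments, audit): ``assignments[(j, k)]``
    holds the state id of every row of ``dev_table`` under that definition,
    and ``audit`` records which stays each fit saw.
    """
    fcols = feature_columns(dev_table)
    X = dev_table[fcols].to_numpy(dtype=float)
    stay_of_row = dev_table["stay_id"].to_numpy()
    sds, assignments, audit = {}, {}, {}
    seeds = child_seeds(seed, len(partitions) * len(list(ks)))
    for idx, (part, k) in enumerate(itertools.product(partitions, ks)):
        rows = np.isin(stay_of_row, part.train_ids)
        emb = fit_embedding(
            X[rows], method=embedding_method, embedding_dim=embedding_dim,
            seed=seeds[idx],
        )
        sd = fit_state_definition(
            emb.transform(X[rows]), k=k, runs=runs, seed=seeds[idx],
            embedding=emb, partition_id=part.id, subsample_cap=subsample_cap,
        )
        sds[(part.id, k)] = sd
        assignments[(part.id, k)] = sd.assign(X)
        audit[("states", part.id, k)] = set(np.unique(stay_of_row[rows]).tolist())
    return sds, assignments, audit


def _train_and_score(
    ts_all: TrajectorySet,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    grid: SearchGrid,
    gamma: float,
    alpha: float,
    tol: float,
    ess_cutoff: float,
):
    """Train the constrained policies for one (partition, state definition) cell
    and score every (tau, n_min, delta) combination on the validation split."""
    train, val = ts_all.subset(train_idx), ts_all.subset(val_idx)
    pi_b = estimate_behavior_policy(train, alpha=alpha)
    model = estimate_mdp(train, gamma)
    combos = list(itertools.product(grid.taus, grid.n_mins))
    P = np.stack([_effective_transitions(model, n_min) for _, n_min in combos])
    allowed = np.stack([bcq_allowed(pi_b, tau) for tau, _ in combos])
    Q, iters, residual = value_iteration_batch(P, allowed, gamma, tol=tol)
    G_val = val.returns(gamma)
    D_val = val.death
    rows = []
    for b, (tau, n_min) in enumerate(combos):
        qt = QTable(
            q=Q[b], allowed=allowed[b], iterations=iters, residual=float(residual[b]),
            gamma=gamma,
        )
        for delta in grid.deltas:
            policy = relax_unimportant(qt, pi_b, delta)
            try:
                w = importance_weights(val, policy, pi_b)
            except ValueError:
                # policy puts mass on an action with zero estimated behavior
                # probability observed in validation: estimate undefined,
                # point unreliable on this partition
                w = np.zeros(val.n)
            wsum = w.sum()
            ess = effective_sample_size(w)
            if wsum > 0:
                wis_value = float((w * G_val).sum() / wsum)
                wis_mort = float((w * D_val).sum() / wsum * 100.0)
            else:
                wis_value, wis_mort = np.nan, np.nan
            rows.append(
                {
                    "tau_bcq": tau, "n_min": n_min, "delta": delta,
                    "wis_value": wis_value, "wis_mortality_pct": wis_mort,
                    "ess": ess, "n_val": val.n,
                    "reliable": bool(wsum > 0 and ess >= ess_cutoff * val.n),
                }
            )
    return rows, pi_b


def grid_search(
    dev_table: pd.DataFrame,
    partitions: list[Partition],
    grid: SearchGrid,
    ess_cutoff: float = 0.10,
    gamma: float = 0.99,
    alpha: float = 0.0,
    embedding_dim: int = 8,
    runs: int = 10,
    tol: float = 1e-8,
    seed: int = 0,
    subsample_cap: int = 2000,
    state_definitions: dict | None = None,
    assignments: dict | None = None,
) -> SSRReport:
    """Train and validate a policy for every hyperparameter point x partition.

    State definitions are fitted on partition ``j``'s training split (or
    passed in precomputed); policies are trained on partition ``i``'s training
    split under each (j, k) definition and scored by WIS on partition ``i``'s
    validation split, with the ESS reliability flag attached.
    """
    audit = {}
    if state_definitions is None:
        state_definitions, assignments, audit = fit_state_definitions(
            dev_table, partitions, grid.ks, embedding_dim=embedding_dim,
            runs=runs, seed=seed, subsample_cap=subsample_cap,
        )
    all_rows = []
    for (j, k), states in sorted(assignments.items()):
        ts_all = TrajectorySet.from_table(dev_table, states=states, n_states=k)
        stay_ids = ts_all.stay_ids
        for part in partitions:
            train_idx = np.flatnonzero(np.isin(stay_ids, part.train_ids))
            val_idx = np.flatnonzero(np.isin(stay_ids, part.val_ids))
            rows, _ = _train_and_score(
                ts_all, train_idx, val_idx, grid, gamma, alpha, tol, ess_cutoff
            )
            audit[("policy", part.id, j, k)] = set(
                np.unique(stay_ids[train_idx]).tolist()
            )
            for r in rows:
                r.update({"partition": part.id, "j": j, "k": k})
            all_rows.extend(rows)
    cols = [
        "partition", "j", "k", "tau_bcq", "n_min", "delta",
        "wis_value", "wis_mortality_pct", "ess", "n_val", "reliable",
    ]
    results = pd.DataFrame(all_rows)[cols].sort_values(
        ["j", "k", "tau_bcq", "n_min", "delta", "partition"], kind="stable"
    ).reset_index(drop=True)
    return SSRReport(
        results=results, state_definitions=state_definitions,
        partitions=partitions, grid=grid, ess_cutoff=ess_cutoff, seed=seed,
        fit_audit=audit,
    )


@dataclass
class FinalPolicy:
    """Retrained final policy with full provenance."""

    policy: LearnedPolicy
    behavior: object  # BehaviorPolicy refit on the entire development set
    state_definition: StateDefinition
    point: HyperparameterPoint
    provenance: dict

    def save(self, dir_path) -> None:
        from pathlib import Path

        d = Path(dir_path)
        d.mkdir(parents=True, exist_ok=True)
        self.policy.to_frame().to_csv(d / "policy.csv", index=False)
        self.state_definition.save(d / "state_definition.json")
        pd.DataFrame(
            {"state": np.arange(self.behavior.k), "p_treat": self.behavior.p_treat,
             "n_state": self.behavior.n_state, "n_treat": self.behavior.n_treat}
        ).to_csv(d / "behavior_policy.csv", index=False)
        (d / "provenance.json").write_text(json.dumps(self.provenance, default=str))


def select_and_retrain(
    report: SSRReport,
    dev_table: pd.DataFrame,
    gamma: float = 0.99,
    alpha: float = 0.0,
    tol: float = 1e-8,
    pessimism: str = "route",
) -> FinalPolicy:
    """Retrain the selected point on the entire development set.

    The selected state definition S_{j,k} is kept fixed; the behavior policy,
    transition model, constrained value iteration, and relaxation are refit
    on all development stays. Raises :class:`NoViablePolicyError` when no
    point was reliable on every partition.
    """
    from .policy_learning import constrained_value_iteration

    point = report.select()
    sd = report.state_definitions[(point.j, point.k)]
    ts = TrajectorySet.from_table(dev_table, state_definition=sd)
    pi_b = estimate_behavior_policy(ts, alpha=alpha)
    model = estimate_mdp(ts, gamma)
    qt = constrained_value_iteration(
        model, pi_b, tau_bcq=point.tau_bcq, n_min=point.n_min, tol=tol,
        pessimism=pessimism,
    )
    policy = relax_unimportant(qt, pi_b, point.delta)
    policy.hyperparams.update(
        {"tau_bcq": point.tau_bcq, "n_min": point.n_min, "j": point.j, "k": point.k}
    )
    agg = report.aggregate()
    sel = agg[
        (agg["j"] == point.j) & (agg["k"] == point.k)
        & (agg["tau_bcq"] == point.tau_bcq) & (agg["n_min"] == point.n_min)
        & (agg["delta"] == point.delta)
    ]
    provenance = {
        "point": point.__dict__,
        "mean_validation_wis": float(sel["mean_wis"].iloc[0]),
        "mean_validation_ess": float(sel["mean_ess"].iloc[0]),
        "n_partitions": len(report.partitions),
        "ess_cutoff": report.ess_cutoff,
        "seed": report.seed,
        "n_dev_stays": int(ts.n),
    }
    return FinalPolicy(
        policy=policy, behavior=pi_b, state_definition=sd, point=point,
        provenance=provenance,
    )


def audit_no_leakage(report: SSRReport) -> bool:
    """Verify no validation stay of partition i touched any fit for partition i."""
    for part in report.partitions:
        val = set(np.asarray(part.val_ids).tolist())
        for key, stays in report.fit_audit.items():
            kind = key[0]
            pid = key[1]
            if pid == part.id and stays & val:
                raise AssertionError(
                    f"leakage: validation stays of partition {part.id} used in {kind} fit"
                )
    return True
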