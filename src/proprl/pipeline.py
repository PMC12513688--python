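"""End-to-end orchestration of the five pipeline steps.

(1) partition the development set; (2) learn candidate discrete state
definitions; (3) estimate and validate the behavior policy; (4) train
constrained policies over the hyperparameter grid and select by aggregated
validation WIS; (5) evaluate the retrained final policy on the held-out test
set with bootstrap comparisons, disagreement rates, and divergent-state
characterization. The held-out test data are touched only in step 5.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._util import child_seeds, rng_from
from .behavior import behavior_sanity_check, disagreement_rate, estimate_behavior_policy
from .data import TrajectorySet
from .ope import bootstrap_compare, wis
from .ssr import (
    FinalPolicy,
    NoViablePolicyError,
    SearchGrid,
    SSRReport,
    grid_search,
    make_partitions,
    select_and_retrain,
)
from .states import diagnose_states
from .windows import feature_columns

logger = logging.getLogger(__name__)

#: process exit code for the structured "no viable policy" failure (vs a crash)
EXIT_NO_VIABLE_POLICY = 3


@dataclass
class PipelineConfig:
    """Everything the pipeline needs, with an explicit seed for every stage."""

    ks: tuple = (20, 40, 60, 80, 100, 120, 140, 160)
    taus: tuple = (0.0, 0.1, 0.3)
    n_mins: tuple = (0, 5, 20)
    deltas: tuple = (0.0, 1.0, 5.0, float("inf"))
    n_partitions: int = 10
    val_frac: float = 0.25
    gamma: float = 0.99
    B: int = 1000
    ess_cutoff: float = 0.10
    alpha: float = 0.0
    embedding_dim: int = 8
    ensemble_runs: int = 10
    subsample_cap: int = 2000
    tol: float = 1e-8
    seed: int = 0
    relaxation: bool = True  # ablation flag: allow unimportant-state deferral

    @property
    def grid(self) -> SearchGrid:
        deltas = tuple(self.deltas) if self.relaxation else (0.0,)
        return SearchGrid(
            ks=tuple(self.ks), taus=tuple(self.taus),
            n_mins=tuple(self.n_mins), deltas=deltas,
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cfg = cls(**raw)
        for name in ("ks", "taus", "n_mins", "deltas"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg


@dataclass
class PipelineResult:
    """Artifact bundle of one pipeline run."""

    status: str  # "ok" or "no_viable_policy"
    config: PipelineConfig
    final: FinalPolicy | None
    ssr_report: SSRReport | None
    state_diagnostics: object | None
    behavior_check: dict | None
    evaluation: dict | None
    divergent_characterization: pd.DataFrame | None
    timings: dict = field(default_factory=dict)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "status.json").write_text(
            json.dumps({"status": self.status, "seed": self.config.seed})
        )
        self.config.to_yaml(out / "config.yaml")
        if self.ssr_report is not None:
            self.ssr_report.to_csv(out / "ssr_results.csv")
        if self.final is not None:
            self.final.save(out / "final_policy")
        if self.evaluation is not None:
            (out / "evaluation.json").write_text(
                json.dumps(self.evaluation, default=float)
            )
        if self.divergent_characterization is not None:
            self.divergent_characterization.to_csv(
                out / "divergent_states.csv", index=False
            )


def evaluate_final(
    final: FinalPolicy,
    test_table: pd.DataFrame,
    gamma: float = 0.99,
    B: int = 1000,
    seed: int = 0,
) -> tuple[dict, pd.DataFrame]:
    """Step 5: score the final policy against the behavior policy on test data.

    Returns the evaluation report (value and mortality for both policies,
    improvement and decrease with bootstrap CIs and one-sided P, ESS, % of
    bootstrap replicates outperformed, disagreement rates) plus the
    divergent-state characterization table (per-state feature means vs the
    population).
    """
    sd = final.state_definition
    ts = TrajectorySet.from_table(test_table, state_definition=sd)
    pi_b = final.behavior
    policy = final.policy
    comp = bootstrap_compare(ts, policy, pi_b, B=B, seed=seed, gamma=gamma)
    est = wis(ts, policy, pi_b, gamma=gamma, n_boot=B, seed=seed)
    dis_b = disagreement_rate(pi_b, ts, n_boot=B, seed=seed)
    dis_e = disagreement_rate(policy, ts, n_boot=B, seed=seed)

    # bootstrap CI for the learned policy's ESS
    rng = rng_from(seed)
    idx = rng.integers(0, ts.n, size=(B, ts.n))
    w = est.weights[idx]
    with np.errstate(invalid="ignore", divide="ignore"):
        ess_reps = w.sum(axis=1) ** 2 / (w**2).sum(axis=1)
    ess_ci = tuple(float(x) for x in np.percentile(ess_reps[~np.isnan(ess_reps)], [2.5, 97.5]))

    evaluation = {
        "n_test": int(ts.n),
        "value_behavior": comp.value_behavior,
        "value_learned": comp.value_eval,
        "value_learned_ci": est.ci,
        "mortality_learned_ci": est.mortality_ci,
        "value_improvement": comp.value_improvement,
        "value_improvement_ci": comp.value_improvement_ci,
        "p_value": comp.p_value,
        "mortality_behavior_pct": comp.mortality_behavior_pct,
        "mortality_learned_pct": comp.mortality_eval_pct,
        "mortality_decrease_pct": comp.mortality_decrease_pct,
        "mortality_decrease_ci": comp.mortality_decrease_ci,
        "mortality_p_value": comp.mortality_p_value,
        "ess_learned": est.ess,
        "ess_learned_ci": ess_ci,
        "pct_outperformed": comp.pct_outperformed,
        "disagreement_behavior_pct": dis_b.rate * 100.0,
        "disagreement_behavior_ci": (dis_b.ci_low * 100.0, dis_b.ci_high * 100.0),
        "disagreement_learned_pct": dis_e.rate * 100.0,
        "disagreement_learned_ci": (dis_e.ci_low * 100.0, dis_e.ci_high * 100.0),
        "n_divergent_states": int(policy.to_frame()["divergent"].sum()),
        "n_defer_states": int(policy.defer.sum()),
    }

    divergent = policy.to_frame()
    div_states = divergent.loc[divergent["divergent"], "state"].to_numpy()
    fcols = feature_columns(test_table)
    states_flat = sd.assign(test_table[fcols].to_numpy(dtype=float))
    char_rows = []
    pop_mean = test_table[fcols].mean()
    for s in div_states:
        in_state = states_flat == s
        row = {"state": int(s), "n_windows": int(in_state.sum())}
        for c in fcols:
            row[f"{c}_state_mean"] = float(test_table.loc[in_state, c].mean())
            row[f"{c}_population_mean"] = float(pop_mean[c])
        char_rows.append(row)
    characterization = pd.DataFrame(char_rows)
    return evaluation, characterization


def run_pipeline(
    config: PipelineConfig,
    dev_table: pd.DataFrame,
    test_table,
) -> PipelineResult:
    """Execute steps 1-5 on a development table and a held-out test table.

    ``test_table`` may be a DataFrame or a zero-argument callable returning
    one; a callable is invoked only at step 5, which makes the test-set
    isolation auditable.
    """
    seeds = child_seeds(config.seed, 5)
    timings = {}
    t0 = time.perf_counter()

    # step 1: data partition
    partitions = make_partitions(
        dev_table["stay_id"], n_partitions=config.n_partitions,
        val_frac=config.val_frac, seed=seeds[0],
    )
    timings["partition"] = time.perf_counter() - t0

    # steps 2 + 4: state definitions, grid search, selection, retraining
    t1 = time.perf_counter()
    report = grid_search(
        dev_table, partitions, config.grid, ess_cutoff=config.ess_cutoff,
        gamma=config.gamma, alpha=config.alpha,
        embedding_dim=config.embedding_dim, runs=config.ensemble_runs,
        tol=config.tol, seed=seeds[1], subsample_cap=config.subsample_cap,
    )
    timings["grid_search"] = time.perf_counter() - t1
    t2 = time.perf_counter()
    try:
        final = select_and_retrain(
            report, dev_table, gamma=config.gamma, alpha=config.alpha, tol=config.tol
        )
    except NoViablePolicyError as err:
        logger.warning("pipeline produced no viable policy: %s", err)
        return PipelineResult(
            status="no_viable_policy", config=config, final=None,
            ssr_report=report, state_diagnostics=None, behavior_check=None,
            evaluation=None, divergent_characterization=None, timings=timings,
        )
    timings["select_retrain"] = time.perf_counter() - t2

    # step 2 diagnostics on the selected state definition (full dev set)
    diag = diagnose_states(dev_table, final.state_definition)

    # step 5: held-out evaluation (the only step that touches the test data)
    test_df = test_table() if callable(test_table) else test_table
    t3 = time.perf_counter()
    ts_test = TrajectorySet.from_table(test_df, state_definition=final.state_definition)
    behavior_check = behavior_sanity_check(
        final.behavior, ts_test, state_aggregates=diag.aggregates,
        n_boot=config.B, seed=seeds[2],
    )
    evaluation, characterization = evaluate_final(
        final, test_df, gamma=config.gamma, B=config.B, seed=seeds[3]
    )
    timings["evaluate"] = time.perf_counter() - t3

    return PipelineResult(
        status="ok", config=config, final=final, ssr_report=report,
        state_diagnostics=diag, behavior_check=behavior_check,
        evaluation=evaluation, divergent_characterization=characterization,
        timings=timings,
    )


def ablation_run(
    config: PipelineConfig,
    dev_table: pd.DataFrame,
    test_table: pd.DataFrame,
    max_single_choices: int | None = None,
) -> pd.DataFrame:
    """Rerun the pipeline with each robustness element removed (2^3 variants).

    The three elements are unimportant-state relaxation (on/off), multiple
    train/validation splits (vs a single partition), and multiple candidate
    state definitions (vs one fixed definition). Single-split / single-
    definition variants are sensitive to *which* split was used, so each such
    variant is rerun for every possible choice (optionally capped at
    ``max_single_choices``) and the worst-case test improvement is reported.
    A variant with no viable policy is reported as such, not raised.
    """
    rows = []
    n_parts = config.n_partitions
    choice_ids = list(range(n_parts if max_single_choices is None else min(n_parts, max_single_choices)))
    for relax in (False, True):
        for multi_split in (False, True):
            for multi_sd in (False, True):
                instances = [None] if (multi_split and multi_sd) else choice_ids
                worst = None
                for inst in instances:
                    cfg = PipelineConfig(**{**asdict(config)})
                    for name in ("ks", "taus", "n_mins", "deltas"):
                        setattr(cfg, name, tuple(getattr(config, name)))
                    cfg.relaxation = relax
                    res = _run_variant(cfg, dev_table, test_table, multi_split, multi_sd, inst)
                    if worst is None or _worse(res, worst):
                        worst = res
                rows.append(
                    {
                        "relaxation": relax,
                        "splits": "multiple" if multi_split else "single",
                        "state_definitions": "multiple" if multi_sd else "single",
                        **worst,
                    }
                )
    return pd.DataFrame(rows)


def _worse(a: dict, b: dict) -> bool:
    if a["status"] != "ok":
        return True
    if b["status"] != "ok":
        return False
    return a["improvement"] < b["improvement"]


def _run_variant(cfg, dev_table, test_table, multi_split, multi_sd, choice) -> dict:
    """One ablation instance; collapses partitions / state definitions as asked."""
    seeds = child_seeds(cfg.seed, 5)
    partitions = make_partitions(
        dev_table["stay_id"], n_partitions=cfg.n_partitions,
        val_frac=cfg.val_frac, seed=seeds[0],
    )
    from .ssr import fit_state_definitions

    sd_parts = partitions if multi_sd else [partitions[choice or 0]]
    sds, assignments, audit = fit_state_definitions(
        dev_table, sd_parts, cfg.grid.ks, embedding_dim=cfg.embedding_dim,
        runs=cfg.ensemble_runs, seed=seeds[1], subsample_cap=cfg.subsample_cap,
    )
    search_parts = partitions if multi_split else [partitions[choice or 0]]
    report = grid_search(
        dev_table, search_parts, cfg.grid, ess_cutoff=cfg.ess_cutoff,
        gamma=cfg.gamma, alpha=cfg.alpha, tol=cfg.tol, seed=seeds[1],
        state_definitions=sds, assignments=assignments,
    )
    report.fit_audit.update(audit)
    try:
        final = select_and_retrain(report, dev_table, gamma=cfg.gamma, alpha=cfg.alpha, tol=cfg.tol)
    except NoViablePolicyError:
        return {
            "status": "no_viable_policy", "improvement": np.nan,
            "improvement_ci": None, "mortality_pct": np.nan,
            "pct_outperformed": np.nan,
        }
    evaluation, _ = evaluate_final(final, test_table, gamma=cfg.gamma, B=cfg.B, seed=seeds[3])
    return {
        "status": "ok",
        "improvement": evaluation["value_improvement"],
        "improvement_ci": evaluation["value_improvement_ci"],
        "mortality_pct": evaluation["mortality_learned_pct"],
        "pct_outperformed": evaluation["pct_outperformed"],
    }
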