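# Methods

This note documents the models and procedures implemented in `proprl`, the
defaults chosen where the design was open, and what the simulation studies
do and do not establish.

## Decision process

A hospitalization is a finite-horizon episode of at most 10 decision points.
Raw records are cut into decision windows: window 1 covers the first 24 h
after admission, window 2 ends at the first boundary hour (default 6 AM,
when most clinical rounds happen) strictly after that, and all later windows
run boundary-to-boundary; analysis stops at 8 days. Stays spanning fewer
than two windows are excluded. The exact first/second-window boundaries are
a package convention (configurable): it is consistent with a 24-hour initial
assessment period and with only the first two windows being irregular.

Treatment decisions made within a window are assumed to rest on the state
observed in the previous window, so the RL transition tuple is
`(state of window t, action of window t+1, state of window t+1)`. That shift
is applied in exactly one place (`windows.decision_view`); every downstream
module consumes the shifted decision-step table. A consequence worth noting:
a stay with `T` windows contributes `T − 1` decision steps, and the action
recorded in the first window (taken before any state was observed) drops out.

Rewards are 0 at every non-terminal step; `+100`/`−100` is received on
arrival at the discharge/death absorbing state. With discount `γ`, a
trajectory with `T` decision steps returns `γ^T · r_terminal`; a certain
one-step discharge is therefore worth `γ · 100 = 99`. For stays truncated at
8 days the terminal reward uses the eventual in-hospital outcome by default
(`truncated_as_alive=True` switches to scoring truncation as alive).
Timestamps are timezone-naive local clock times; durations are elapsed
hours.

## State space

Features are z-scored (fit on the training split only; constant columns get
unit scale) and embedded. The embedding is a pluggable contract —
deterministic under a seed, defined for any real feature vector — and the
default is PCA to 8 dimensions. PCA was chosen as the default because it is
deterministic, dependency-light, and sufficient for the pipeline's
correctness, which does not hinge on the encoder; a learned autoencoder can
be dropped in behind the same contract.

States are nearest-center assignments to `k` cluster centers (ties to the
lowest id). Centers come from a single seeded k-means fit (`runs=1`) or a
cluster ensemble: `runs` seeded k-means fits on a capped subsample, a
co-association frequency matrix, an average-linkage agglomerative cut into
`k` groups, and group means as centers. If nearest-center assignment leaves
a state empty on the training data, the largest state is re-split (logged).

Diagnostics screen a definition before any policy is learned: the fraction
of trajectories visiting ≥ 2 distinct states (default threshold 0.95,
configurable — note that single-decision-step stays can never pass), the
maximum occupancy share (default `5/k`), and per-state aggregates
(mortality, previous/next treatment rates, named feature means) with a 2-D
PCA projection of the centers for visual inspection.

## Behavior policy

`π_b(1|s) = (n(s,1) + α) / (n(s) + 2α)` with `α = 0` by default — the plain
per-state average observed action. Unseen states get 0.5. `α > 0` exists for
WIS stability on held-out data, where an estimated zero probability on an
observed action would make an importance weight undefined. The sanity check
compares the WIS mortality estimate of `π_b` on held-out data (all weights 1
when a policy is evaluated against itself, so on its own fitting set the
estimate equals the empirical death fraction exactly) with the empirical
mortality, and tabulates `π_b(1|s)` against per-state feature aggregates.
Disagreement between a policy and the data is the mean over windows of
`1 − π(a_observed|s)`, with a stay-level bootstrap CI; applied to `π_b`
itself it measures clinician-to-clinician variation.

## Constrained policy learning

The tabular MDP uses maximum-likelihood transition frequencies over the `k`
states plus two absorbing terminals. Backups are
`Q(s,a) = γ Σ_{s'} P̂(s'|s,a) (R(s') + V(s'))` with `V` zero at terminals and
`V(s) = max_{a ∈ allowed(s)} Q(s,a)`. Value iteration stops when the
sup-norm change falls below `tol = 1e−8` (≤ 10,000 sweeps); the final Q is
within `tol·γ/(1−γ)` of the fixed point and all values are bounded by 100.

Safeguards against extrapolation error:

* **BCQ mask** — `allowed(s) = {a : π_b(a|s) ≥ τ · max_a' π_b(a'|s)}`, the
  standard relative-threshold discrete form; never empty.
* **Pessimism** — pairs with `n(s,a) < n_min` are routed to the death
  terminal (`Q = −100γ` for a one-step consequence). Never-observed pairs
  are always routed there, since their ML transition row is undefined. A
  softer subtractive penalty `n_min/√n(s,a)` is available behind the same
  knob (`pessimism="penalty"`). Routing is monotone: raising `n_min` can
  only lower values.
* **Tie-break** — argmax ties resolve to action 0 (no treatment), the
  conservative clinical default.

**Relaxation.** A state is *unimportant* when the spread (max−min, i.e. the
absolute gap for binary actions) of Q over its allowed actions is below `δ`:
no available action meaningfully changes the outcome there, so the policy
defers to the clinician, minimizing workflow disruption and alert load.
`δ = 0` relaxes nothing; `δ = ∞` returns the behavior policy. A non-deferring
state is *divergent* when clinicians take the recommended action less than
half the time (`π_b(recommended|s) < 0.5`).

## Off-policy evaluation

WIS: per-trajectory weights `w_i = Π_t π_e(a_t|s_t)/π_b(a_t|s_t)`,
`Ĵ = Σ w_i G_i / Σ w_i`, `ESS = (Σw)²/Σw²`. Mortality is estimated by
applying the same weights to the death indicator — chosen so the behavior
policy's estimated mortality equals the empirical rate exactly; a linear
value-to-mortality mapping would not have that property. A step where `π_e`
has zero mass zeroes the trajectory weight; a zero *behavior* probability on
an observed action is an error (impossible on the fitting set with `α = 0`).
Two policies with identical probability tables produce weights identically 1.

Auxiliary estimators: FQE solves `Q^{π_e}` on the empirical transition table
by iterative backups (never-observed pairs needed by `π_e` default
pessimistically to −100, with a warning); the approximate-model estimate
evaluates `π_e` exactly on the estimated MDP by a linear solve; WDR combines
stepwise importance weights (normalized across trajectories at each step,
persisting past trajectory end) with the Q-based control variate and reduces
to stepwise WIS when `Q̂ ≡ 0`.

Comparisons use a paired bootstrap over whole trajectories (default
`B = 1000`): each replicate computes WIS for both policies on the same
resample. The reported improvement is the full-sample difference (so the
report is internally consistent); the CI and the one-sided P come from the
replicate distribution. P uses the mid-P convention —
`P = mean(improvement < 0) + 0.5 · mean(improvement = 0)` — which equals the
conventional definition whenever ties have probability ≈ 0 and yields the
correct `P = 0.5` in the fully degenerate case of a policy compared against
itself. Percentile CIs (not BCa) are used throughout for reproducibility
under seeds.

## Split-Select-Retrain

The development set is split `n_partitions = 10` times (default; the
simulation studies use 5) into stay-level train/validation splits with
`val_frac = 0.25`. For every combination of state definition `(j, k)` and
policy knobs `(τ, n_min, δ)`, a policy is trained on each partition's
training split and scored by WIS on its validation split. A point is
unreliable on a partition when its ESS is below `ess_cutoff = 0.10` of the
validation size (or its estimate is undefined); points unreliable anywhere
are excluded. Selection maximizes the unweighted mean validation WIS (median
available by configuration), breaking ties toward larger mean ESS, then
smaller `k`, then deterministic table order. The selected state definition
is kept fixed and the behavior policy, MDP, and constrained policy are refit
on the entire development set. No reliable point is a structured
`NoViablePolicyError` (distinct process exit code in the CLI), not a crash.

Grid defaults — `k ∈ {20, 40, …, 160}`, `τ ∈ {0, 0.1, 0.3}`,
`n_min ∈ {0, 5, 20}`, `δ ∈ {0, 1, 5, ∞}` — are package choices; `δ` is on
the terminal-reward scale of ±100.

The ablation harness reruns the pipeline with relaxation off (`δ` grid
collapsed to 0), a single partition, and/or a single state definition.
Single-choice variants are rerun for each possible choice of the single
partition and the worst-case test improvement is reported, since sensitivity
to that choice is precisely what the ablation measures.

## Ground-truth simulator

The simulator emulates the *structure* of an inpatient cohort, not its
physiology: `K` latent states with a Dirichlet-sampled continuation kernel;
per-state per-action death and discharge hazards applied at every step;
horizons capped at 10 steps with survivors scored as discharged alive;
Gaussian feature emissions per latent state; and a behavior policy that
mixes a softmax over the environment's true action values with uniform
noise (`π_b = ε/2 + (1−ε)·softmax(Q_true/temperature)`), guaranteeing the
support overlap WIS requires while retaining clinician-like skill and
heterogeneity.

Defaults, chosen once to mirror a realistic acute-care cohort: base death
hazard per step `U(0.004, 0.02)` and discharge hazard `U(0.10, 0.25)`, which
give roughly 5–10% in-hospital mortality and ~5 decision steps per stay;
treatment alters only the death hazard, by `effect_size = 0.05` per step in
a `responsive_fraction = 0.4` share of states (`effect_size = 0` yields a
null environment in which outcomes are provably policy-invariant);
`ε = 0.3`, `temperature = 5` (≈ 0.75 propensity for the better action in
responsive states); emission centers rescaled so the closest pair is 6
standard deviations apart, which makes latent states recoverable by the
state-learning step — deliberately favorable, see limitations. An optional
carryover term adds a previous-action signature to the emissions (off by
default; with it off, marginalizing a learned-state policy onto the latent
states via sampled emissions is exact up to Monte-Carlo error, which the
oracle composition relies on).

The oracle evaluates any latent-state policy exactly by backward induction
over the 10-step horizon, returning the true value and the true death
probability. Policies defined on learned states are first marginalized onto
latent states with 4,000 sampled emissions per state.

## Validation studies and their scope

The recovery study (`proprl.study`) simulates 2,000 development and 2,000
test stays (`K = 10`, `d = 20`), runs the full pipeline with a reduced grid
(`k ∈ {5, 10, 20}`, 5 partitions, ensemble of 3 on a 1,000-point subsample —
sizes chosen to keep a replicate in a few seconds) and scores the final
policy with the oracle. Across 20 replicate seeds the learned policy's true
value matches or beats the clinicians' in ≥ 18, and the 95% bootstrap WIS
interval covers the oracle value in ≥ 17. In the null environment the median
replicate defers in ≥ 90% of states; single null replicates occasionally
select a small `δ` (all points have identical true value there, so the
WIS-argmax is noise-driven — an inherent property of selection by estimated
performance) and defer in fewer.

What passing these studies does **not** show: robustness to non-Markov
dynamics, confounded treatment assignment, emission overlap between latent
states, missing or irregular measurements, or behavior drift between
development and test periods — all present in real EHR cohorts and all
outside the simulator by design. The studies establish that the machinery is
correct and that the selection-and-relaxation logic behaves as intended when
its assumptions hold.

## Numerical notes

Every stochastic stage takes an explicit seed; nested seeds derive from
`numpy.random.SeedSequence`. Value iteration in the grid search batches all
`(τ, n_min)` cells of a partition into one stacked update loop — identical
arithmetic to the single-problem path, verified against independently run
cells to 1e−9. Degenerate inputs: empty validation resamples are dropped and
counted in bootstrap results; a policy putting mass on an action with zero
estimated behavior probability is unreliable-flagged during search and an
error elsewhere; empty datasets raise.
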