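# Methods

This note documents the models implemented in `sailrl`, the estimation
machinery, the defaults chosen where the design was genuinely open, and what
the simulation-based tests do and do not establish.

## Task environment

A session consists of `n_pairs = 200` alternating traversal / non-traversal
trial pairs. Boats 0–1 belong to island 0 and boats 2–3 to island 1; all
indices are 0-based. Rewards are Bernoulli with per-boat probabilities drawn
from the canonical set {0.15, 0.325, 0.675, 0.85}, arranged so that each
island always hosts one high/low pair averaging 0.5 — islands never differ
in expected reward under random boat sampling. Probabilities are constant
within a block and permuted between blocks by one of three operators:

* **congruent** — the two island-wise optimal probabilities trade places,
  as do the two suboptimal ones;
* **incongruent (cross-island)** — each island's optimal probability trades
  with the other island's suboptimal one;
* **incongruent (within-island)** — the two probabilities on each island
  trade places.

All three preserve per-island means and are involutions on island-balanced
assignments; `apply_swap` rejects vectors that are not decomposable into one
optimal and one suboptimal boat per island with equal island means.

A default session has 22 blocks of 8–12 pairs and 21 transitions: 15
congruent, 3 incongruent-cross, 3 incongruent-within, in a seeded uniform
permutation (no spacing constraint is imposed, as none is specified for the
task). Block lengths are drawn by sequential constrained sampling — each
length uniform over the values that keep the remaining total feasible —
which guarantees an exact sum without rejection loops. Blocks switch only at
pair boundaries, so a pair's non-traversal trial always shares its
traversal trial's probabilities. Per-subject randomization of boat
identities is modeled as a structured permutation (which island hosts which
probability pair × within-island order, 8 variants); an arbitrary
permutation of the four values would break the equal-island-mean invariant
and is therefore not used. Non-traversal presentation order is a seeded
global shuffle with each boat appearing exactly `n_pairs / 4` (= 50) times.

## Mixture-of-agents choice model

All agents share one boat-value estimate per boat, updated by a delta rule

    V(b) ← (1 − α) V(b) + α R,

with the *active* rate `α_A` on traversal trials and the *passive* rate
`α_P` on non-traversal trials. Island values come from three systems:

* **MB**: `V_MB(i) = max(V(b_i1), V(b_i2))`;
* **SR**: `V_SR = M R`, where the 2×4 occupancy matrix `M` is row-stochastic
  with support restricted to each island's own boats and learned by a
  Hebbian rule, `M[i,b] ← α_M 1{b = chosen} + (1 − α_M) M[i,b]`, applied to
  *both* boats of the visited island (the indicator is 0 for the unchosen
  boat), which preserves row normalization. The reward vector `R` is taken
  to be the learned boat values — the only per-boat reward estimate the
  model maintains;
* **TD(1)**: `V_TD(i) ← (1 − α_A) V_TD(i) + α_A V(b_chosen)`, a cached
  island value with no world model, updated at the end of each traversal
  trial so that it bootstraps from the just-updated boat value.

Choice is softmax at both stages:

    P(island i) ∝ exp(β_MB V_MB(i) + β_SR V_SR(i) + β_TD V_TD(i)
                      + β_persistenceI · LastChosen(i))
    P(boat b | i) ∝ exp(β_boat V(b) + β_persistenceB · LastChosen(b))

Initialization is uninformative: all values at the reward midpoint 0.5,
occupancy rows uniform, no last-chosen indicators (perseveration contributes
nothing on the first trial). Non-traversal trials update only the sampled
boat's value: no island is visited, so `M`, `V_TD` and the perseveration
indicators are untouched.

## Linear RL

The alternative single-computation model evaluates islands under a learned
default transition model `T` (same Hebbian update and initialization as the
SR's `M`) through an exponential nonlinearity with temporal-abstraction
scale λ:

    v*(i) = λ · log Σ_b T[i,b] · exp(V(b)/λ).

As λ → 0 this approaches the per-island max (MB); as λ → ∞ the T-weighted
mean (the SR value with occupancy `T`). The general default-representation
matrix `M = (diag(exp(−r_N/λ)) − T_NN)^{-1}` is implemented for arbitrary
chains (and checked against a truncated Neumann series in the tests); in
this task islands lead only to terminal boats and island rewards are zero,
so it reduces to the identity. Values are always computed in log space with
a max shift — the literal exponential form overflows for λ ≲ 0.05 with boat
values near 1. The convergence to the max carries an `O(λ·|log T[i,b]|)`
offset, so numerical limit checks use moderately mixed rows. The
computational-precision cost of MB-like evaluation is exposed as
`value_magnitude` = `max_b exp(V(b)/λ)`, which grows without bound as λ
shrinks.

Island choice is `P(i) ∝ exp(β_island v*(i) + β_persistenceI LastChosen(i))`;
the boat stage is shared with the mixture model. The blockwise linear-RL
variant additionally carries a TD temperature per block type, matching the
descriptive model it is compared with; the plain variant fixes it at zero.

## Synthetic cohorts

`simulate` plays parameterized agents through generated schedules; the logs
are schema-identical to real session logs, and ground-truth parameters live
in a sidecar table only. Simulated agents carry no perseveration terms;
those parameters enter only when fitting (where they absorb choice inertia
in real data). Preset parameter values are package constants: learning
rates 0.3, boat temperature 5, and island temperatures 5 (pure agents),
2.5/2.5/0.5 (hybrid), chosen so that choices are clearly value-driven yet
stochastic given that island values differ by at most ~0.35 on the reward
scale. The blockwise-adaptive preset uses w_SR+ = 0.75 and w_SR− = 0.25 at
combined temperature 5; the block-insensitive control uses identical (+)
and (−) hybrid sets. Gaussian cohorts draw subject parameters on the
*transformed* scale of the fitting model (logit learning rates and SR
weight, log positive temperatures), so recovered group means are directly
comparable to generating ones. Per-subject RNG streams are spawned from a
root `SeedSequence`, making cohorts stable under size changes.

## Hierarchical estimation

The session likelihood sums, over traversal trials, the island- and
boat-choice log probabilities, with learning applied in trial order;
non-traversal trials contribute learning only. A compiled (numba) kernel
evaluates this inside the optimizer; the pure-numpy step functions are the
reference implementation and the test suite requires agreement to 1e-10.

Free parameters are estimated on unconstrained scales (logit: learning
rates, `w_SR`; log: `β_MBSR`, λ; identity: signed temperatures and
perseveration weights; transforms round-trip to 1e-10). Estimation is
expectation-maximization with a Laplace approximation:

* **E-step**: per-subject MAP under the current group Gaussian
  (multi-start L-BFGS from the prior mean, jittered restarts and a warm
  start from the previous iteration), with the Hessian of the negative log
  posterior at the MAP from central finite differences;
* **M-step**: group mean = mean of MAPs; group variance = mean of squared
  deviations *plus* per-subject Laplace variances (inverse-Hessian
  diagonal) — omitting the correction would bias the variance toward zero.

Iteration stops when the group mean moves less than 1e-3 (default; max 200
iterations). The group variance is floored at 1e-6; with duplicated
subjects the between-subject component collapses and the estimate shrinks
toward the Laplace floor, as it should. Group-level standard errors use an
information matrix that accounts for E-step uncertainty ("missing
information"): each subject contributes `(Σ + C_i)^{-1}`, where `C_i` is
the Laplace covariance of that subject's likelihood (posterior Hessian
minus prior precision, eigenvalue-floored when the likelihood is locally
flat). This is a Laplace-based approximation; exact reproduction of any
particular reference implementation's bookkeeping is not claimed.

The blockwise analysis re-parameterizes the island stage per block type as
`(w_SR±, β_MBSR±, β_TD±)` with `β_MB± = (1 − w_SR±) β_MBSR±` and
`β_SR± = w_SR± β_MBSR±`; the likelihood is invariant under this change of
variables (tested). The (+) set applies on blocks following congruent
changes, the (−) set after incongruent ones. The session's first block has
no preceding change and is assigned to the (+) set, treating the stable
initial environment as congruent; boat-stage parameters are shared across
block types. Contrasts on the group means are tested with Wald statistics;
nonlinear contrasts such as `log(w_SR+) − log(w_SR−)` use the delta method
on the full group-mean covariance. Degrees of freedom follow the
observation-count convention (total island-choice observations minus the
number of group-level parameters); this convention is a documented choice,
as others exist.

## Regression signatures

One design row is built per (non-traversal, following traversal) pair; the
outcome is whether the next traversal chose the sampled boat's island.
Primary regressors are coded −0.5/+0.5: `rwd` (sampled boat rewarded),
`sibNoRwd` (the *most recently observed* outcome of the island sibling —
from either trial type — was unrewarded), `onPolicy` (the previous
traversal choice at that island was the sampled boat), plus the products
`rwd×sibNoRwd` and `rwd×onPolicy`. Lagged controls are coded 0/1 for past
events: neighbor-boat outcome lags 2–5 (lag 1 being `sibNoRwd`), same-island
choice lags 2–5 (lag 1 being `onPolicy`), sampled-boat outcome lags 1–5,
each with its `rwd` interaction; plus five centered lags of the opposite
island's running value (the mean of each opposite boat's empirical outcome
average over its full observed history, snapshotted at the end of each
pair — a model-free proxy, since the analysis should not presuppose a
learning model) and five ±0.5-coded lags of an island choice kernel (was
each of the last five traversals toward the sampled island). Rows whose
primary regressors are undefined (sibling never observed; island never
chosen) are dropped; out-of-history lags are zero-filled; both policies are
switchable.

The hierarchical logistic model gives every subject random coefficients for
the intercept and the primary terms (Gaussian population), with the ~36 lag
controls as shared fixed effects — per-subject slopes on all controls would
not be identifiable at typical cohort sizes. It is fit by the same
Laplace/EM scheme as the choice models, with analytic logistic
gradients/Hessians (damped Newton per subject, one pooled Newton step for
the fixed effects per EM iteration). Group means are tested with Wald z
statistics using the missing-information-corrected covariance; fixed
effects use the pooled curvature (ignoring cross-terms with the random
effects — adequate for nuisance controls, and documented as such). With
preset cohorts the true between-subject variance is zero, so the group
variance decays slowly toward its floor and the convergence flag may stay
false at the default tolerance; the group means are stable well before
that.

## Problem sizes used in the test suite

End-to-end checks run at 30 subjects × 200 trial pairs — the full session
length, with the cohort scaled to what a single-core run completes in a few
minutes. At these sizes, fitted group means recover generating values
within 0.25 transformed units; pure-MB and pure-SR cohorts classify to
group `w_SR` below 0.2 and above 0.8; the blockwise-adaptive cohort yields
a significantly positive `log(w_SR+) − log(w_SR−)` contrast while the
block-insensitive control does not; and the regression signatures show the
expected double dissociation (MB: `rwd×sibNoRwd` only; SR: `rwd×onPolicy`
only; hybrid: both, with the main reward effect attenuated when the
interactions are included).

## Limitations

* Simulated agents are exactly the models being fit (plus known presets);
  passing recovery and signature tests shows the pipeline is self-
  consistent and identifiable at these scales, not that the models describe
  any particular real dataset. Real data add reaction times, lapses,
  session-level nonstationarity and exclusion criteria that the generator
  deliberately omits.
* `w_SR` is weakly identified within a single session (MB and SR values
  correlate strongly under a learned, mostly-greedy policy); separation
  relies on hierarchical pooling.
* The E-step uses finite-difference Hessians and L-BFGS; likelihoods are
  not globally convex, and the multi-start scheme reduces but does not
  eliminate the chance of local optima.
* The regression engine is a Laplace/EM approximation to a generalized
  linear mixed model, not an exact marginal-likelihood maximizer; its
  fixed-effect standard errors ignore random-effect cross-terms.
* The linear-RL default representation reduces to the identity in this
  two-step task; the general matrix inverse is exercised only on synthetic
  chains in the tests.
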