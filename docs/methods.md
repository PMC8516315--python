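# Methods

## The task

`viforage` simulates and analyzes the discrete variable-interval (VI)
reward schedule, a two-alternative foraging task in which reward
availability is coupled to choice history. Each option `i` carries a
*set* reward probability `pset[i]`. On every trial a reward is
(conceptually) baited onto each option with probability `pset[i]`;
once baited it persists until the option is chosen. The momentary
probability that choosing option `i` pays out therefore obeys

    p[i, t+1] = 1 - (1 - pset[i, t]) * (1 - p[i, t] * (1 - delta[i, t]))

with `delta[i, t] = 1` when `i` was chosen at trial `t`. Under a
constant `pset`, `ti` completed trials of neglect give the closed form
`p = 1 - (1 - pset)^(ti + 1)`. The implementation draws rewards as
Bernoulli trials on the tracked probability rather than keeping
explicit bait flags; the two are distributionally identical (verified
by a bait-bookkeeping oracle in the test suite) and the probability
form matches the update rule literally.

Conventions the equations leave open, fixed here:

* Trials are 1-based; `ti` counts completed trials since last choice,
  so `ti = 0` immediately after an option is chosen and the momentary
  probability exponent is `ti + 1` everywhere (including inside the IB
  agent's likelihood, where an alternative statement of the same
  quantity drops the `+1`).
* At `t = 1`, `p = pset` of the first block (the closed form with
  `ti = 0`).
* At block transitions the chosen option resets to the *new* block's
  set probability while unchosen options carry their accumulated `p`
  forward and continue to grow under the new `pset`.

Protocol generators reproduce the study conditions: mouse-like
sessions (9 blocks of U{50..150} trials, pairs from {0.25:0.25,
0.40:0.10, 0.10:0.40}), human-like sessions (>= 6 blocks of U{20..30}
trials, pairs {0.40:0.10, 0.10:0.40}), and the uniform-[0, 0.5]
single-block condition used for the Oracle analyses.

## Agents

All agents implement one choose/update contract. Only the Oracle is
handed the true momentary probabilities; every other agent sees
nothing but its own choices and outcomes (enforced by a test that
feeds agents observations with and without the true probabilities).

**Oracle** — greedy argmax of the true momentary probabilities; ties
are split uniformly at random (they arise only for equal `pset` at
equal neglect). On constant 0.1:0.4 the greedy cycle visits the lean
option exactly every fifth trial, since `1 - 0.9^5 = 0.40951` first
exceeds 0.4 after four trials of neglect.

**Inference-based (IB)** — each option carries N = 1000 particles over
its set probability, initialized uniform on [0, 1]. A particle's
predicted momentary probability is the closed form at the current
neglect count; the option value is the particle mean of those
predictions and actions are softmax in the values. After feedback the
*chosen* option's cloud is reweighted by the Bernoulli likelihood of
the outcome, resampled multinomially in proportion to posterior mass,
jittered by U[-0.025, 0.025] and clipped to [0, 1]; the unchosen
cloud is untouched (its likelihood factor is flat). If every weight
underflows (a reward observed when all particles say impossible) the
cloud is resampled uniformly and a warning is emitted. The softmax
inverse temperature is not pinned down by the source description; it
is exposed as a parameter with default 10, sharp enough to harvest
near-greedily while still sampling the lean option.

**LK** — learns the set probability by a Rescorla–Wagner rule on the
chosen option (`Qset`), and a per-option baiting factor `psi` that
resets to 0 when chosen and relaxes toward 1 while unchosen at an
adaptive rate `alpha_psi` driven by the reward prediction error
(`alpha_psi += tau_psi * ((PE + 1)/2 - alpha_psi)`, well-defined for
rewards in [0, 1]). The momentary value recombines the two through
the baiting recursion `Q = 1 - (1 - Qset)(1 - Q * psi)`. The
within-trial order is PE, then `Qset`, then `alpha_psi`, then `psi`,
then `Q`, so the recursion uses the already-updated `psi`. Initial
state is not specified by the source equations; `Qset = Q = 0.5`
(uninformative probability estimates), `psi = 0`, `alpha_psi = 0.5`.

**Double trace (DT)** — a forgetting-Q learner with two choice traces:

    Q <- Q + alpha * (delta * R - Q)         (both options)
    F <- F + tau_f * (delta - F),  S <- S + tau_s * (delta - S)

and softmax values `Q + phi * F + vartheta * S`. `Q` starts at 0 (the
forgetting fixed point for never-chosen options) and `F, S` at 0.5
each, which makes `F_l + F_r = 1` and `S_l + S_r = 1` exact at every
trial. The constrained variant used for regret optimization enforces
`phi <= 0` (short-term alternation) and `vartheta >= 0` (long-term
perseverance) at construction.

**Comparison models** — indirect actor (chosen-option RW, unchosen
frozen), direct actor (policy-style update scaled by `R - c` with an
average-reward offset `c`), F-Q (forgetting-Q), F-Q with one choice
trace, and F-Q "up" (unchosen values grow toward a ceiling `C`;
initial Q uniform on [0, 1]).

### DT model and the lagged logistic form

Unrolling the recursions turns the DT choice probability into a
logistic function of lagged regressors: reward coefficients
`alpha (1-alpha)^(m-1)` on the signed reward history, and choice
coefficients `phi tau_f (1-tau_f)^(m-1) + vartheta tau_s (1-tau_s)^(m-1)`
with the factor-2 {0,1} choice coding and constant offset
`-(phi + vartheta)` from the trace-complement identity. Two
bookkeeping notes. First, the decay family can be written with the
learning rate as base (`tau^(m-1)`) or its complement
(`(1-tau)^(m-1)`); the recursion is exact in the complement form,
which the equivalence tests use, while `trace_shapes` and
`fit_decay_model` report the rate-as-base parameterization. Second,
the sign of the constant offset follows from the complement identity;
tests verify the resulting probabilities agree with the recursive
model to better than 1e-6 after a 100-trial burn-in (initial-condition
terms decay like `(1-tau)^t`, hence the burn-in and the `tau >= 0.2`
restriction in those tests).

Because the two trace components enter the value symmetrically, a
fitted DT parameter vector is only identified up to exchanging
`(phi, tau_f)` with `(vartheta, tau_s)`; `canonicalize_dt` resolves
the label symmetry by placing the more negative scaling in the fast
slot, without changing the likelihood.

## History regression

`build_design` produces, for every usable trial, M lags of the signed
reward `R = R_right - R_left` in {-1, 0, +1} and M lags of the choice
indicator in {0, 1}; the response is the current choice (1 = right).
The first M trials of each session are dropped so no row mixes
history across sessions. The extended design has six blocks in fixed
order — unsigned rewards, choices, right rewards, left rewards, right
no-rewards, left no-rewards — where a "no-reward" indicator marks an
unrewarded choice of that side; exactly one of the four signed
outcome indicators is active per trial.

The fit is a logistic regression penalized by
`lambda * sum(0.25 b^2 + 0.5 |b|)`, i.e. an elastic net with fixed
equal L1/L2 mixing. It is computed with scikit-learn's saga solver
(`l1_ratio = 0.5`, `C = 1/(n lambda)`, warm-started down a descending
lambda path); the intercept is unpenalized. `lambda` is chosen at the
minimum mean held-out binomial deviance in a 5-fold cross-validation
whose folds are contiguous row blocks (rotated by a seeded offset),
limiting leakage through the serial correlation of behavioral data;
the final coefficients are refit once on all rows. The default grid
is 50 log-spaced values on [1e-4, 10]; no grid was prescribed. Fits
are re-tuned per call; callers comparing sessions can pass a fixed
one-point grid to share a lambda.

`fit_decay_model` inverts fitted coefficient curves into decay
parameters: a bounded scalar fit for the reward curve and a
multistart bounded least-squares fit (36 starts over a tau grid) for
the two-exponential choice curve, with the components canonically
ordered `tau_f >= tau_s`. A flat zero choice curve makes the decays
unidentifiable and is returned as a flagged degenerate fit.
`condition_correlation` implements the session-sorting analysis:
Pearson correlation of lag-1 coefficients with a per-session
covariate plus tercile summaries.

## Likelihood fitting and model comparison

Likelihoods are computed by teacher forcing: replay a recorded
session through the model, score the probability of each recorded
choice, then update with the recorded choice and outcome.
Probabilities are floored at 1e-12 before the log. The fit search
mimics simulated annealing: 1000 draws per iteration (uniform over
the bounds first — `alpha, tau_* in [0,1]`, `beta in [0,50]`, scaling
factors and the extra scalar in [-25, 25] — then Gaussian around the
mean/SD of the top 1%, clipped to bounds), stopping when the best
mean log-likelihood changes by less than 0.01% in relative magnitude
for two consecutive iterations, with an iteration cap of 50. The
stopping phrase in the source is ambiguous between a ratio and a
relative-change reading; the relative-change reading is implemented.
Because the proposal can contract into a local basin (the DT
likelihood has a ridge trading `beta` against the scaling factors),
the search runs 3 independent restarts by default and keeps the
highest-likelihood result. A `tau_m` bound appears in the stated
search space but no shipped model carries a third trace; configs may
include it and it is ignored.

Scoring hundreds of parameter vectors is made tractable by a
vectorized engine (`viforage._engine`) that broadcasts the state
recursions over draws — and, for the two-option forgetting-Q family,
over sessions, using exact value-difference recursions. The
object-oriented agents remain the reference implementation and the
test suite pins the two routes to each other at 1e-9.

Model comparison is 5-fold cross-validation on contiguous blocks of
the concatenated trials (a boundary falling inside a session splits
it into independently replayed segments), with fold assignment shared
across models. Held-out metrics are per-trial negative log-likelihood
and AUC (Mann–Whitney formulation, ties counted half; an O(n^2)
pair-counting oracle backs it in the tests). Bayesian model selection
(exceedance probabilities) is out of scope; cross-validated NLL/AUC
is the comparison currency.

## Regret and policy optimization

Regret is `sum_t max_a p[a, t] - sum_t R_t` along the realized
trajectory (default), or alternatively relative to an independent
Oracle run on the same schedule; both baselines are implemented
because both readings appear in the benchmark descriptions, and the
trajectory form is the default. Named conditions cover the volatility
benchmark (blocks of 50/100/500 trials, pair 0.10:0.40 alternating)
and the set-probability-difference benchmark (100-trial blocks; pair
families {0.20:0.80, 0.30:0.70, 0.40:0.60} and {0.45:0.05, 0.40:0.10,
0.35:0.15} are both available as conditions, neither privileged, as
the source lists both).

Optimization draws uniformly within the harvesting bounds
(`beta in [0, 10]`, `phi in [-2, 0]`, `vartheta in [0, 2]`, rates in
[0, 1] — the sign constraints of the constrained DT are the bounds),
scores each draw by mean regret over 4 fresh 1000-trial sessions,
keeps the lowest 5%, redraws Gaussian proposals at 3 standard
deviations spread, keeps the lowest 10%, and re-tests each survivor
100 times before returning the lowest mean. Per-draw evaluation seeds
fan out from the master seed so each draw faces different reward
randomness. The source's draw counts are internally inconsistent
(10,000 initial draws described, 1,000 referenced later); the counts
are configuration knobs with defaults of 10,000 / 5,000, and the
scaled-down benchmarks in the tests use 500.

## Synthetic data and study conditions

The recovery generator runs the DT model closed-loop on 100-trial
blocks alternating 0.1:0.4 / 0.4:0.1 (1000 trials per session) — the
protocol of the recovery study — with true parameters drawn from
`alpha, tau_f, tau_s in [0, 1]`, `beta, vartheta in [0, 4]`,
`phi in [-4, 0]`. The manifest records truth and per-session seeds,
and flags the `tau_f == tau_s` degeneracy. The mouse-fit
(`alpha=0.75, beta=1.60, tau_f=0.71, tau_s=0.24, vartheta=3.31,
phi=-2.22`) and human-fit parameter sets ship as named constants and
serve as realistic generating conditions.

What the generator emulates: the trial-level contingency between
choices and reward availability, block structure, and the studied
probability pairs. What it does not: reaction times, inter-trial
timing, motivational drift, or session-length variability driven by
subject state. Tests passing on synthetic data therefore validate the
estimators' internal consistency (parameter recovery, model-selection
dominance of the generating model, regression signatures), not claims
about any particular animal dataset.

## Problem sizes and numerical choices

The shipped benchmark sizes are chosen to be informative at desk
scale: 30 sessions x 1000 trials per probability pair for the IB
recovery; 40 sessions for the uniform-pset regression shape; 100
generate-and-refit draws (500 annealing draws, 2 restarts) for the
recovery study; 500 initial draws for the regret optimizations, with
50-session evaluations. Determinism: every stochastic component takes
an injected `numpy.random.Generator`; master seeds fan out to
per-session and per-draw seeds below 2^31.

One empirical caveat surfaced by the test suite: in the
uniform-[0, 0.5] Oracle condition the choice-history curve's
crossover from alternation (negative coefficients) to perseverance
(positive) sits around lag 5–6 rather than immediately after the
first lags — greedy cycling against uniformly drawn probability
pairs concentrates positive structure at the cycle periods, and lags
just below the typical period stay negative. Coefficients near the
crossover are weak, and at small session counts the L1 part of the
penalty can shrink them exactly to zero.

Known limitations: the value-difference fast path and the
logistic-equivalence results are two-option only (the softmax itself
supports more options); penalized regression coefficients come
without standard errors by design; the direct actor's likelihood can
degenerate when `|c|` is large (its probability-dependent update can
push values apart without bound), mirroring its known instability in
model comparison; and the LK model's adaptive baiting-rate update
makes its likelihood surface rough, so fits benefit from the restart
mechanism.
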