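# Methods

## Model

`ddmcrowd` treats each crowd annotator as a drift-diffusion decision maker.
For item *i* with hidden binary class `z_i`, annotator *j* runs an evidence
process

    dX = mu dt + sigma dW,   X(0) = 0,

between absorbing boundaries at −1 and +1, with a condition-specific
parameter pair: `(mu1_j, sigma1_j)` when `z_i = 1` and `(mu0_j, sigma0_j)`
when `z_i = 0`.  The label is correct iff the process is absorbed at +1, and
the reaction time is the absorption time.  For this symmetric geometry the
optional-stopping (Wald) identity gives closed forms:

* probability of a correct response: `p = S(2 mu / sigma^2)`, `S` the
  logistic function — this is the annotator's sensitivity (condition 1) or
  specificity (condition 0);
* expected decision time: `E[tau] = (2p − 1)/mu` for `mu ≠ 0`, with the
  Brownian limit `1/sigma^2` at `mu = 0`.

Two consequences shape everything downstream.  First, annotator
reliability is a *derived* quantity of two behavioural parameters, so label
matrices plus reaction times identify more than a confusion matrix would.
Second, the map `(mu, sigma) → (c·mu, √c·sigma)` leaves accuracy invariant
while scaling `E[tau]` by `1/c`: accuracy pins down only the ratio
`2 mu / sigma^2`, and reaction times resolve the remaining scale.

Hidden classes are linked to item features through a latent function value
`f_i` with `P(z_i = 0) = S(f_i)` (see *Conventions* below), estimated
per-item during inference and smoothed afterwards by a Gaussian-process
regressor over feature space.

## Inference

Mean-field variational inference keeps, per item, a posterior probability
`q_i` and a latent point value `f_i`, and per annotator the four point
estimates `(mu0, sigma0, mu1, sigma1)`.  The objective is

    sum_i ln[ S(f_i) · prod_j a_ij + (1 − S(f_i)) · prod_j b_ij ]
    + sum_i [ q_i ln S(f_i) + (1 − q_i) ln(1 − S(f_i)) ]
    − sum_i [ q_i ln q_i + (1 − q_i) ln(1 − q_i) ]
    + sum over bounded blocks of c(v),

where `a_ij` / `b_ij` are the probabilities of the observed label under
annotator *j*'s condition-0 / condition-1 process, and

    c(v) = −exp(beta (max v − 1)) − exp(−beta min v),   beta = 30,

is a soft containment penalty applied to `q` and the four annotator vectors
(negligible well inside (0, 1), dominant outside); `f` is unconstrained by
default (a flag adds it to the penalised set).  The stationary condition in
`q_i` is `q_i = S(f_i)`.

**Likelihood form.** The default data term is the mixture of *products* of
per-annotator label probabilities — the likelihood of conditionally
independent annotators.  A variant with the sum over annotators moved
inside the logarithm (`likelihood_form="printed"`) is retained for
comparison; its per-item gradients are damped by the number of annotators,
and under the reference schedule it stalls far short of the product form's
accuracy (measured: ~80% vs ~98% label accuracy at the stop rule), so it is
not the default.

**Optimisation.** Full-batch ascent from the prescribed all-0.5 start, step
size 0.01, stopping at the *later* of 300 iterations and the first ELBO
change below 0.1 (hard cap 5000).  The default update is Adam-style
moment-normalised ascent: normalisation caps every parameter's movement at
roughly one step size per iteration, which is what makes the product-form
objective optimisable from the overconfident 0.5 initialisation (the
implied annotator accuracy at the start is `S(4) ≈ 0.98`, so raw gradients
contain `1/probability` spikes of order 10²–10³ that plain gradient steps
turn into divergence — the penalty then overflows, which the engine reports
as a diagnostic naming the offending block).  Plain gradient ascent
(`optimizer="gd"`) is kept as an option and works with the printed form.
Gradients are analytic throughout and are verified against central finite
differences (relative 10⁻⁴) in the test suite.

**Reaction times.** Two integration routes, selected by `method`:

1. *Regularised ascent* — the objective gains
   `−lambda · Σ_{j,c} (E[tau](mu_c_j, sigma_c_j) − observed mean RT_{j,c})²`
   with `lambda = 1` by default.  Condition membership is latent, so the
   observed per-condition means are recomputed each iteration from the
   current `q` thresholded at 0.5 and treated as constants in the gradient.
2. *Post-hoc rescaling* — plain ascent first; then, per annotator and
   condition, `(mu, sigma) → (c·mu, √c·sigma)` with `c` = model-implied
   `E[tau]` / observed mean RT.  Sensitivities and specificities are
   unchanged to machine precision; observed mean RTs are matched exactly.
   A condition that received no items falls back to the annotator's overall
   mean RT.

Both routes are reconstructions from the Wald identity: the scale direction
`2 mu / sigma^2 = const` is unidentified by labels alone, and the mean RT is
the natural statistic that fixes it.

## Conventions

The mixture weight `S(f_i)` is paired with the condition-0 branch, i.e.
`S(f_i) = P(z_i = 0)`: items whose labels look like condition-0 responses
push `f_i` up.  Predicted labels threshold `q` at 0.5 with ties resolved to
class 0; the GP classifier then maps positive predicted latents to class 0.
A global `positive_branch` flag flips the pairing to `S(f) = P(z = 1)`
everywhere (inference, decision rules, reported `P(z = 1)` scores).  The
flip is exact at the likelihood and decision level; end-to-end trajectories
differ microscopically because the prescribed all-0.5 initialisation is not
symmetric under `f → −f`, so cross-convention agreement is asserted at the
98%+ level rather than bitwise.

## Gaussian-process classifier

A zero-mean GP *regressor* (RBF kernel times a free amplitude, plus a white
noise term) is fitted from item features to the inferred `f_i` by marginal
likelihood maximisation — length scale bounded to [0.001, 1000], white
noise variance to [0.001, 10], five seeded optimiser restarts.  A new point
gets `z* = 0` iff the predicted latent is ≥ 0 under the default convention
(the logistic of the latent is reported as `P(z = 1)`); the exact-zero tie
resolves to class 0 for determinism.  Training on latents rather than hard
labels preserves per-item confidence: an item the crowd barely resolved
contributes a near-zero latent rather than a full ±1 vote.  Duplicate-only
training inputs are rejected with a conditioning error.

## Synthetic data generator

The generator is the package's study world, not a fixture: items uniform on
[0, 2π] × [−1, 1]; ground truth `z = 0` iff `sin(x1) < x2` (a non-linear
boundary with exactly balanced classes); annotator pools drawn from uniform
supports — experiment 1: drifts U[0.1, 0.5] and diffusions U[0.5, 0.9] in
both conditions; experiment 2: U[0.1, 0.4] × U[0.5, 0.7] for condition 0
and U[0.2, 0.5] × U[0.5, 0.9] for condition 1; defaults of 200 items and
10 annotators.  Labels and RTs come from explicit Euler–Maruyama paths with
`dt = 0.01` s, terminated at the first grid time with `|X| ≥ 1` (no
overshoot correction) — deliberately the literal discrete rule, since it is
also the data-generating assumption of the inference.  Randomness uses one
root seed with per-annotator and per-item substreams, so growing the pool
or the item set never perturbs existing labels.

What the generator does *not* emulate: reaction-time contamination
(lapses, network delays), time-varying drift or diffusion (fatigue,
learning), annotator collaboration, and feature-dependent difficulty —
labels are conditionally independent of features given the class.  Passing
tests therefore certify the estimator under its own generative assumptions,
not robustness to real crowd data.

**First-passage numerics.** The plain Euler scheme absorbs late: missed
between-grid crossings bias the hit time upward by O(√dt) (about +2% on the
mean decision time at `dt = 10⁻³`), which is many Monte-Carlo standard
errors at 10⁵ paths.  For oracle-grade comparisons against the closed
forms, `first_passage_times(bridge=True)` samples interior crossings with
the Brownian-bridge probability `exp(−2(a − x_t)(a − x_{t+dt})/(sigma² dt))`,
removing the √dt bias; data generation keeps the plain scheme.

## Numerical choices

* `q` is clipped to [10⁻⁹, 1 − 10⁻⁹] inside logarithms and after updates;
  diffusion estimates are floored at 10⁻⁶.  All-zero or all-one label
  columns are legal inputs (the penalty keeps estimates interior).
* Penalty exponents are capped at 700 so extreme excursions produce a huge
  finite penalty instead of overflow.
* The product-form data term is evaluated in log space with `logaddexp`.
* Mixture totals in the printed form are floored at 10⁻³⁰⁰ inside `ln`.
* `E[tau]` switches to its `1/sigma²` limit for `|mu| < 10⁻¹⁰`.
* Ties: `q = 0.5` and `f* = 0` both resolve to class 0.
* CSV floats are written at 17 significant digits and parsed in
  round-trip mode, so dataset writes/reads are bit-exact.

## Problem sizes in tests and replication scripts

Replication checks and the acceptance script use ten replicate seeds per
experiment/method cell at the study's native size (200 items, 10
annotators, 10,000 test points); unit and property tests use reduced worlds
(40–150 items, 1–7 annotators) chosen to keep the full suite in a few
minutes while leaving every estimator code path exercised.  The Monte-Carlo
oracle grid uses 10⁵ paths per cell at `dt = 10⁻³`.

## Replication notes

Reference single-run values for this design sit inside a wide per-seed
distribution.  Across ten replicates of experiment 1, crowd-label accuracy
of the variational method averages ≈ 98 % and ranges roughly 93–100 %; a
log-odds decoder *given the true annotator parameters* — the Bayes optimum
for the conditional-independence model — shows nearly the same spread and
clears a 97.9 % floor on all three rates in fewer than 8 of 10 replicates
(the floor test computes this comparison and reports both counts).  A
single-run headline near the top of that range is therefore reproducible in
distribution but not as a per-seed guarantee, and the corresponding floor
check is expected to fail honestly under replication.  Parameter-recovery
MSEs and GP-classifier rates, by contrast, reproduce comfortably within
their stated tolerances.

## Known limitations

* Binary labels only; per-annotator parameters are constant over items and
  time.
* Point-estimate (non-Bayesian) treatment of annotator parameters and
  latents: no posterior uncertainty on `mu`, `sigma`, or `f`.
* The RT regulariser uses first moments only; full first-passage-time
  densities are out of scope.
* The GP is exact (O(n³)); crowdsourcing sets much beyond 10³–10⁴ items
  would need inducing-point approximations.
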