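# Methods

## The model

`stratddm` models a child's response on one addition-verification trial as
a race of strategy-specific evidence accumulators gated by a metacognitive
switching process.

Each trial begins, after a non-decision time `tau`, with a **retrieval**
accumulator: a Wiener diffusion with drift `delta - d` (retrieval
efficiency penalized linearly by the item difficulty `d`), threshold
separation `alpha`, relative start point `beta` toward the correct (upper)
boundary, and unit diffusion coefficient.  If retrieval has not resolved
by the switching time

    s = max(gamma + omega * d, 1 ms)

a strategy is selected probabilistically:

- continue retrieval with probability `p_r = logistic(mu - d)`; the
  running accumulator simply continues;
- otherwise restart a fresh accumulator at the switch point with the
  **counting** drift `kappa - lambda * d` (probability
  `(1 - p_r) * (1 - logistic(nu))`) or the **decomposition** drift
  `kappa - lambda * d - Delta` (probability `(1 - p_r) * logistic(nu)`);
  both reuse `alpha` and `beta` and add no extra non-decision time (the
  switch cost lives in `gamma`).

Any trial whose active accumulator has not hit a boundary by the deadline
`T_max` is censored (`response = none`).  Writing `f` and `S` for the
Wiener first-passage density and survival function, `u = rt - tau` and
`U = T_max - tau`, the likelihood of an answered trial is

    f_R(u, b)                                           for u <= s
    p_r f_R(u, b) + S_R(s) [p_c f_C(u - s, b) + p_d f_D(u - s, b)]   for u > s

with `b` the boundary implied by accuracy coding, and the censored-trial
mass is the analogous survival mixture.  The factor `S_R(s)` — the
probability that retrieval is still unresolved at the switch point — gates
the restarted branches; for the continue-retrieval branch it cancels
against the conditioning of the running accumulator.  With this form the
answered density plus censor mass integrates to 1, which the test suite
checks to 1e-5 across the reported parameter ranges.

Trial-level **responsibilities** are the posterior probabilities of each
strategy given the observed RT and accuracy (the likelihood components
normalized to sum to 1); selection-probability-based ("prior")
responsibilities are available as an option.  Derived per-person measures:
mean responsibility-entropy `Omega` (nats, pooled over all of a person's
trials; maximum ln 3), its population SD `Sigma`, adaptivity `psi` (the
Pearson correlation across trials between `delta - d` and the retrieval
responsibility; Spearman optional), and mean strategy-use proportions.
`Sigma` is pooled over sessions by default; per-session values are emitted
alongside for reliability analyses.

## Wiener first-passage numerics

Densities use the classical dual series (small-time image expansion /
large-time eigenfunction expansion), choosing per evaluation the
representation that needs fewer terms for truncation error below 1e-12;
the two representations agree to better than 1e-8 at the crossover.
Survival and CDF values integrate the large-time series analytically term
by term.  The upper-boundary absorption probability is the standard
closed form, continuous at zero drift.  An Euler–Maruyama path simulator
is kept as an independent brute-force oracle; when comparing it with the
analytic law at step `dt` the analytic reference is evaluated at
boundaries widened by 0.5826·sqrt(dt), the standard continuity correction
for the overshoot of a discrete Gaussian walk.  The exact trial sampler
inverts the survival function by bisection (1e-6 s tolerance) and draws
the boundary from the conditional density ratio.

## Hierarchy and priors

Individual parameters live on transformed scales: log for `alpha, kappa,
tau, delta, omega, gamma`, logit for `beta`, identity for `mu`.  The
hierarchy is `person ~ Normal(M, S)` and `session ~ Normal(person,
sess_sd)` per transformed parameter, with item difficulties `d_i ~
Normal(0, sigma_d)`.  Hyperpriors: `M ~ Normal(0, 2)`; `S`, `sess_sd`,
`sigma_d ~ half-Normal(1)`; `nu ~ Normal(0, 2)`; `lambda`, `Delta ~
half-Normal(2)` (drift-scale quantities, hence the wider scale).  Every
fit report prints the hyperpriors it used.

## Sampler

Gradient-free blocked Metropolis-within-Gibbs, robust to the likelihood
kink at `u = s`:

- one 8-dimensional random-walk block per person-session, proposals
  scaled by the *current* session scale (the block conditional is
  dominated by the tight session prior; using another state component to
  scale a symmetric proposal keeps the conditional kernel reversible);
- one joint shift block per person that moves the person mean and all its
  session values together, restoring likelihood-scale mixing that the
  centered hierarchy otherwise loses when the session scale is small;
  proposals use the warmup-estimated empirical covariance (adaptive
  Metropolis), and with probability 0.2 a Metropolized draw from the
  hierarchical prior for one coordinate or for the trade-off pairs/trio
  (`mu, omega, gamma`; `kappa–gamma`; `tau–gamma`) — for these the prior
  and proposal terms cancel, so acceptance is a pure likelihood ratio and
  the chain can cross the per-person bimodalities these trade-offs create;
- scalar Metropolis blocks per item and one 3-dimensional block for the
  group extras `(nu, log lambda, log Delta)`;
- conjugate Gibbs draws for person means and group locations; log-scale
  random walks for all scale parameters.

Step sizes follow Robbins–Monro adaptation toward acceptance 0.3 during
warmup only; covariance estimation also stops at the end of warmup, so
retained draws come from a fixed kernel.  Initialization is
domain-anchored and overdispersed: group locations start at the package's
default anchor plus chain-specific jitter, persons are drawn with the
anchor scale, and each block's non-decision time starts below its fastest
answered RT (up to 100 progressively lowered restarts; a non-finite
posterior after that raises).  With a single session per person the
session layer is dropped and persons are sampled directly.  Diagnostics
are split rank-normalized R-hat and bulk ESS (via ArviZ); constant series
are flagged as degenerate rather than crashing.

The longitudinal procedure fits the first timepoint fully, freezes item
difficulties at their posterior means (reported with a `fixed` flag), and
refits persons/sessions/group on the second timepoint, tabulating
per-person natural-scale changes with central 95% intervals.

## Synthetic-data generator

The generator is first-class code and defines the study conditions: ~105
children, 3 sessions, 60 trials per session, addition verification with
sums 3–14 (easy = sum <= 10), 5 s response deadline.  Group locations and
scales are the reported individual-level means/SDs (alpha 3.91/0.70,
kappa 3.06/0.43, tau 0.66/0.32, delta 1.49/0.44, beta 0.54/0.03,
mu −0.83/1.29, omega 0.51/0.29, gamma 0.81/0.37) mapped onto the
transformed scales by moment matching (log-normal) and the delta method
(logit); the session scale defaults to 10% of the between-person scale,
which produces the high between-session reliability of the metacognitive
parameters relative to behavioural summaries.  A log-normal population
distribution is used for `omega` (rather than a half-normal) so the
generator and the inference model share one scale family; the reported
strictly positive interval for `omega` is compatible with either.

Free generator constants were fixed once against the reported qualitative
strategy-split pattern (slower and less accurate decomposition, larger
easy/hard RT gap for counting) and not revisited: `nu =
logit(0.07/0.67) ≈ −2.15` from the average decomposition share among
non-retrieval use, `lambda = 0.5`, `Delta = 2.5`, `sigma_d = 0.8` with
item difficulty rank-correlated with problem size (weight 0.82, matching
the reported difficulty–problem-size association).  Item difficulties are
shared across persons and exactly centered.

What the generator does **not** emulate: practice/sequence effects within
a session, RT autocorrelation, across-trial drift or start-point
variability, omissions other than deadline censoring, and response
biases beyond the start point.  Passing tests therefore demonstrate
internal consistency and recoverability under the model's own
assumptions, not robustness to these real-data features.  One known
divergence: with the reported parameter means and the post-`tau` switch
convention, about half of simulated trials resolve or continue as
retrieval, which is higher than the reported average retrieval share
(0.32); the strategy-split orderings, reliability pattern and
crossing/cutoff concordance are insensitive to this.

## Problem sizes and numerical choices in the test suite

Desk-scale sizes keep the full suite within a commodity-CPU budget while
preserving each property's power: the path oracle uses 30k paths at
`dt = 2e-4` (with the boundary correction above); simulator/likelihood
agreement uses 1e5 trials; parameter recovery uses 5 replicate cohorts of
20 persons × 3 sessions × 60 trials with 2 chains × 1500 retained draws
(warmup 1000); simulation-based calibration uses 200 replicates of a
60-trial single-person model with 2000 draws thinned by 10; the
reliability and crossing/cutoff studies use 50 replicate cohorts; the
longitudinal checks use 8 persons × 2 sessions × 50 trials.  Switch times
are clamped at 1 ms; entropies use natural logarithms; responsibilities
normalize component masses with 0·ln 0 = 0; trials with `rt <= tau` score
−inf (flagged, never raised) during fitting; ICC degeneracy (zero total
variance) yields NaN flags rather than errors.

## Known limitations

- The sampler's R-hat on hierarchical fits of the standard recovery
  design can exceed 1.05 for a minority of person-level parameters at the
  budgeted draw counts; posterior means (the quantity the recovery
  criteria use) are stable well before full mixing of those coordinates.
- `beta` and `tau` person-level recovery is reported without a hard
  threshold: the reported between-person spread of `beta` is small
  relative to its posterior width at 180 trials per person.
- Decomposition-specific individual parameters are not modelled (group
  share `nu` and drift decrement `Delta` only), consistent with the small
  average decomposition share.
- No across-trial variability parameters or collapsing bounds; no
  variational or gradient-based backends.
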