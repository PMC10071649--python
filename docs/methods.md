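# Methods

## Model and data structure

`ltcox` fits the Cox proportional-hazards model

Λ(t | Z) = Λ(t) · exp(Z'β)

to failure times that are **left-truncated** — a subject with underlying
failure time T\* and entry time A\* is observed only when T\* ≥ A\* — and
censored in any mixture of the common patterns.  Each observed subject
carries an entry time A, a covariate vector Z, and either an exact event
time T (δ = 1) or a bracketing interval (L, R] with A ≤ L < R ≤ ∞
(δ = 0).  Left censoring is L = A, right censoring R = ∞, so right-,
interval- and partly interval-censored samples are all special cases of
one record layout.

Two likelihood components are combined:

* the **conditional likelihood** of the event/censoring data given
  (A, Z), which conditions the truncation away — survival factors are
  ratios S(·|Z)/S(A|Z) — but discards the information the entry times
  carry about the survival law; and
* the **pairwise pseudo-likelihood** of the entry times.  For each
  ordered pair (i, j) the probability that the two observed entry times
  are assigned as observed rather than swapped is 1/(1 + R_ij) with

  R_ij = exp[{Λ(A_i) − Λ(A_j)}{exp(Z_i'β) − exp(Z_j'β)}].

  The unknown entry-time density cancels from this contrast, so the
  pairwise term recovers entry-time information without ever estimating
  the truncation law.  R_ij is symmetric in (i, j): both factors of the
  exponent change sign under a swap, so the ordered-pair sum simply
  counts each unordered pair twice.

Λ is treated nonparametrically as a right-continuous step function with
nonnegative jumps λ_k.

### Jump support

The likelihood evaluates Λ at exact event times, finite interval
endpoints and entry times.  The fitter places **jumps only at event
times and finite interval endpoints**; entry times serve as evaluation
points of Λ (all the pairwise factor needs) and at-risk window edges.
Granting entry times their own jumps lets the optimizer concentrate a
censored subject's interval mass at an entry time where almost nobody
is at risk — the estimated baseline then inflates near the left edge of
the entry distribution (this is the known boundary misbehaviour of the
truncated interval-censoring NPMLE).  With the restricted support the
baseline bias in the simulation designs below is at the Monte-Carlo
noise level.  `build_time_grid(..., include_entry=True)` (the default)
still returns the full evaluation grid for likelihood utilities.

## EM algorithm

Latent Poisson counts W_ik with means λ_k·exp(Z_i'β) are attached to
every grid point in the subject's window [A_i, R*_i], where R\*_i is T_i
(exact), R_i (interval/left censored) or L_i (right censored).  The
censoring pattern becomes a set of constraints (all counts zero up to
L_i; positive total on (L_i, R_i]; a single unit count at an exact event
time), under which the E-step means are available in closed form; a
positive-total window has mean λ_k·e^{Z'β} / (1 − e^{−μ}) per point,
with μ the window mass.  Each iteration performs:

1. **E-step** at the current θ;
2. **λ update**, closed-form per grid point: expected counts divided by
   the at-risk mass plus (pairwise variant only) an entry-time contrast
   term, all evaluated at the current θ — a self-consistency update that
   solves the λ_k score equation exactly;
3. **one Newton step** on the β score at the fresh λ (Gauss–Seidel
   ordering), with an analytic Jacobian; a central-finite-difference
   Jacobian is kept as a cross-check and the two agree to 1e−6 in the
   test suite.  If the Jacobian is singular or has condition number
   above 1e12 a damped gradient step (factor 0.1) is taken with a
   warning.

Iteration stops when the summed absolute parameter change over (β, λ)
falls below `tol` (default 0.001).  Initial values are β = 0 and
λ_k = 1/K.  A single iteration's λ update can turn negative through the
pairwise contrast term; negative updates are clamped to
`lam_floor = 1e−10` and counted (zero activations in all simulation
designs here).  A jump whose numerator is exactly zero is set to zero.
Window masses below 1e−300 fall back to the μ→0 limit λ_k/Σλ_k so the
M-step stays defined.

Three estimator variants share the loop: `pairwise` (the full composite
likelihood), `conditional` (pairwise terms dropped), and
`ignore_truncation` (entry times zeroed before fitting, then identical
to `conditional`) — the last exists as the biased baseline comparator.

### Convergence behaviour

The NPMLE genuinely diverges (logarithmically) at grid points where a
single censored subject is at risk alone on part of its interval —
typically isolated late endpoints; the stopping rule then terminates on
the slow tail of those jumps.  They receive large λ̂ but lie beyond
other subjects' windows, so β̂ and Λ̂ on the reported range are
unaffected.  Under the 0.001 rule the median iteration count at n = 100
is ≈ 1 200; the package default `max_iter = 1000` reports
`converged=False` honestly, and the studies below run with
`max_iter = 3000`, which converges essentially all fits up to n = 500.

## Inference

Standard errors come from the **nonparametric bootstrap**: subjects are
resampled with replacement, the grid rebuilt, and the model refitted per
resample; the SE is the sample SD over converged resamples (failures are
dropped and counted).  Refits are warm-started from the full-data
estimates — β̂ directly, Λ̂ re-expressed as jumps on the resample grid —
which changes nothing statistically (the EM fixed point is the same) and
roughly quarters the per-resample cost.  Confidence intervals for β are
Wald-normal; intervals for Λ(t) use the log transform
Λ̂·exp{±z·σ̂/Λ̂}, keeping endpoints positive.  Wald z = est/SE with a
two-sided normal p-value covers single-covariate testing.

## Synthetic data

The generator reproduces three study designs used to validate the
method; their parameters are the study conditions, not knobs:

* failure times from Λ(t) = t² (Weibull shape 2, scale 1) with
  β = (1, 1), Z₁ ~ Bernoulli(0.5), Z₂ ~ Uniform(−0.5, 0.5)
  (Uniform(−1, 1) in the right-censored design);
* entry times Uniform(0, τ\*) — the length-biased case — or exponential
  with rate θ\*, with τ\*/θ\* calibrated by Monte-Carlo bisection
  (100 000 draws, tolerance 0.005, fixed internal seed, cached) so that
  P(T\* < A\*) ≈ 50%; subjects are kept only when T\* ≥ A\*;
* **partly interval / interval designs**: examinations start at the
  entry time with gaps 0.05 + Uniform(0, 0.5) and stop at calendar time
  1.5 (an absolute bound — the per-subject A+1.5 reading pushes the
  right-censoring rate below the range the designs are meant to
  produce); the bracketing exam pair gives (L, R], the first interval
  yields left censoring, times beyond the last exam right censoring;
  in the partly-interval design a bracket shorter than 0.2 is recorded
  as an exact observation;
* **right-censored design**: censoring at A + C with C ~ Uniform(0,
  C_max), C_max calibrated to a 30% censoring rate among retained
  subjects.  Measuring C from the origin instead is a config switch
  (`censor_from_entry=False`).

What the generator does **not** emulate: covariate-dependent truncation
or examination schedules, informative censoring, ties in continuous
times, covariate measurement error.  Passing tests therefore certify
the estimator under independent truncation/censoring with smooth
continuous data — not robustness to violations of those assumptions.

## Numerical choices

* Pairwise exponents are computed in log space; `pairwise_ratio` clamps
  the exponent at ±700 before exponentiation, and log(1+R) uses
  `logaddexp`; the EM's pair weights use the logistic sigmoid, which
  saturates safely.
* Subject endpoints are snapped to grid indices once; all indicator
  tests are integer comparisons, so float-equality issues cannot arise.
* A grid point equal to both an entry and an event time is a single
  shared point.
* Zero-probability censored intervals make the conditional
  log-likelihood −∞ with a warning (flag, not an exception).

## Reduced problem sizes

The packaged acceptance studies run the published designs at reduced
replicate counts (60–100 replicates at n = 100–300, 20 at n = 500,
bootstrap B = 25 for coverage) chosen as a desk-scale compromise; all
tolerances are three Monte-Carlo standard errors computed from the
replicates themselves, so they widen automatically with fewer
replicates and contain no hand-tuned slack.

## Known limitations

* No asymptotic (profile-likelihood) variance estimator — bootstrap
  only, which is expensive for very large n.
* The boundary divergence described above means individual λ̂_k at
  sparse-risk late grid points are not interpretable; use Λ̂ over the
  data-supported range.
* The β-bias of the truncation-ignoring variant is design-dependent;
  it is included for comparison, not for analysis.
* Single-covariate Wald tests only; no multiple-testing machinery.
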