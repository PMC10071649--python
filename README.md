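# ltcox

Cox proportional-hazards regression for **left-truncated** failure-time
data under right, interval, left or mixed ("partly interval") censoring,
estimated by a **pairwise pseudo-likelihood NPMLE** fitted with a
Poisson-augmented EM algorithm.

## Who this is for

Epidemiologists and biostatisticians analysing cohorts recruited
cross-sectionally — e.g. disease registries where subjects enter only if
the event has not yet happened by enrolment, and the event time is then
ascertained at scheduled follow-ups.  Such sampling left-truncates the
event time (long survivors are over-represented) and periodic
examination interval-censors it.  Ignoring the truncation biases the
hazard-ratio estimates; conditioning it away (the classical conditional
likelihood) is valid but wastes the information the entry times carry.

## The estimator

With Λ(t | Z) = Λ(t)·e^{Z'β} and a step-function baseline Λ with jumps
λ_k, the package maximises a composite objective combining

* the conditional likelihood of the censoring data given entry times:
  survival ratios S(t|Z)/S(A|Z); and
* the pairwise pseudo-likelihood of the entry times,
  ∏_{i≠j} {1 + R_ij}⁻¹ with
  R_ij = exp[{Λ(A_i) − Λ(A_j)}{e^{Z_i'β} − e^{Z_j'β}}],
  which contrasts entry-time pairs and cancels the unknown truncation
  density.

The EM algorithm augments the data with Poisson latent counts so the
E-step is closed-form, updates every λ_k by an explicit
self-consistency formula, and takes one Newton step per iteration for
β.  Standard errors come from the nonparametric bootstrap.  Estimator
variants `conditional` (no pairwise term) and `ignore_truncation`
(entry times zeroed) are included for comparison.

## Worked example

```python
import ltcox

design = ltcox.calibrated_design("partly_interval", "uniform")
data = ltcox.simulate_dataset(design, n=100, seed=7)

model = ltcox.LeftTruncatedCoxPH(data)
res = model.fit(method="pairwise", max_iter=3000)
res.bootstrap(B=100, eval_times=(0.8,), seed=1)
print(res.summary())
```

prints

```
Left-truncated Cox proportional hazards (NPMLE, EM)
method: pairwise    n: 100    grid size: 174
converged: True    iterations: 646
bootstrap resamples: 100 (0 failed)
      coef  boot se       z   P>|z|  [0.025  0.975]
Z1  0.9621   0.2346  4.1009  0.0000  0.5023  1.4219
Z2  0.8958   0.3836  2.3351  0.0195  0.1439  1.6476
```

The data were generated with true β = (1, 1): both log-hazard ratios
are recovered well within one bootstrap standard error and the Wald
tests reject zero effect.  `res.cumulative_hazard(0.8)` gives 0.993 for
this draw — the baseline cumulative hazard at t = 0.8, whose true value
under this design is 0.8² = 0.64 with a sampling SD around 0.18 at
n = 100 — and `res.cumhaz_conf_int(0.8)` returns its log-transformed
95% interval, here (0.58, 1.70).

The same workflow is scriptable:

```bash
ltcox simulate --design pic --trunc unif --n 100 --seed 7 --out data.csv
ltcox fit --data data.csv --method pairwise --bootstrap 100 \
      --eval-times 0.8 --max-iter 3000 --seed 1 --out results/
ltcox simstudy --design pic --trunc unif --n 100 --reps 50 \
      --methods pairwise,conditional --max-iter 3000 --seed 1 --out study/
```

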