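"""Bootstrap standard errors, confidence intervals and the Monte-Carlo
simulation-study harness.

All uncertainty quantification is by the nonparametric bootstrap:
subjects are resampled with replacement, the model refitted per resample
(baseline-hazard grid rebuilt each time), and standard errors taken as
sample standard deviations over converged resamples.  Confidence
intervals for the cumulative hazard use a log transform so the endpoints
stay positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import Dataset, build_time_grid
from .em import FitOptions, fit
from .exceptions import ConvergenceWarning, InvalidInputError
from .likelihood import cumulative_hazard
from .simulate import SimulationDesign, simulate_dataset

__all__ = [
    "BootstrapResult",
    "SimStudySummary",
    "bootstrap_se",
    "lambda_ci",
    "wald_test",
    "simulation_study",
]


@dataclass
class BootstrapResult:
    """Bootstrap standard errors for β and for Λ̂(t) at requested times."""

    se_beta: np.ndarray
    se_lambda_at: dict
    B: int
    n_failed: int


@dataclass
class SimStudySummary:
    """Replicated-simulation summary: Bias, SSE, SEE and 95% CP per
    parameter and method, plus per-replicate estimates for downstream
    analysis."""

    table: pd.DataFrame
    estimates: dict  # method -> DataFrame (one row per converged replicate)
    design: SimulationDesign
    n: int
    reps: int
    B: int
    n_excluded: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def bootstrap_se(
    dataset: Dataset,
    options: FitOptions,
    B: int,
    eval_times=(),
    seed: int = 0,
    warm_start=None,
) -> BootstrapResult:
    """Nonparametric bootstrap SEs for β̂ and Λ̂(t) at ``eval_times``.

    Resamples subjects with replacement ``B`` times, rebuilding the
    baseline grid per resample; each refit is warm-started from the
    full-data estimates (``warm_start``, computed here if not supplied).
    Non-converged resamples are dropped (and counted) with a warning.
    Deterministic given ``seed``.
    """
    if B < 2:
        raise InvalidInputError("need at least B=2 bootstrap resamples")
    rng = np.random.default_rng(seed)
    n = dataset.n
    eval_times = list(eval_times)
    if warm_start is None:
        warm_start = fit(dataset, FitOptions(
            method=options.method, tol=options.tol, max_iter=options.max_iter,
            lam_floor=options.lam_floor, track_objective=False,
        ))
    warm_params = warm_start.params
    betas, lams = [], []
    n_failed = 0
    for _ in range(B):
        ds = dataset.subset(rng.integers(0, n, size=n))
        # warm start: the resample's grid differs, so re-express the
        # full-data step function Λ̂ as jumps on the new grid
        base = ds.with_zero_entry() if options.method == "ignore_truncation" else ds
        new_grid = build_time_grid(base, include_entry=False)
        ch = np.asarray(cumulative_hazard(warm_params, new_grid.points))
        init_lam = np.maximum(np.diff(np.concatenate([[0.0], ch])), 1e-8)
        opts = FitOptions(
            method=options.method, tol=options.tol, max_iter=options.max_iter,
            init_beta=warm_start.beta_hat, init_lam=init_lam,
            lam_floor=options.lam_floor, track_objective=False,
        )
        res = fit(ds, opts)
        if not res.converged:
            n_failed += 1
            continue
        betas.append(res.beta_hat)
        if eval_times:
            lams.append(np.asarray(cumulative_hazard(res.params,
                                                     np.asarray(eval_times))))
    if not betas:
        raise InvalidInputError("all bootstrap resamples failed to converge")
    if n_failed:
        warnings.warn(
            f"{n_failed}/{B} bootstrap resamples did not converge and were "
            "excluded", ConvergenceWarning,
        )
    if len(betas) < 2:
        raise InvalidInputError("fewer than 2 converged bootstrap resamples")
    betas = np.asarray(betas)
    se_beta = betas.std(axis=0, ddof=1)
    se_lam = {}
    if eval_times:
        lams = np.asarray(lams)
        sds = lams.std(axis=0, ddof=1)
        se_lam = {t: float(s) for t, s in zip(eval_times, sds)}
    return BootstrapResult(se_beta=se_beta, se_lambda_at=se_lam, B=B,
                           n_failed=n_failed)


def lambda_ci(lam_hat_t: float, sigma_hat_t: float, level: float = 0.95):
    """Log-transformed confidence interval for the cumulative hazard:
    Λ̂ exp{∓ z σ̂/Λ̂}.  Degenerate [0, 0] (with a warning) when Λ̂ = 0."""
    if not 0 < level < 1:
        raise InvalidInputError("level must be in (0,1)")
    if lam_hat_t < 0 or sigma_hat_t < 0:
        raise InvalidInputError("estimates and SEs must be nonnegative")
    if lam_hat_t == 0:
        warnings.warn("cumulative hazard estimate is 0; degenerate interval",
                      ConvergenceWarning)
        return (0.0, 0.0)
    z = stats.norm.ppf(1 - (1 - level) / 2)
    half = z * sigma_hat_t / lam_hat_t
    return (lam_hat_t * np.exp(-half), lam_hat_t * np.exp(half))


def wald_test(est: float, se: float):
    """Normal-approximation z statistic and two-sided p-value."""
    if se <= 0:
        raise InvalidInputError("se must be positive")
    z = est / se
    return z, float(2 * stats.norm.sf(abs(z)))


def _true_cumhaz(t: float) -> float:
    return t * t


def simulation_study(
    design: SimulationDesign,
    n: int,
    reps: int,
    B: int = 0,
    eval_times=(0.4, 0.8, 1.2),
    seed: int = 0,
    methods=("pairwise",),
    max_iter: int = 1000,
) -> SimStudySummary:
    """Replicate the design ``reps`` times and summarise estimator
    performance (Bias, SSE, and with ``B > 0`` also SEE and 95% CP).

    The replicate seed stream is split from ``seed`` so results are
    reproducible and replicates independent.  Replicates that fail to
    converge are excluded (an error is raised if more than 10% are).
    """
    if reps < 2:
        raise InvalidInputError("need reps >= 2")
    eval_times = list(eval_times)
    truth = {"beta1": design.beta_true[0], "beta2": design.beta_true[1]}
    for t in eval_times:
        truth[f"Lam({t})"] = _true_cumhaz(t)

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(reps)
    est = {m: [] for m in methods}
    ses = {m: [] for m in methods}
    excluded = {m: 0 for m in methods}
    for rep, child in enumerate(children):
        st = child.generate_state(2)
        data_seed = int(st[0] % (2**31))
        boot_seed = int(st[1] % (2**31))
        ds = simulate_dataset(design, n, data_seed)
        for m in methods:
            opts = FitOptions(method=m, max_iter=max_iter, track_objective=False)
            res = fit(ds, opts)
            if not res.converged:
                excluded[m] += 1
                continue
            row = {"beta1": res.beta_hat[0]}
            if res.beta_hat.size > 1:
                row["beta2"] = res.beta_hat[1]
            for t in eval_times:
                row[f"Lam({t})"] = float(cumulative_hazard(res.params, t))
            est[m].append(row)
            if B > 0:
                bs = bootstrap_se(ds, opts, B, eval_times, seed=boot_seed,
                                  warm_start=res)
                serow = {"beta1": bs.se_beta[0]}
                if bs.se_beta.size > 1:
                    serow["beta2"] = bs.se_beta[1]
                for t in eval_times:
                    serow[f"Lam({t})"] = bs.se_lambda_at[t]
                ses[m].append(serow)

    for m in methods:
        if excluded[m] > 0.1 * reps:
            raise InvalidInputError(
                f"method {m}: {excluded[m]}/{reps} replicates failed to converge"
            )

    rows = []
    estimates = {}
    for m in methods:
        em = pd.DataFrame(est[m])
        estimates[m] = em
        sm = pd.DataFrame(ses[m]) if ses[m] else None
        for par in em.columns:
            tv = truth[par]
            vals = em[par].to_numpy()
            bias = float(vals.mean() - tv)
            sse = float(vals.std(ddof=1))
            see = cp = np.nan
            if sm is not None:
                svals = sm[par].to_numpy()
                see = float(svals.mean())
                if par.startswith("beta"):
                    z = stats.norm.ppf(0.975)
                    cover = np.abs(vals - tv) <= z * svals
                else:
                    cover = np.array([
                        lo <= tv <= hi
                        for lo, hi in (lambda_ci(v, s) for v, s in zip(vals, svals))
                    ])
                cp = float(100.0 * cover.mean())
            rows.append({
                "design": f"{design.censoring_scheme}/{design.truncation}",
                "method": m, "n": n, "parameter": par, "truth": tv,
                "bias": bias, "sse": sse, "see": see, "cp": cp,
            })
    return SimStudySummary(
        table=pd.DataFrame(rows), estimates=estimates, design=design,
        n=n, reps=reps, B=B, n_excluded=excluded,
    )
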