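"""Likelihood components of the left-truncated Cox model.

The baseline cumulative hazard is a step function Λ(t) = Σ_{t_k <= t} λ_k
on a :class:`~ltcox.data.TimeGrid`.  Two observed-data components are
evaluated:

* the conditional log-likelihood of the event/censoring data given entry
  times and covariates (truncation-adjusted survival ratios), and
* the pairwise pseudo-log-likelihood of the entry times, which contrasts
  pairs of subjects and thereby eliminates the unknown entry-time density
  while retaining its information about (β, λ).

All boundary conventions are inclusive on the entry side: hazard sums run
over A_i <= t_k <= (T_i, L_i or R_i), and interval mass over L_i < t_k <= R_i.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import Dataset, SubjectRecord, TimeGrid
from .exceptions import DegenerateDataWarning, InvalidInputError

__all__ = [
    "ParameterState",
    "PairStat",
    "cumulative_hazard",
    "conditional_loglik",
    "pairwise_ratio",
    "pairwise_loglik",
    "composite_objective",
]

#: clamp for pairwise log-ratio exponents before exponentiation
EXP_CLAMP = 700.0


@dataclass
class ParameterState:
    """Model parameters θ = (β, λ_1..λ_K) tied to a :class:`TimeGrid`."""

    beta: np.ndarray
    lam: np.ndarray
    grid: TimeGrid

    def __post_init__(self):
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        self.lam = np.atleast_1d(np.asarray(self.lam, dtype=float))
        if self.lam.size != self.grid.K:
            raise InvalidInputError("lam length must match grid size")
        if np.any(self.lam < 0):
            raise InvalidInputError("baseline jumps must be nonnegative")

    @property
    def p(self) -> int:
        return self.beta.size

    def copy(self) -> "ParameterState":
        return ParameterState(self.beta.copy(), self.lam.copy(), self.grid)


@dataclass(frozen=True)
class PairStat:
    """Pairwise contrast statistics for one ordered pair (i, j): the ratio
    R_ij and the per-grid-point contrasts Q^(0), Q^(1).

    All three are symmetric under swapping i and j — both factors of each
    product change sign."""

    ratio: float
    q0: np.ndarray  # (K,)
    q1: np.ndarray  # (K, p)


def cumulative_hazard(params: ParameterState, t) -> np.ndarray | float:
    """Λ(t) = Σ_{t_k <= t} λ_k — right-continuous, nondecreasing, 0 below
    the first grid point.  Vectorised in ``t``."""
    idx = params.grid.index_leq(t)
    csum = np.concatenate([[0.0], np.cumsum(params.lam)])
    out = csum[idx]
    return float(out) if np.isscalar(t) else out


def conditional_loglik(
    params: ParameterState, dataset: Dataset, grid: TimeGrid | None = None
) -> float:
    """Log of the truncation-conditional likelihood under the step-function
    baseline hazard.

    Exact events contribute ``log λ_{k(T_i)} + Z_i'β − Σ_{A_i<=t_k<=T_i} λ_k e^{Z_i'β}``;
    censored subjects the log of the probability mass on their interval.
    A censored subject with zero interval mass (or an exact event at a
    zero jump) yields −inf with a :class:`DegenerateDataWarning` rather
    than an exception.
    """
    if grid is None:
        grid = params.grid
    csum = np.concatenate([[0.0], np.cumsum(params.lam)])
    Z = dataset.covariates()
    eta = Z @ params.beta
    g = np.exp(eta)
    A = dataset.entry_times()
    lo = np.searchsorted(grid.points, A, side="left")  # first k with t_k >= A_i
    delta = np.array([rec.delta for rec in dataset.records])

    total = 0.0
    exact = np.flatnonzero(delta == 1)
    if exact.size:
        T = np.array([dataset.records[i].T for i in exact])
        k_exact = np.array([grid.exact_index(t) for t in T])
        lam_T = params.lam[k_exact]
        if np.any(lam_T <= 0):
            warnings.warn("zero jump at an exact event time", DegenerateDataWarning)
            return -np.inf
        hsum = csum[grid.index_leq(T)] - csum[lo[exact]]
        total += float(np.sum(np.log(lam_T) + eta[exact] - hsum * g[exact]))

    cens = np.flatnonzero(delta == 0)
    if cens.size:
        L = np.array([dataset.records[i].L for i in cens])
        R = np.array([dataset.records[i].R for i in cens])
        hL = (csum[grid.index_leq(L)] - csum[lo[cens]]) * g[cens]
        total += float(-hL.sum())
        fin = np.isfinite(R)
        if fin.any():
            hR = (csum[grid.index_leq(R[fin])] - csum[lo[cens][fin]]) * g[cens][fin]
            dm = hR - hL[fin]  # interval mass exponent, must be > 0
            if np.any(dm <= 0):
                warnings.warn(
                    "zero probability mass on a censoring interval",
                    DegenerateDataWarning,
                )
                return -np.inf
            total += float(np.sum(np.log(-np.expm1(-dm))))
    return total


def _log_ratio(params: ParameterState, rec_i: SubjectRecord, rec_j: SubjectRecord) -> float:
    """log R_ij = {Λ(A_i) − Λ(A_j)} {e^{Z_i'β} − e^{Z_j'β}} (grid-summed)."""
    Lam_i = cumulative_hazard(params, rec_i.A)
    Lam_j = cumulative_hazard(params, rec_j.A)
    gi = np.exp(float(np.dot(rec_i.Z, params.beta)))
    gj = np.exp(float(np.dot(rec_j.Z, params.beta)))
    return (Lam_i - Lam_j) * (gi - gj)


def pairwise_ratio(
    params: ParameterState,
    rec_i: SubjectRecord,
    rec_j: SubjectRecord,
    grid: TimeGrid | None = None,
) -> float:
    """Survival-odds ratio R_ij of the entry-time pair (A_i, A_j):
    the odds of the swapped assignment of the two entry times against the
    observed one, exp[{Λ(A_i) − Λ(A_j)}{e^{Z_i'β} − e^{Z_j'β}}].

    Computed on the log scale; the exponent is clamped at ±``EXP_CLAMP``
    so the result is always finite and positive.  Symmetric: R_ji = R_ij
    (both exponent factors change sign when i and j swap).
    """
    x = _log_ratio(params, rec_i, rec_j)
    return float(np.exp(np.clip(x, -EXP_CLAMP, EXP_CLAMP)))


def pair_stat(
    params: ParameterState, rec_i: SubjectRecord, rec_j: SubjectRecord
) -> PairStat:
    """Full pairwise contrast statistics for one ordered pair."""
    grid = params.grid
    ci = (grid.points <= rec_i.A).astype(float)
    cj = (grid.points <= rec_j.A).astype(float)
    gi = np.exp(float(np.dot(rec_i.Z, params.beta)))
    gj = np.exp(float(np.dot(rec_j.Z, params.beta)))
    dind = ci - cj
    q0 = (gi - gj) * dind
    zi = np.asarray(rec_i.Z, dtype=float)
    zj = np.asarray(rec_j.Z, dtype=float)
    q1 = np.outer(dind, zi * gi - zj * gj)
    return PairStat(pairwise_ratio(params, rec_i, rec_j), q0, q1)


def _pairwise_logratio_matrix(params: ParameterState, dataset: Dataset) -> np.ndarray:
    """n x n matrix of log R_ij (zero diagonal)."""
    Z = dataset.covariates()
    g = np.exp(Z @ params.beta)
    LamA = np.asarray(cumulative_hazard(params, dataset.entry_times()))
    X = (LamA[:, None] - LamA[None, :]) * (g[:, None] - g[None, :])
    return np.clip(X, -EXP_CLAMP, EXP_CLAMP)


def pairwise_loglik(
    params: ParameterState, dataset: Dataset, grid: TimeGrid | None = None
) -> float:
    """Pairwise pseudo-log-likelihood −Σ_{i≠j} log(1 + R_ij) over ordered
    pairs.  Returns 0 with a warning when n == 1."""
    n = dataset.n
    if n < 2:
        warnings.warn("pairwise likelihood undefined for n=1; returning 0",
                      DegenerateDataWarning)
        return 0.0
    X = _pairwise_logratio_matrix(params, dataset)
    # log(1 + e^x), stable for large |x|
    term = np.logaddexp(0.0, X)
    np.fill_diagonal(term, 0.0)
    return float(-term.sum())


def composite_objective(
    params: ParameterState, dataset: Dataset, grid: TimeGrid | None = None
) -> float:
    """Monitoring objective: conditional part weighted 1/n plus pairwise
    part weighted 1/(n(n−1)) (0 when n == 1)."""
    n = dataset.n
    cond = conditional_loglik(params, dataset, grid)
    if n == 1:
        return cond
    return cond / n + pairwise_loglik(params, dataset, grid) / (n * (n - 1))
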