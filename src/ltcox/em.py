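"""EM algorithm with Poisson data augmentation.

Independent latent Poisson counts W_ik with means λ_k exp(Z_i'β) are
attached to every grid point t_k in the subject's active window
[A_i, R*_i], where R*_i is the exact event time (δ=1), the finite right
endpoint (interval/left censoring) or the last-exam time (right
censoring).  Conditioning on the censoring pattern turns the E-step into
closed-form truncated-Poisson means, and the M-step gives each baseline
jump λ_k in closed form (a self-consistency equation); the regression
coefficients take a single Newton step on the composite score per EM
iteration.

Three estimator variants share the loop:

``pairwise``
    conditional likelihood + pairwise pseudo-likelihood of entry times
    (the efficient estimator);
``conditional``
    conditional likelihood only (pairwise terms dropped);
``ignore_truncation``
    conditional fit after forcing every entry time to 0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .data import Dataset, TimeGrid, build_time_grid
from .exceptions import (
    ConvergenceWarning,
    InvalidInputError,
    NumericalError,
)
from .likelihood import ParameterState, composite_objective

__all__ = [
    "ExpectationSet",
    "FitOptions",
    "FitResult",
    "estep_expectations",
    "update_lambda",
    "score_beta",
    "score_lambda",
    "beta_jacobian",
    "fd_beta_jacobian",
    "newton_step_beta",
    "fit",
    "METHODS",
]

METHODS = ("pairwise", "conditional", "ignore_truncation")

log = logging.getLogger(__name__)

#: below this window mass the truncated-Poisson mean is replaced by its
#: μ→0 limit λ_k / Σλ_k to keep the M-step defined
_MU_UNDERFLOW = 1e-300


@dataclass
class ExpectationSet:
    """E-step output: conditional means e_ik = E(W_ik | data, θ) on each
    subject's active window (zero outside)."""

    values: np.ndarray  # (n, K)
    window: np.ndarray  # (n, K) float 0/1 mask I(A_i <= t_k <= R*_i)


@dataclass
class FitOptions:
    """Fitting controls.

    ``tol`` is the threshold on the sum of absolute parameter changes
    between successive iterations (default 0.001); each λ_k starts at
    1/K and β at 0 unless overridden.
    """

    method: str = "pairwise"
    tol: float = 1e-3
    max_iter: int = 1000
    init_beta: np.ndarray | None = None
    init_lam: np.ndarray | None = None
    lam_floor: float = 1e-10
    seed: int | None = None
    track_objective: bool = True

    def __post_init__(self):
        if self.method not in METHODS:
            raise InvalidInputError(f"unknown method {self.method!r}")
        if not self.tol > 0:
            raise InvalidInputError("tol must be positive")
        if self.max_iter < 1:
            raise InvalidInputError("max_iter must be >= 1")


@dataclass
class FitResult:
    """Converged (or capped) EM estimates and diagnostics."""

    beta_hat: np.ndarray
    lam_hat: np.ndarray
    grid: TimeGrid
    converged: bool
    n_iter: int
    objective_trace: list
    method: str
    warnings: list = field(default_factory=list)
    n_floored: int = 0

    @property
    def params(self) -> ParameterState:
        return ParameterState(self.beta_hat, self.lam_hat, self.grid)


# ---------------------------------------------------------------------------
# Precomputed index structure shared by all E/M computations on one dataset
# ---------------------------------------------------------------------------


class _Indexed:
    """Grid-index representation of a dataset: all indicator tests become
    integer index comparisons (endpoints are snapped to the grid once)."""

    def __init__(self, dataset: Dataset, grid: TimeGrid):
        self.dataset = dataset
        self.grid = grid
        n, K = dataset.n, grid.K
        pts = grid.points
        self.Z = dataset.covariates()
        self.A = dataset.entry_times()
        self.delta = np.array([r.delta for r in dataset.records])
        rstar = np.array([r.r_star for r in dataset.records])

        k = np.arange(K)
        a_lo = np.searchsorted(pts, self.A, side="left")  # first k: t_k >= A
        rs_hi = grid.index_leq(rstar)  # count of t_k <= R*
        self.window = ((k >= a_lo[:, None]) & (k < rs_hi[:, None])).astype(float)

        # exact events: one-hot at T_i
        self.e_exact = np.zeros((n, K))
        for i, rec in enumerate(dataset.records):
            if rec.delta == 1:
                self.e_exact[i, grid.exact_index(rec.T)] = 1.0

        # censored subjects with finite R: positive region (L, R]
        self.pos = np.zeros((n, K))
        for i, rec in enumerate(dataset.records):
            if rec.delta == 0 and np.isfinite(rec.R):
                lo = grid.index_leq(rec.L)  # first k with t_k > L
                hi = grid.index_leq(rec.R)
                if hi <= lo:
                    raise InvalidInputError(
                        f"subject {rec.id}: interval ({rec.L}, {rec.R}] "
                        "contains no grid point"
                    )
                self.pos[i, lo:hi] = 1.0

        # entry-time indicators I(t_k <= A_i), for the pairwise contrasts
        self.entry_ind = (k < grid.index_leq(self.A)[:, None]).astype(float)

    def linpred(self, beta: np.ndarray):
        eta = self.Z @ beta
        return eta, np.exp(eta)


def _pairwise_weights(idx: _Indexed, beta: np.ndarray, lam: np.ndarray):
    """Sigmoid pair weights w_ij = R_ij / (1 + R_ij) and the entry-time
    cumulative-hazard differences ΔΛ_ij, both n x n with zero-information
    diagonal."""
    _, g = idx.linpred(beta)
    LamA = idx.entry_ind @ lam  # Σ_{t_k <= A_i} λ_k
    DL = np.subtract.outer(LamA, LamA)
    w = expit(DL * np.subtract.outer(g, g))
    return w, DL, g


# ---------------------------------------------------------------------------
# E-step
# ---------------------------------------------------------------------------


def estep_expectations(
    params: ParameterState, dataset: Dataset, grid: TimeGrid | None = None,
    _idx: _Indexed | None = None,
) -> ExpectationSet:
    """Conditional means of the latent Poisson counts at the current θ.

    Exact events contribute a unit mass at T_i and zero before; right
    censoring zero throughout; interval (and left) censoring the
    positive-sum-conditioned Poisson mean
    λ_k e^{Z'β} / (1 − exp(−μ_i)) on (L_i, R_i], with μ_i the window mass.
    """
    if _idx is None:
        _idx = _Indexed(dataset, grid if grid is not None else params.grid)
    _, g = _idx.linpred(params.beta)
    M = _idx.pos * params.lam[None, :]
    M *= g[:, None]
    mu = M.sum(axis=1)
    denom = -np.expm1(-mu)  # 1 - e^{-mu}
    safe = np.where(denom > 0, denom, 1.0)  # zero-mass rows stay zero
    M /= safe[:, None]
    small = (mu > 0) & (mu < _MU_UNDERFLOW)
    if small.any():
        # window mass underflowed: use the μ→0 limit λ_k / Σλ_k
        lam_win = _idx.pos[small] * params.lam[None, :]
        tot = lam_win.sum(axis=1, keepdims=True)
        M[small] = np.where(tot > 0, lam_win / np.where(tot > 0, tot, 1.0), 0.0)
    M += _idx.e_exact
    return ExpectationSet(values=M, window=_idx.window)


# ---------------------------------------------------------------------------
# M-step pieces
# ---------------------------------------------------------------------------


def _lambda_denominator_pairwise(idx: _Indexed, beta, lam) -> np.ndarray:
    """Pairwise term of the λ-update denominator at each grid point:
    (1/(n(n−1))) Σ_{i≠j} Q⁰_ij(t_k) w_ij, reduced to O(n² + nK) via the
    factorisation Q⁰_ij(t_k) = (g_i − g_j)(I(t_k<=A_i) − I(t_k<=A_j))."""
    n = idx.dataset.n
    w, _, g = _pairwise_weights(idx, beta, lam)
    S = w * (g[:, None] - g[None, :])
    d = S.sum(axis=1) - S.sum(axis=0)
    return (d @ idx.entry_ind) / (n * (n - 1))


def update_lambda(
    expect: ExpectationSet,
    params: ParameterState,
    dataset: Dataset,
    grid: TimeGrid | None = None,
    method: str = "pairwise",
    lam_floor: float = 1e-10,
    _idx: _Indexed | None = None,
):
    """Closed-form self-consistent update of every baseline jump.

    Numerator: mean expected count at t_k over subjects whose window
    covers t_k.  Denominator: mean at-risk exp(Z'β) plus (pairwise method
    only) the entry-time contrast term evaluated at the *current* θ.
    Grid points with zero numerator estimate λ_k = 0.  The closed form
    does not guarantee nonnegativity (the pairwise contrast can turn the
    denominator negative): negative updates are clamped to ``lam_floor``
    with a warning count.  Tiny positive updates are kept as-is — they
    are legitimate convergence of a jump towards zero.

    Returns ``(new_lam, n_floored)``.
    """
    if _idx is None:
        _idx = _Indexed(dataset, grid if grid is not None else params.grid)
    n = dataset.n
    _, g = _idx.linpred(params.beta)
    num = expect.values.sum(axis=0) / n
    den = (g @ _idx.window) / n
    if method == "pairwise" and n > 1:
        den = den + _lambda_denominator_pairwise(_idx, params.beta, params.lam)

    new_lam = np.zeros_like(num)
    pos = num > 0
    bad = pos & (den == 0)
    if bad.any():
        t_bad = _idx.grid.points[np.argmax(bad)]
        raise NumericalError(
            f"zero denominator with positive numerator in the baseline-jump "
            f"update at t_k = {t_bad}"
        )
    new_lam[pos] = num[pos] / den[pos]
    floored = new_lam < 0
    new_lam[floored] = lam_floor
    return new_lam, int(floored.sum())


def score_lambda(
    params: ParameterState,
    expect: ExpectationSet,
    dataset: Dataset,
    grid: TimeGrid | None = None,
    method: str = "pairwise",
) -> np.ndarray:
    """Composite score U_λk at the given θ and expectations (defined only
    where λ_k > 0)."""
    idx = _Indexed(dataset, grid if grid is not None else params.grid)
    n = dataset.n
    _, g = idx.linpred(params.beta)
    num = expect.values.sum(axis=0) / n
    den = (g @ idx.window) / n
    if method == "pairwise" and n > 1:
        den = den + _lambda_denominator_pairwise(idx, params.beta, params.lam)
    with np.errstate(divide="ignore", invalid="ignore"):
        u = num / params.lam - den
    return u


def score_beta(
    params: ParameterState,
    expect: ExpectationSet,
    dataset: Dataset,
    grid: TimeGrid | None = None,
    method: str = "pairwise",
    _idx: _Indexed | None = None,
) -> np.ndarray:
    """Composite score U_β with expectations held fixed."""
    if _idx is None:
        _idx = _Indexed(dataset, grid if grid is not None else params.grid)
    n = dataset.n
    _, g = _idx.linpred(params.beta)
    resid = expect.values.sum(axis=1) - (_idx.window @ params.lam) * g
    U = (_idx.Z.T @ resid) / n
    if method == "pairwise" and n > 1:
        w, DL, g = _pairwise_weights(_idx, params.beta, params.lam)
        M = w * DL
        c = M.sum(axis=1) - M.sum(axis=0)
        U = U - (_idx.Z.T @ (g * c)) / (n * (n - 1))
    return U


def beta_jacobian(
    params: ParameterState,
    expect: ExpectationSet,
    dataset: Dataset,
    grid: TimeGrid | None = None,
    method: str = "pairwise",
    _idx: _Indexed | None = None,
) -> np.ndarray:
    """Analytic derivative of U_β in β (expectations fixed)."""
    if _idx is None:
        _idx = _Indexed(dataset, grid if grid is not None else params.grid)
    n = dataset.n
    Z = _idx.Z
    _, g = _idx.linpred(params.beta)
    Lg = (_idx.window @ params.lam) * g
    J = -(Z.T @ (Z * Lg[:, None])) / n
    if method == "pairwise" and n > 1:
        w, DL, g = _pairwise_weights(_idx, params.beta, params.lam)
        M = w * DL
        c = M.sum(axis=1) - M.sum(axis=0)
        B = w * (1.0 - w) * DL * DL  # symmetric
        rb = B.sum(axis=1)
        U_mat = Z * g[:, None]  # rows u_i = Z_i e^{Z_i'β}
        term1 = Z.T @ (Z * (g * c)[:, None])
        term2 = 2.0 * (U_mat.T @ (U_mat * rb[:, None]) - U_mat.T @ B @ U_mat)
        J = J - (term1 + term2) / (n * (n - 1))
    return J


def fd_beta_jacobian(
    params: ParameterState,
    expect: ExpectationSet,
    dataset: Dataset,
    grid: TimeGrid | None = None,
    method: str = "pairwise",
    h: float = 1e-6,
) -> np.ndarray:
    """Central finite-difference derivative of U_β in β (expectations
    fixed); reference implementation for the analytic Jacobian."""
    g = grid if grid is not None else params.grid
    p = params.p
    J = np.zeros((p, p))
    for j in range(p):
        bp, bm = params.beta.copy(), params.beta.copy()
        bp[j] += h
        bm[j] -= h
        up = score_beta(ParameterState(bp, params.lam, g), expect, dataset, g, method)
        um = score_beta(ParameterState(bm, params.lam, g), expect, dataset, g, method)
        J[:, j] = (up - um) / (2 * h)
    return J


def _score_and_jacobian(idx: _Indexed, params: ParameterState, expect, method):
    """U_β and its analytic Jacobian sharing one pairwise-weight pass."""
    n = idx.dataset.n
    Z = idx.Z
    _, g = idx.linpred(params.beta)
    Lg = (idx.window @ params.lam) * g
    resid = expect.values.sum(axis=1) - Lg
    U = (Z.T @ resid) / n
    J = -(Z.T @ (Z * Lg[:, None])) / n
    if method == "pairwise" and n > 1:
        w, DL, g = _pairwise_weights(idx, params.beta, params.lam)
        M = w * DL
        c = M.sum(axis=1) - M.sum(axis=0)
        U = U - (Z.T @ (g * c)) / (n * (n - 1))
        B = w * (1.0 - w) * DL * DL
        rb = B.sum(axis=1)
        U_mat = Z * g[:, None]
        term1 = Z.T @ (Z * (g * c)[:, None])
        term2 = 2.0 * (U_mat.T @ (U_mat * rb[:, None]) - U_mat.T @ B @ U_mat)
        J = J - (term1 + term2) / (n * (n - 1))
    return U, J


def newton_step_beta(
    params: ParameterState,
    expect: ExpectationSet,
    dataset: Dataset,
    grid: TimeGrid | None = None,
    method: str = "pairwise",
    _idx: _Indexed | None = None,
):
    """One Newton–Raphson step on U_β(θ) = 0 at the current λ.

    Falls back to a damped gradient (ascent) step with a warning when the
    Jacobian is singular or ill-conditioned.  Returns ``(new_beta,
    fell_back)``.
    """
    if _idx is None:
        _idx = _Indexed(dataset, grid if grid is not None else params.grid)
    U, J = _score_and_jacobian(_idx, params, expect, method)
    try:
        cond = np.linalg.cond(J)
        if not np.isfinite(cond) or cond > 1e12:
            raise np.linalg.LinAlgError("ill-conditioned Jacobian")
        step = np.linalg.solve(J, U)
        return params.beta - step, False
    except np.linalg.LinAlgError:
        warnings.warn(
            "singular/ill-conditioned Jacobian in the β update; taking a "
            "damped gradient step",
            ConvergenceWarning,
        )
        return params.beta + 0.1 * U, True


# ---------------------------------------------------------------------------
# Full EM loop
# ---------------------------------------------------------------------------


def fit(dataset: Dataset, options: FitOptions | None = None) -> FitResult:
    """Run the EM algorithm to convergence (or the iteration cap).

    Each iteration performs: E-step at θ^(l); closed-form λ update (the
    pairwise contrast term frozen at θ^(l)); one Newton step on β at the
    fresh λ.  Convergence is declared when Σ|θ^(l+1) − θ^(l)| < tol.
    """
    if options is None:
        options = FitOptions()
    method = options.method

    if method == "ignore_truncation":
        work = dataset.with_zero_entry()
    else:
        work = dataset
    # jumps live at event/observation times; entry times only locate the
    # at-risk windows and the evaluation points of Λ
    grid = build_time_grid(work, include_entry=False)
    idx = _Indexed(work, grid)
    K, p = grid.K, work.p

    beta = (np.zeros(p) if options.init_beta is None
            else np.atleast_1d(np.asarray(options.init_beta, float)).copy())
    lam = (np.full(K, 1.0 / K) if options.init_lam is None
           else np.atleast_1d(np.asarray(options.init_lam, float)).copy())
    if beta.size != p or lam.size != K:
        raise InvalidInputError("initial values have wrong dimensions")

    # the pairwise contrast drops for the non-pairwise variants
    em_method = "pairwise" if method == "pairwise" else "conditional"

    params = ParameterState(beta, lam, grid)
    if options.track_objective:
        obj0 = composite_objective(params, work, grid)
        if not np.isfinite(obj0):
            raise InvalidInputError(
                "likelihood is -inf at the initial values; data degenerate"
            )
        trace = [obj0]
    else:
        trace = []

    msgs: list = []
    n_floored_total = 0
    converged = False
    it = 0
    for it in range(1, options.max_iter + 1):
        expect = estep_expectations(params, work, grid, _idx=idx)
        new_lam, nfl = update_lambda(
            expect, params, work, grid, em_method,
            lam_floor=options.lam_floor, _idx=idx,
        )
        n_floored_total += nfl
        mid = ParameterState(params.beta, new_lam, grid)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            new_beta, _ = newton_step_beta(mid, expect, work, grid, em_method, _idx=idx)
            msgs.extend(str(c.message) for c in caught)
        delta = np.abs(new_beta - params.beta).sum() + np.abs(new_lam - params.lam).sum()
        params = ParameterState(new_beta, new_lam, grid)
        if options.track_objective:
            trace.append(composite_objective(params, work, grid))
        if log.isEnabledFor(logging.DEBUG):
            log.debug("iter %d  sum|dtheta|=%.3e  objective=%s  floored=%d",
                      it, delta, trace[-1] if trace else "n/a", nfl)
        if delta < options.tol:
            converged = True
            break

    if not converged:
        msgs.append(f"EM did not converge in {options.max_iter} iterations")
    if n_floored_total:
        msgs.append(
            f"baseline-jump floor {options.lam_floor} activated "
            f"{n_floored_total} time(s)"
        )
    return FitResult(
        beta_hat=params.beta,
        lam_hat=params.lam,
        grid=grid,
        converged=converged,
        n_iter=it,
        objective_trace=trace,
        method=method,
        warnings=msgs,
        n_floored=n_floored_total,
    )
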