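"""Model / results interface for the left-truncated Cox fit.

`LeftTruncatedCoxPH` holds the data; `fit()` runs the EM algorithm and
returns a `LeftTruncatedCoxPHResults` carrying the estimates, the
step-function baseline cumulative hazard, convergence diagnostics and —
after `bootstrap()` — standard errors, Wald tests and confidence
intervals, with a `summary()` table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import Dataset, build_time_grid, dataset_from_dataframe, read_dataset
from .em import FitOptions, FitResult, fit as _em_fit
from .exceptions import InvalidInputError
from .inference import BootstrapResult, bootstrap_se, lambda_ci, wald_test
from .likelihood import cumulative_hazard

__all__ = ["LeftTruncatedCoxPH", "LeftTruncatedCoxPHResults"]


class LeftTruncatedCoxPH:
    """Proportional-hazards model for left-truncated, partly
    interval-censored failure times.

    Parameters
    ----------
    data : Dataset or pandas.DataFrame
        Subject-level data; a DataFrame must follow the package's column
        dialect (id, A, delta, T, L, R, Z1..Zp).

    Examples
    --------
    >>> model = LeftTruncatedCoxPH.from_csv("subjects.csv")
    >>> res = model.fit(method="pairwise")
    >>> res.bootstrap(B=100, seed=1)
    >>> print(res.summary())
    """

    def __init__(self, data):
        if isinstance(data, pd.DataFrame):
            data = dataset_from_dataframe(data)
        if not isinstance(data, Dataset):
            raise InvalidInputError("data must be a Dataset or DataFrame")
        self.data = data
        self.exog_names = list(data.covariate_names)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "LeftTruncatedCoxPH":
        return cls(df)

    @classmethod
    def from_csv(cls, path) -> "LeftTruncatedCoxPH":
        return cls(read_dataset(path))

    @property
    def nobs(self) -> int:
        return self.data.n

    def time_grid(self):
        return build_time_grid(self.data)

    def fit(self, method: str = "pairwise", tol: float = 1e-3,
            max_iter: int = 1000, init_beta=None, init_lam=None,
            lam_floor: float = 1e-10,
            track_objective: bool = True) -> "LeftTruncatedCoxPHResults":
        """Fit by the Poisson-augmented EM algorithm.

        ``method`` selects the estimator: ``"pairwise"`` (entry-time
        pairwise pseudo-likelihood, the efficient default),
        ``"conditional"`` (conditional likelihood only) or
        ``"ignore_truncation"`` (entry times zeroed).
        """
        options = FitOptions(
            method=method, tol=tol, max_iter=max_iter, init_beta=init_beta,
            init_lam=init_lam, lam_floor=lam_floor,
            track_objective=track_objective,
        )
        result = _em_fit(self.data, options)
        return LeftTruncatedCoxPHResults(self, result, options)


class LeftTruncatedCoxPHResults:
    """EM estimates plus diagnostics; bootstrap-based inference attaches
    on demand."""

    def __init__(self, model: LeftTruncatedCoxPH, result: FitResult,
                 options: FitOptions):
        self.model = model
        self._result = result
        self._options = options
        self.method = result.method
        self.converged = result.converged
        self.n_iter = result.n_iter
        self.objective_trace = result.objective_trace
        self.grid = result.grid
        self.baseline_jumps = result.lam_hat
        self.params = pd.Series(result.beta_hat, index=model.exog_names)
        self._bootstrap: BootstrapResult | None = None

    # -- point estimates ---------------------------------------------------

    def cumulative_hazard(self, t):
        """Baseline cumulative hazard estimate Λ̂(t) (step function)."""
        return cumulative_hazard(self._result.params, t)

    def baseline_frame(self) -> pd.DataFrame:
        """Step-function table: (t_k, λ̂_k, Λ̂(t_k))."""
        return pd.DataFrame({
            "t": self.grid.points,
            "lambda": self.baseline_jumps,
            "cumhaz": np.cumsum(self.baseline_jumps),
        })

    # -- inference ---------------------------------------------------------

    def bootstrap(self, B: int = 100, eval_times=(), seed: int = 0) -> BootstrapResult:
        """Attach nonparametric-bootstrap standard errors (B resamples)."""
        self._bootstrap = bootstrap_se(
            self.model.data, self._options, B, eval_times=eval_times,
            seed=seed, warm_start=self._result,
        )
        return self._bootstrap

    @property
    def bse(self) -> pd.Series:
        """Bootstrap standard errors of β̂ (NaN before `bootstrap()`)."""
        if self._bootstrap is None:
            return pd.Series(np.nan, index=self.model.exog_names)
        return pd.Series(self._bootstrap.se_beta, index=self.model.exog_names)

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        out = {}
        for name in self.model.exog_names:
            se = self.bse[name]
            out[name] = (wald_test(self.params[name], se)[1]
                         if np.isfinite(se) and se > 0 else np.nan)
        return pd.Series(out)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        from scipy import stats
        z = stats.norm.ppf(1 - alpha / 2)
        lo = self.params - z * self.bse
        hi = self.params + z * self.bse
        return pd.DataFrame({"lower": lo, "upper": hi})

    def cumhaz_conf_int(self, t: float, level: float = 0.95):
        """Log-transformed CI for Λ(t); requires `bootstrap()` with ``t``
        among its ``eval_times``."""
        if self._bootstrap is None or t not in self._bootstrap.se_lambda_at:
            raise InvalidInputError(
                f"no bootstrap SE available at t={t}; pass it via "
                "bootstrap(eval_times=...)"
            )
        return lambda_ci(float(self.cumulative_hazard(t)),
                         self._bootstrap.se_lambda_at[t], level)

    # -- presentation ------------------------------------------------------

    def summary(self) -> str:
        lines = [
            "Left-truncated Cox proportional hazards (NPMLE, EM)",
            f"method: {self.method}    n: {self.model.nobs}    "
            f"grid size: {self.grid.K}",
            f"converged: {self.converged}    iterations: {self.n_iter}",
        ]
        if self._bootstrap is not None:
            lines.append(f"bootstrap resamples: {self._bootstrap.B} "
                         f"({self._bootstrap.n_failed} failed)")
        tab = pd.DataFrame({
            "coef": self.params,
            "boot se": self.bse,
            "z": self.zvalues,
            "P>|z|": self.pvalues,
        })
        ci = self.conf_int()
        tab["[0.025"] = ci["lower"]
        tab["0.975]"] = ci["upper"]
        lines.append(tab.to_string(float_format=lambda v: f"{v: .4f}"))
        return "\n".join(lines)

    def plot_cumulative_hazard(self, ax=None, tmax=None):
        """Step plot of Λ̂(t)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.grid.points
        ax.step(np.concatenate([[0.0], t]),
                np.concatenate([[0.0], np.cumsum(self.baseline_jumps)]),
                where="post")
        ax.set_xlabel("time")
        ax.set_ylabel(r"$\hat\Lambda(t)$")
        if tmax is not None:
            ax.set_xlim(0, tmax)
        return ax
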