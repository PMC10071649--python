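"""Data containers for left-truncated, censored failure-time samples.

A subject enters the study at a truncation (entry) time ``A`` and its
failure time is either observed exactly (``delta=1``, time ``T``) or known
only to lie in an interval ``(L, R]`` with ``R`` possibly infinite
(``delta=0``).  Left censoring is the special case ``L == A`` and right
censoring the case ``R == inf``.  The nonparametric baseline cumulative
hazard is a step function supported on the finite observation, event and
truncation times of the sample; :func:`build_time_grid` constructs that
support.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError

__all__ = [
    "SubjectRecord",
    "Dataset",
    "TimeGrid",
    "build_time_grid",
    "read_dataset",
    "write_dataset",
    "dataset_from_dataframe",
    "dataset_to_dataframe",
]

_INF = float("inf")


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's entry time, censoring status and covariates.

    Parameters
    ----------
    id : object
        Opaque subject label.
    A : float
        Entry (left-truncation) time, ``>= 0``.
    delta : int
        1 if the failure time is observed exactly, 0 if censored.
    T : float, optional
        Exact failure time; present iff ``delta == 1``.
    L, R : float, optional
        Censoring interval ``(L, R]``; present iff ``delta == 0``.
        ``R`` may be ``inf`` (right censoring); ``L == A`` is left
        censoring.
    Z : sequence of float
        Covariate vector of length ``p``.
    """

    id: object
    A: float
    delta: int
    Z: tuple
    T: float | None = None
    L: float | None = None
    R: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "Z", tuple(float(z) for z in self.Z))
        if not np.all(np.isfinite(self.Z)):
            raise InvalidInputError(f"record {self.id}: non-finite covariate")
        if not (math.isfinite(self.A) and self.A >= 0):
            raise InvalidInputError(f"record {self.id}: A must be finite and >= 0")
        if self.delta not in (0, 1):
            raise InvalidInputError(f"record {self.id}: delta must be 0 or 1")
        if self.delta == 1:
            if self.T is None or not math.isfinite(self.T):
                raise InvalidInputError(f"record {self.id}: delta=1 requires finite T")
            if self.L is not None or self.R is not None:
                raise InvalidInputError(f"record {self.id}: delta=1 forbids L/R")
            if self.T < self.A:
                raise InvalidInputError(f"record {self.id}: T < A")
        else:
            if self.T is not None:
                raise InvalidInputError(f"record {self.id}: delta=0 forbids T")
            if self.L is None or self.R is None:
                raise InvalidInputError(f"record {self.id}: delta=0 requires L and R")
            if not math.isfinite(self.L):
                raise InvalidInputError(f"record {self.id}: L must be finite")
            if not (self.A <= self.L < self.R):
                raise InvalidInputError(
                    f"record {self.id}: need A <= L < R (got A={self.A}, "
                    f"L={self.L}, R={self.R})"
                )

    @property
    def p(self) -> int:
        return len(self.Z)

    @property
    def right_censored(self) -> bool:
        return self.delta == 0 and self.R == _INF

    @property
    def left_censored(self) -> bool:
        return self.delta == 0 and self.L == self.A and self.R != _INF

    @property
    def interval_censored(self) -> bool:
        return self.delta == 0 and self.A < self.L and self.R != _INF

    @property
    def r_star(self) -> float:
        """Right end of the subject's latent-count window: T if exact,
        R if interval-censored, L if right-censored."""
        if self.delta == 1:
            return self.T
        return self.L if self.R == _INF else self.R


@dataclass
class Dataset:
    """Ordered collection of :class:`SubjectRecord` sharing covariate
    dimension ``p``."""

    records: list = field(default_factory=list)
    covariate_names: list = None

    def __post_init__(self):
        self.records = list(self.records)
        if len(self.records) < 1:
            raise InvalidInputError("dataset must contain at least one record")
        p = self.records[0].p
        for rec in self.records:
            if rec.p != p:
                raise InvalidInputError("records have inconsistent covariate dimension")
        if self.covariate_names is None:
            self.covariate_names = [f"Z{j + 1}" for j in range(p)]
        elif len(self.covariate_names) != p:
            raise InvalidInputError("covariate_names length must equal p")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def p(self) -> int:
        return self.records[0].p

    def covariates(self) -> np.ndarray:
        """n x p covariate matrix."""
        return np.array([rec.Z for rec in self.records], dtype=float)

    def entry_times(self) -> np.ndarray:
        return np.array([rec.A for rec in self.records], dtype=float)

    def with_zero_entry(self) -> "Dataset":
        """Copy of the dataset with every entry time set to 0 (used by the
        truncation-ignoring estimator)."""
        recs = []
        for rec in self.records:
            if rec.delta == 1:
                recs.append(SubjectRecord(rec.id, 0.0, 1, rec.Z, T=rec.T))
            else:
                recs.append(SubjectRecord(rec.id, 0.0, 0, rec.Z, L=rec.L, R=rec.R))
        return Dataset(recs, covariate_names=list(self.covariate_names))

    def subset(self, indices: Iterable[int]) -> "Dataset":
        """Dataset built from ``records[i]`` for i in ``indices`` (with
        repetition allowed; used by the bootstrap)."""
        recs = [self.records[i] for i in indices]
        return Dataset(recs, covariate_names=list(self.covariate_names))


@dataclass(frozen=True)
class TimeGrid:
    """Strictly increasing support points ``t_1 < ... < t_K`` of the
    step-function baseline cumulative hazard."""

    points: np.ndarray

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 1 or pts.size < 1:
            raise InvalidInputError("grid must be a non-empty 1-d sequence")
        if not np.all(np.diff(pts) > 0):
            raise InvalidInputError("grid points must be strictly increasing")
        if not np.all(np.isfinite(pts)):
            raise InvalidInputError("grid points must be finite")
        object.__setattr__(self, "points", pts)

    @property
    def K(self) -> int:
        return self.points.size

    def index_leq(self, t) -> np.ndarray:
        """Number of grid points <= t, i.e. the exclusive upper index of the
        set {k : t_k <= t}.  Vectorised in ``t``."""
        return np.searchsorted(self.points, np.asarray(t, dtype=float), side="right")

    def exact_index(self, t: float) -> int:
        """Index k with t_k == t; raises if t is not a grid point."""
        k = int(np.searchsorted(self.points, t))
        if k >= self.K or self.points[k] != t:
            raise InvalidInputError(f"time {t} is not a grid point")
        return k


def build_time_grid(dataset: Dataset, include_entry: bool = True) -> TimeGrid:
    """Candidate support of the step-function baseline hazard.

    With ``include_entry=True`` (default) the grid is the sorted unique
    union of exact event times, finite interval endpoints and entry
    times — every time point at which the likelihood evaluates Λ.  The
    fitter places jumps only on the ``include_entry=False`` subset
    (event times and finite interval endpoints): entry times are
    evaluation points of Λ, not candidate mass locations, and granting
    them jumps lets censored-interval mass escape to entry points with
    near-empty risk sets, inflating the baseline estimate near the left
    boundary of the entry distribution.
    """
    times = []
    for rec in dataset:
        if include_entry:
            times.append(rec.A)
        if rec.delta == 1:
            times.append(rec.T)
        else:
            times.append(rec.L)
            if rec.R != _INF:
                times.append(rec.R)
    return TimeGrid(np.unique(np.asarray(times, dtype=float)))


# ---------------------------------------------------------------------------
# CSV dialect: columns id, A, delta, T, L, R, Z1..Zp; T blank when delta=0;
# L,R blank when delta=1; infinite R written as the literal "Inf".
# ---------------------------------------------------------------------------

_FIXED_COLS = ["id", "A", "delta", "T", "L", "R"]


def dataset_to_dataframe(dataset: Dataset) -> pd.DataFrame:
    rows = []
    for rec in dataset:
        row = {
            "id": rec.id,
            "A": rec.A,
            "delta": rec.delta,
            "T": rec.T if rec.delta == 1 else None,
            "L": rec.L if rec.delta == 0 else None,
            "R": rec.R if rec.delta == 0 else None,
        }
        for name, z in zip(dataset.covariate_names, rec.Z):
            row[name] = z
        rows.append(row)
    return pd.DataFrame(rows, columns=_FIXED_COLS + list(dataset.covariate_names))


def dataset_from_dataframe(df: pd.DataFrame) -> Dataset:
    missing = [c for c in _FIXED_COLS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"missing required columns: {missing}")
    znames = [c for c in df.columns if c not in _FIXED_COLS]
    if not znames:
        raise InvalidInputError("no covariate columns (Z1..Zp) found")
    records = []
    for pos, (_, row) in enumerate(df.iterrows()):
        line = pos + 2  # header is line 1
        try:
            delta = int(row["delta"])
            A = float(row["A"])
            Z = [float(row[c]) for c in znames]
            if delta == 1:
                if not (pd.isna(row["L"]) and pd.isna(row["R"])):
                    raise InvalidInputError("delta=1 row has nonempty L/R")
                rec = SubjectRecord(row["id"], A, 1, Z, T=float(row["T"]))
            else:
                if not pd.isna(row["T"]):
                    raise InvalidInputError("delta=0 row has nonempty T")
                rec = SubjectRecord(
                    row["id"], A, 0, Z, L=float(row["L"]), R=float(row["R"])
                )
        except (InvalidInputError, TypeError, ValueError) as exc:
            raise InvalidInputError(f"line {line}: {exc}") from exc
        records.append(rec)
    return Dataset(records, covariate_names=znames)


def read_dataset(path) -> Dataset:
    """Read the package's CSV dialect into a validated :class:`Dataset`."""
    df = pd.read_csv(path, na_values=[""], keep_default_na=False,
                     float_precision="round_trip")
    df = df.replace({"Inf": np.inf, "inf": np.inf})
    df = df.replace("", np.nan)
    for col in ("A", "delta", "T", "L", "R"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="raise")
    return dataset_from_dataframe(df)


def write_dataset(dataset: Dataset, path) -> None:
    """Write ``dataset`` in the CSV dialect (infinite R as ``Inf``)."""
    df = dataset_to_dataframe(dataset)
    df["R"] = df["R"].map(lambda v: "Inf" if v == _INF else v)
    # %.17g guarantees float -> text -> float roundtrips exactly
    df.to_csv(path, index=False, na_rep="", float_format="%.17g")
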