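"""Information processing capacity (IPC).

The metric quantifies how many linearly independent functions of a scalar
input stream a dynamical system computes.  Target functions are products of
Legendre polynomials of delayed inputs,

    y_l(k) = prod_i P_{d_i}(u(k - i)),

identified by their degree tuple ``D_l = (d_0, ..., d_m)`` (trailing entry
nonzero).  The capacity of one target is the squared correlation between
``y_l`` and its best linear reconstruction from the system's state matrix,

    C_l = cov(y_l, z_l)^2 / (var(y_l) var(z_l)),

where ``z_l`` is the least-squares estimate obtained via the Moore-Penrose
pseudoinverse.  Summed over an orthogonal family of targets the capacities
are bounded by the number of readout variables.  Because the estimate is
computed in-sample on a finite record, each capacity carries a chance-level
bias of order N/T; capacities below a chi-squared-derived cutoff are zeroed.

The space of degree tuples is infinite, so :class:`CapacityEstimator`
explores it breadth-first over total degree, extending delays within each
degree level until a run of below-cutoff blocks, and stopping degree growth
after consecutive empty levels (two by default, so that odd-symmetric
systems whose even-degree capacities vanish are still fully explored).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator

__all__ = [
    "TargetFunction",
    "CapacityTable",
    "CapacityEstimator",
    "legendre",
    "build_target",
    "capacity_score",
    "cutoff_threshold",
    "explore_capacities",
    "profile",
]


# ---------------------------------------------------------------------------
# target functions
# ---------------------------------------------------------------------------


def legendre(d: int, s):
    """Legendre polynomial P_d evaluated at s (s in [-1, 1], P_0 = 1)."""
    if d < 0:
        raise ValueError("degree must be non-negative")
    return special.eval_legendre(int(d), s)


@dataclass(frozen=True)
class TargetFunction:
    """A Legendre-product target identified by its degree tuple.

    ``degrees[i]`` is the polynomial degree applied to ``u(k - i)``.  The
    canonical form has a nonzero trailing entry; the tuple then uniquely
    identifies the target.
    """

    degrees: tuple

    def __post_init__(self):
        degs = tuple(int(d) for d in self.degrees)
        if len(degs) == 0 or any(d < 0 for d in degs):
            raise ValueError("degree tuple must be non-empty with non-negative entries")
        if degs[-1] == 0:
            raise ValueError("degree tuple must be canonical (trailing entry nonzero)")
        if sum(degs) < 1:
            raise ValueError("total degree must be >= 1")
        object.__setattr__(self, "degrees", degs)

    @property
    def total_degree(self) -> int:
        return sum(self.degrees)

    @property
    def max_delay(self) -> int:
        return len(self.degrees) - 1

    @property
    def n_factors(self) -> int:
        return sum(1 for d in self.degrees if d > 0)

    def shifted(self, i: int) -> "TargetFunction":
        """The same product applied i steps further in the past."""
        if i < 0:
            raise ValueError("shift must be non-negative")
        return TargetFunction((0,) * i + self.degrees)

    def label(self) -> str:
        return "-".join(str(d) for d in self.degrees)

    @classmethod
    def from_label(cls, label: str) -> "TargetFunction":
        return cls(tuple(int(tok) for tok in label.split("-")))


def build_target(degrees, u, washout: int = 0) -> np.ndarray:
    """Evaluate a Legendre-product target on the input sequence.

    Returns y(k) for k = washout .. T-1; ``washout`` must be at least the
    target's maximum delay so that every required past value exists.
    """
    tf = degrees if isinstance(degrees, TargetFunction) else TargetFunction(tuple(degrees))
    values = np.asarray(getattr(u, "values", u), dtype=float)
    T = values.size
    if tf.max_delay > washout:
        raise ValueError(
            f"target max delay {tf.max_delay} exceeds washout {washout}: history undefined"
        )
    if washout >= T:
        raise ValueError("washout leaves no samples")
    y = np.ones(T - washout)
    for i, d in enumerate(tf.degrees):
        if d > 0:
            y *= special.eval_legendre(d, values[washout - i : T - i])
    return y


# ---------------------------------------------------------------------------
# scores and cutoff
# ---------------------------------------------------------------------------


def capacity_score(y, X) -> float:
    """Squared correlation between y and its least-squares reconstruction from X.

    Columns of X are the readout variables; an intercept is implicit because
    both sides are mean-centered (the covariance form is translation
    invariant).  Returns a value in [0, 1].
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.size:
        raise ValueError("X must be (T, N) and y must be (T,) with matching T")
    yc = y - y.mean()
    ss_y = yc @ yc
    if ss_y <= 0:
        raise ValueError("target has zero variance")
    Xc = X - X.mean(axis=0)
    w, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
    z = Xc @ w
    ss_z = z @ z
    if ss_z <= 0:
        return 0.0
    # for the least-squares z, cov(y,z) = var(z), so corr^2 = var(z)/var(y)
    return float(min((yc @ z) ** 2 / (ss_y * ss_z), 1.0))


def cutoff_threshold(
    N: int, T: int, factor: float = 6.0, tail_p: float = 1e-4, tail: str = "upper"
) -> float:
    """Chance-level cutoff for in-sample capacities.

    Under the null (states independent of the target) T*C is approximately
    chi-squared with N degrees of freedom, so the chance level scales as N/T.
    ``c_ind`` is the chi-squared tail quantile at ``tail_p`` divided by T and
    the returned cutoff is ``factor * c_ind``; the safety factor absorbs the
    unknown dependence corrections for correlated state variables.

    ``tail='upper'`` (default) uses P(chi2(N) >= T*c_ind) = tail_p, the only
    direction that filters chance capacity.  ``tail='lower'`` reproduces the
    literal lower-quantile reading, which is near zero and filters nothing.
    """
    if N <= 0 or T <= 0:
        raise ValueError("N and T must be positive")
    if factor == 0:
        return 0.0
    if tail == "upper":
        q = stats.chi2.isf(tail_p, df=N)
    elif tail == "lower":
        q = stats.chi2.ppf(tail_p, df=N)
    else:
        raise ValueError("tail must be 'upper' or 'lower'")
    return float(factor) * float(q) / float(T)


# ---------------------------------------------------------------------------
# capacity table
# ---------------------------------------------------------------------------


class CapacityTable:
    """Evaluated capacity records with aggregations.

    ``records`` is a DataFrame with columns ``target`` (dash-joined degree
    tuple), ``degree``, ``delay``, ``raw`` (in-sample estimate) and
    ``capacity`` (raw value, or 0 if below the cutoff).  Totals, maximum
    degree and maximum delay are computed over above-cutoff records only.
    """

    def __init__(self, records: pd.DataFrame, N: int, T: int, cutoff: float, meta: dict | None = None):
        self.records = records
        self.N = int(N)
        self.T = int(T)
        self.cutoff = float(cutoff)
        self.meta = dict(meta or {})

    @classmethod
    def from_results(cls, targets, raw, N, T, cutoff, meta=None) -> "CapacityTable":
        raw = np.asarray(raw, dtype=float)
        above = raw >= cutoff
        df = pd.DataFrame(
            {
                "target": [t.label() for t in targets],
                "degree": [t.total_degree for t in targets],
                "delay": [t.max_delay for t in targets],
                "raw": raw,
                "capacity": np.where(above, raw, 0.0),
                "above_cutoff": above,
            }
        )
        return cls(df, N=N, T=T, cutoff=cutoff, meta=meta)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def total_capacity(self) -> float:
        return float(self.records["capacity"].sum())

    @property
    def max_degree(self) -> int:
        above = self.records[self.records["above_cutoff"]]
        return int(above["degree"].max()) if len(above) else 0

    @property
    def max_delay(self) -> int:
        above = self.records[self.records["above_cutoff"]]
        return int(above["delay"].max()) if len(above) else 0

    def above(self) -> pd.DataFrame:
        return self.records[self.records["above_cutoff"]]

    def capacity_at(self, degrees) -> float:
        tf = degrees if isinstance(degrees, TargetFunction) else TargetFunction(tuple(degrees))
        hit = self.records.loc[self.records["target"] == tf.label(), "capacity"]
        return float(hit.iloc[0]) if len(hit) else 0.0

    def linear_memory(self, max_delay: int | None = None) -> np.ndarray:
        """Degree-1 capacity per delay (the system's linear memory curve)."""
        if max_delay is None:
            deg1 = self.records[self.records["degree"] == 1]
            max_delay = int(deg1["delay"].max()) if len(deg1) else 0
        out = np.zeros(max_delay + 1)
        deg1 = self.records[(self.records["degree"] == 1)]
        for _, row in deg1.iterrows():
            if row["delay"] <= max_delay:
                out[int(row["delay"])] = row["capacity"]
        return out

    def profile(self, by: str = "delay", stratify: bool = False):
        return profile(self, by=by, stratify=stratify)

    def nonlinear_capacity(self, min_delay: int = 0) -> float:
        """Total above-cutoff capacity of degree >= 2 targets with delay >= min_delay."""
        df = self.records
        mask = (df["degree"] >= 2) & (df["delay"] >= min_delay)
        return float(df.loc[mask, "capacity"].sum())

    # -- serialization ------------------------------------------------------

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    def to_json(self, path=None):
        payload = {
            "N": self.N,
            "T": self.T,
            "cutoff": self.cutoff,
            "total_capacity": self.total_capacity,
            "max_degree": self.max_degree,
            "max_delay": self.max_delay,
            "meta": self.meta,
            "records": self.records.to_dict(orient="records"),
        }
        if path is None:
            return json.dumps(payload)
        with open(path, "w") as fh:
            json.dump(payload, fh)
        return None


def profile(table: CapacityTable, by: str = "delay", stratify: bool = False):
    """Capacity profile: thresholded capacities summed by delay or degree.

    With ``stratify=True`` returns a delay-by-degree (or degree-by-delay)
    pivot whose entries sum to the total capacity.
    """
    if by not in ("delay", "degree"):
        raise ValueError("by must be 'delay' or 'degree'")
    df = table.records
    if len(df) == 0:
        return pd.Series(dtype=float, name="capacity")
    if stratify:
        other = "degree" if by == "delay" else "delay"
        return df.pivot_table(values="capacity", index=by, columns=other, aggfunc="sum", fill_value=0.0)
    return df.groupby(by)["capacity"].sum()


# ---------------------------------------------------------------------------
# exploration
# ---------------------------------------------------------------------------


def _compositions(total: int, n_slots: int, max_parts: int | None) -> Iterator[tuple]:
    """Weak compositions of `total` into `n_slots` with at most `max_parts` nonzero."""
    if n_slots == 0:
        if total == 0:
            yield ()
        return
    if max_parts is not None and max_parts <= 0:
        if total == 0:
            yield (0,) * n_slots
        return
    for first in range(total + 1):
        rest_parts = max_parts - (1 if first > 0 else 0) if max_parts is not None else None
        for rest in _compositions(total - first, n_slots - 1, rest_parts):
            yield (first,) + rest


def _block_tuples(degree: int, max_delay: int, max_factors: int | None) -> list[TargetFunction]:
    """All canonical degree tuples with the given total degree and exact max delay."""
    out = []
    for last in range(1, degree + 1):
        budget = max_factors - 1 if max_factors is not None else None
        for head in _compositions(degree - last, max_delay, budget):
            out.append(TargetFunction(head + (last,)))
    return out


class CapacityEstimator(BaseEstimator):
    """Estimate the information processing capacity of a state matrix.

    Parameters
    ----------
    max_degree : int
        Hard cap on the total degree explored.
    max_delay : int
        Hard cap on the maximum delay explored (also bounded by the washout).
    max_factors : int or None
        Cap on the number of nonzero entries per degree tuple (None: no cap).
    delay_stall : int
        Consecutive all-below-cutoff delay blocks after which delay growth
        stops within a degree level.
    degree_stall : int
        Consecutive degree levels without any above-cutoff capacity after
        which exploration stops.  The default 2 tolerates systems with a
        parity symmetry whose even (or odd) degrees vanish identically.
    cutoff_factor, tail_p, tail
        Cutoff parameters, see :func:`cutoff_threshold`.
    washout : int or None
        Initial steps excluded from all regressions so every explored target
        has a fully defined history.  None: ``min(max_delay, T // 5)``.
    dtype : numpy dtype
        Floating type for the projection pipeline.

    Attributes
    ----------
    table_ : CapacityTable
        All evaluated records.
    total_capacity_, max_degree_, max_delay_, cutoff_ : summary statistics.
    rank_ : numerical rank of the centered state matrix.
    """

    def __init__(
        self,
        max_degree: int = 20,
        max_delay: int = 200,
        max_factors: int | None = None,
        delay_stall: int = 3,
        degree_stall: int = 2,
        cutoff_factor: float = 6.0,
        tail_p: float = 1e-4,
        tail: str = "upper",
        washout: int | None = None,
        batch_size: int = 256,
        dtype=np.float64,
    ):
        self.max_degree = max_degree
        self.max_delay = max_delay
        self.max_factors = max_factors
        self.delay_stall = delay_stall
        self.degree_stall = degree_stall
        self.cutoff_factor = cutoff_factor
        self.tail_p = tail_p
        self.tail = tail
        self.washout = washout
        self.batch_size = batch_size
        self.dtype = dtype

    # -- internals ----------------------------------------------------------

    def _basis(self, X: np.ndarray) -> np.ndarray:
        """Orthonormal basis of the centered column space (rank-revealing)."""
        Xc = X - X.mean(axis=0)
        # drop exactly constant columns (zero after centering) silently; warn
        # only when the matrix is rank deficient beyond that
        U, s, _ = np.linalg.svd(Xc, full_matrices=False)
        tol = s[0] * max(Xc.shape) * np.finfo(self.dtype).eps if s.size and s[0] > 0 else 0.0
        rank = int(np.sum(s > tol))
        if 0 < rank < min(Xc.shape):
            warnings.warn(
                f"state matrix is rank deficient (rank {rank} < {min(Xc.shape)}); "
                "capacities computed on its column space via the pseudoinverse",
                stacklevel=3,
            )
        self.rank_ = rank
        return np.ascontiguousarray(U[:, :rank])

    def _eval_batch(self, targets: Sequence[TargetFunction]) -> np.ndarray:
        """Capacity of each target against the cached orthonormal basis."""
        W, Tn = self._washout_, self._T_
        n = Tn - W
        Y = np.empty((n, len(targets)), dtype=self.dtype)
        for j, tf in enumerate(targets):
            y = np.ones(n, dtype=self.dtype)
            for i, d in enumerate(tf.degrees):
                if d > 0:
                    y *= self._leg_[d][W - i : Tn - i]
            Y[:, j] = y
        Y -= Y.mean(axis=0)
        ss = np.einsum("ij,ij->j", Y, Y)
        proj = self._Q_.T @ Y
        num = np.einsum("ij,ij->j", proj, proj)
        with np.errstate(invalid="ignore", divide="ignore"):
            caps = np.where(ss > 0, num / ss, 0.0)
        return np.clip(caps, 0.0, 1.0)

    def _eval_and_record(self, targets: list[TargetFunction]) -> np.ndarray:
        caps = np.empty(len(targets))
        bs = int(self.batch_size)
        for start in range(0, len(targets), bs):
            chunk = targets[start : start + bs]
            caps[start : start + len(chunk)] = self._eval_batch(chunk)
        self._targets_.extend(targets)
        self._caps_.append(caps)
        return caps

    # -- estimator API ------------------------------------------------------

    def fit(self, X, u, y=None):
        """Explore the target space and record capacities.

        Parameters
        ----------
        X : array-like of shape (T, N)
            State matrix, one row per input step.
        u : StepSignal or array-like of shape (T,)
            The driving input sequence in [-1, 1].
        """
        X = np.asarray(X, dtype=self.dtype)
        values = np.asarray(getattr(u, "values", u), dtype=self.dtype)
        if X.ndim != 2:
            raise ValueError("X must be 2-d (T, N)")
        if X.shape[0] != values.size:
            raise ValueError("X rows and input length differ")
        if not np.all(np.isfinite(X)):
            raise ValueError("state matrix contains non-finite entries")
        T, N = X.shape
        self.n_features_in_ = N

        washout = self.washout if self.washout is not None else min(self.max_delay, T // 5)
        if washout >= T:
            raise ValueError("washout leaves no samples")
        self._washout_ = int(washout)
        self._T_ = T
        T_eff = T - self._washout_
        delay_cap = min(self.max_delay, self._washout_)

        self.cutoff_ = cutoff_threshold(
            N, T_eff, factor=self.cutoff_factor, tail_p=self.tail_p, tail=self.tail
        )

        self._Q_ = self._basis(X[self._washout_ :])
        # Legendre value cache P_d(u(k)) for every degree that can appear
        self._leg_ = {d: np.asarray(special.eval_legendre(d, values), dtype=self.dtype)
                      for d in range(1, self.max_degree + 1)}
        self._targets_: list[TargetFunction] = []
        self._caps_: list[np.ndarray] = []

        cut = self.cutoff_

        # degree 1: plain delayed inputs, scanned until a below-cutoff run
        stall = 0
        for m in range(delay_cap + 1):
            c = self._eval_and_record([TargetFunction((0,) * m + (1,))])[0]
            stall = 0 if c >= cut else stall + 1
            if stall >= self.delay_stall:
                break

        # higher degrees: blocks of all tuples with given (degree, max delay)
        empty_levels = 0
        for degree in range(2, self.max_degree + 1):
            level_has_mass = False
            stall = 0
            for m in range(delay_cap + 1):
                block = _block_tuples(degree, m, self.max_factors)
                caps = self._eval_and_record(block)
                if np.any(caps >= cut):
                    level_has_mass = True
                    stall = 0
                else:
                    stall += 1
                    if stall >= self.delay_stall:
                        break
            if level_has_mass:
                empty_levels = 0
            else:
                empty_levels += 1
                if empty_levels >= self.degree_stall:
                    break

        raw = np.concatenate(self._caps_) if self._caps_ else np.empty(0)
        self.table_ = CapacityTable.from_results(
            self._targets_,
            raw,
            N=N,
            T=T_eff,
            cutoff=cut,
            meta={
                "washout": self._washout_,
                "rank": self.rank_,
                "params": {k: (None if v is None else (v if np.isscalar(v) else str(v)))
                           for k, v in self.get_params().items()},
            },
        )
        self.total_capacity_ = self.table_.total_capacity
        self.max_degree_ = self.table_.max_degree
        self.max_delay_ = self.table_.max_delay
        # free the large caches but keep the basis for score-like queries
        del self._leg_, self._targets_, self._caps_
        return self

    def evaluate(self, X, u, targets) -> CapacityTable:
        """Score a fixed list of degree tuples without exploring.

        Useful for chance-level calibration (random targets against a null
        state matrix) and for querying specific targets.  The washout and
        cutoff follow the estimator's parameters; targets whose delay
        exceeds the washout are rejected.
        """
        X = np.asarray(X, dtype=self.dtype)
        values = np.asarray(getattr(u, "values", u), dtype=self.dtype)
        tfs = [t if isinstance(t, TargetFunction) else TargetFunction(tuple(t)) for t in targets]
        T, N = X.shape
        washout = self.washout if self.washout is not None else min(self.max_delay, T // 5)
        if any(tf.max_delay > washout for tf in tfs):
            raise ValueError("a target's delay exceeds the washout")
        self._washout_, self._T_ = int(washout), T
        T_eff = T - int(washout)
        self.cutoff_ = cutoff_threshold(
            N, T_eff, factor=self.cutoff_factor, tail_p=self.tail_p, tail=self.tail
        )
        self._Q_ = self._basis(X[int(washout):])
        max_deg = max(max(tf.degrees) for tf in tfs)
        self._leg_ = {d: np.asarray(special.eval_legendre(d, values), dtype=self.dtype)
                      for d in range(1, max_deg + 1)}
        caps = np.empty(len(tfs))
        bs = int(self.batch_size)
        for start in range(0, len(tfs), bs):
            chunk = tfs[start : start + bs]
            caps[start : start + len(chunk)] = self._eval_batch(chunk)
        del self._leg_
        return CapacityTable.from_results(
            tfs, caps, N=N, T=T_eff, cutoff=self.cutoff_,
            meta={"washout": int(washout), "rank": self.rank_, "mode": "evaluate"},
        )

    def score(self, X=None, u=None) -> float:
        """Total capacity of the fitted run (sklearn-style convenience)."""
        if not hasattr(self, "table_"):
            raise AttributeError("CapacityEstimator is not fitted")
        return self.total_capacity_


def explore_capacities(X, u, **limits) -> CapacityTable:
    """Functional wrapper over :class:`CapacityEstimator`; returns the table."""
    est = CapacityEstimator(**limits)
    est.fit(X, u)
    return est.table_
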