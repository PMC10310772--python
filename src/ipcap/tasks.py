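"""Benchmark tasks and linear readouts.

Temporal benchmarks whose scores can be compared with capacity statistics:

* XOR of two simultaneous binary streams (nonlinearity, no memory),
* tXOR — XOR of the current and previous value of one binary stream,
* XORXOR — XOR of two pairwise XORs over four streams,
* delayed classification — which of ten one-hot streams was active d steps
  ago, reported as the largest d still decodable above chance,
* NARMA5 — fifth-order nonlinear autoregressive moving average, requiring
  combined memory and nonlinear computation.

All readouts are linear least-squares fits on the state matrix (the same
machinery the capacity metric uses), trained on a contiguous 80% split and
scored on the held-out 20%.  Binary tasks are scored with Cohen's kappa
(0 at chance, 1 perfect), NARMA with the squared Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import cohen_kappa_score

from ._rng import rng_for

__all__ = [
    "xor_targets",
    "xorxor_targets",
    "txor_targets",
    "narma5",
    "kappa",
    "TaskResult",
    "train_readout",
    "max_classification_delay",
    "capacity_task_correlation",
    "binary_streams",
    "one_hot_streams",
]


# ---------------------------------------------------------------------------
# target generators
# ---------------------------------------------------------------------------


def _check_binary(S) -> np.ndarray:
    S = np.asarray(S)
    if not np.isin(S, (0, 1)).all():
        raise ValueError("task inputs must be binary")
    return S.astype(int)


def xor_targets(streams) -> np.ndarray:
    """XOR of two binary streams, elementwise.  ``streams`` is (T, 2)."""
    S = _check_binary(streams)
    if S.ndim != 2 or S.shape[1] != 2:
        raise ValueError("XOR needs two streams")
    return S[:, 0] ^ S[:, 1]


def xorxor_targets(streams) -> np.ndarray:
    """Nested XOR over four streams: XOR(XOR(s1, s2), XOR(s3, s4))."""
    S = _check_binary(streams)
    if S.ndim != 2 or S.shape[1] != 4:
        raise ValueError("XORXOR needs four streams")
    return (S[:, 0] ^ S[:, 1]) ^ (S[:, 2] ^ S[:, 3])


def txor_targets(stream) -> np.ndarray:
    """Temporal XOR of one stream with its previous value; defined from k=1."""
    s = _check_binary(stream).ravel()
    return s[1:] ^ s[:-1]


def narma5(u_task, alpha: float = 0.2, beta: float = 0.004, gamma: float = 1.5,
           eps: float = 0.001, n: int = 5, bound: float = 1e3) -> np.ndarray:
    """NARMA recurrence of order n (default 5).

    y(t+1) = alpha*y(t) + beta*y(t-1) * sum_{i=0}^{n-1} y(t-i)
             + gamma*u(t-n+1)*u(t) + eps

    History before t=0 is treated as zero for both y and u.  The input is
    expected in a bounded non-negative range (e.g. [0, 0.5]); the recurrence
    aborts if |y| exceeds ``bound``.
    """
    u = np.asarray(u_task, dtype=float)
    T = u.size
    y = np.zeros(T)

    def yv(t):
        return y[t] if t >= 0 else 0.0

    def uv(t):
        return u[t] if t >= 0 else 0.0

    for t in range(T - 1):
        acc = sum(yv(t - i) for i in range(n))
        y[t + 1] = alpha * yv(t) + beta * yv(t - 1) * acc + gamma * uv(t - n + 1) * uv(t) + eps
        if not np.isfinite(y[t + 1]) or abs(y[t + 1]) > bound:
            raise FloatingPointError(f"NARMA{n} diverged at t={t + 1} (y={y[t + 1]:g})")
    return y


def narma_input(u) -> np.ndarray:
    """Map a [-1, 1] signal onto the stable NARMA input range [0, 0.5]."""
    values = np.asarray(getattr(u, "values", u), dtype=float)
    return (values + 1.0) / 4.0


# ---------------------------------------------------------------------------
# scoring and readouts
# ---------------------------------------------------------------------------


def kappa(pred, true) -> float:
    """Cohen's kappa: chance-corrected agreement, 1 perfect, 0 chance.

    Degenerate case with expected agreement 1 (both sides constant and
    equal) is defined as 0.
    """
    pred = np.asarray(pred)
    true = np.asarray(true)
    if pred.shape != true.shape:
        raise ValueError("label vectors must have equal length")
    if np.array_equal(pred, true) and np.unique(true).size == 1:
        return 0.0  # p_e = 1: agreement is guaranteed, no skill shown
    return float(cohen_kappa_score(pred, true))


@dataclass
class TaskResult:
    """Score of one linear-readout benchmark."""

    name: str
    score: float
    score_type: str                      # kappa | r_squared | max_delay
    per_delay_accuracy: list = field(default_factory=list)
    seed: int | None = None


def _split(T: int, train_fraction: float = 0.8) -> int:
    n_train = int(round(T * train_fraction))
    if n_train < 2 or n_train >= T:
        raise ValueError("split leaves too few samples")
    return n_train


def _lstsq_fit(Xtr: np.ndarray, ytr: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
    mean_x = Xtr.mean(axis=0)
    mean_y = ytr.mean(axis=0)
    w, *_ = np.linalg.lstsq(Xtr - mean_x, ytr - mean_y, rcond=None)
    return w, mean_y, mean_x


def train_readout(X, targets, name: str = "task", train_fraction: float = 0.8,
                  kind: str = "auto", washout: int = 0) -> TaskResult:
    """Fit a linear readout on a contiguous train split and score held-out data.

    ``kind='binary'`` thresholds the readout at 0.5 and reports Cohen's
    kappa; ``kind='regression'`` reports the squared Pearson correlation;
    ``'auto'`` picks binary iff the targets take only values {0, 1}.
    """
    X = np.asarray(X, dtype=float)[washout:]
    yt = np.asarray(targets, dtype=float)[washout:]
    if X.shape[0] != yt.shape[0]:
        raise ValueError("states and targets must align (apply the same washout)")
    if kind == "auto":
        kind = "binary" if np.isin(yt, (0.0, 1.0)).all() else "regression"
    n_train = _split(X.shape[0], train_fraction)
    Xtr, Xte = X[:n_train], X[n_train:]
    ytr, yte = yt[:n_train], yt[n_train:]
    if kind == "binary" and np.unique(ytr).size < 2:
        raise ValueError("single-class training split: degenerate targets")
    if np.std(ytr) == 0:
        raise ValueError("constant training targets")
    w, mean_y, mean_x = _lstsq_fit(Xtr, ytr)
    zhat = (Xte - mean_x) @ w + mean_y
    if kind == "binary":
        score = kappa((zhat >= 0.5).astype(int), yte.astype(int))
        return TaskResult(name=name, score=score, score_type="kappa")
    if np.std(yte) == 0 or np.std(zhat) == 0:
        return TaskResult(name=name, score=0.0, score_type="r_squared")
    r = np.corrcoef(zhat, yte)[0, 1]
    return TaskResult(name=name, score=float(r**2), score_type="r_squared")


def max_classification_delay(X, one_hot, train_fraction: float = 0.8,
                             alpha: float = 0.01, washout: int = 0,
                             max_delay: int | None = None) -> TaskResult:
    """Largest delay at which the active one-hot stream is decodable above chance.

    Fits ten one-vs-all linear readouts per delay, classifies held-out steps
    by argmax, and tests the accuracy against the chance rate 1/n_classes
    with a one-sided binomial test at level ``alpha``.  Scanning stops at
    the first delay that fails.
    """
    X = np.asarray(X, dtype=float)
    S = _check_binary(one_hot)
    if not np.all(S.sum(axis=1) == 1):
        raise ValueError("exactly one stream must be active per step")
    T, n_classes = S.shape
    labels = S.argmax(axis=1)
    if max_delay is None:
        max_delay = T // 4
    chance = 1.0 / n_classes
    per_delay = []
    best = -1
    for d in range(max_delay + 1):
        w0 = max(washout, d)
        Xd = X[w0:]
        yd = labels[w0 - d : T - d]
        n_train = _split(Xd.shape[0], train_fraction)
        Xtr, Xte = Xd[:n_train], Xd[n_train:]
        ytr, yte = yd[:n_train], yd[n_train:]
        Y = np.eye(n_classes)[ytr]
        w, mean_y, mean_x = _lstsq_fit(Xtr, Y)
        scores = (Xte - mean_x) @ w + mean_y
        pred = scores.argmax(axis=1)
        acc = float(np.mean(pred == yte))
        per_delay.append(acc)
        k = int(np.sum(pred == yte))
        pval = stats.binomtest(k, n=yte.size, p=chance, alternative="greater").pvalue
        if pval < alpha:
            best = d
        else:
            break
    return TaskResult(name="delayed_classification", score=float(max(best, 0)),
                      score_type="max_delay", per_delay_accuracy=per_delay)


def capacity_task_correlation(scan_stats: pd.DataFrame, task_scores: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations between capacity statistics and task scores.

    ``scan_stats`` and ``task_scores`` are aligned row-per-scan-point frames;
    every stat column is correlated with every task column.  Zero-variance
    columns yield NaN (reported as missing).
    """
    if len(scan_stats) != len(task_scores):
        raise ValueError("scan statistics and task scores must align")
    if len(scan_stats) < 3:
        raise ValueError("need at least 3 scan points for a correlation")
    out = pd.DataFrame(index=scan_stats.columns, columns=task_scores.columns, dtype=float)
    for stat in scan_stats.columns:
        x = scan_stats[stat].to_numpy(dtype=float)
        for task in task_scores.columns:
            y = task_scores[task].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                out.loc[stat, task] = np.nan
            else:
                out.loc[stat, task] = float(np.corrcoef(x, y)[0, 1])
    return out


# ---------------------------------------------------------------------------
# input stream generators
# ---------------------------------------------------------------------------


def binary_streams(T: int, n_streams: int, seed: int = 0) -> np.ndarray:
    """(T, n) i.i.d. fair binary streams from the task-input seed stream."""
    rng = rng_for(seed, "task-input")
    return rng.integers(0, 2, size=(T, n_streams))


def one_hot_streams(T: int, n_classes: int = 10, seed: int = 0) -> np.ndarray:
    """(T, n_classes) one-hot matrix with a uniformly random active stream."""
    rng = rng_for(seed, "task-input")
    labels = rng.integers(0, n_classes, size=T)
    return np.eye(n_classes, dtype=int)[labels]
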