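"""Parameter scans and summary tables.

A scan runs the capacity estimator (and optionally the task suite) over a
grid of system parameters, repeating each grid point for several trials
with derived seeds, and returns a tidy DataFrame: one row per grid point
per trial with total capacity, maximum degree, maximum delay, maximum
memory (max delay times step duration) and task scores.  Per-point seeds
are derived from the root seed and the point index, so serial and
parallel execution agree exactly.
"""

from __future__ import annotations

import itertools
import traceback
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .capacity import CapacityEstimator, CapacityTable
from .encoders import (
    AmplitudeEncoder,
    DistributedEncoder,
    SpatialEncoder,
    choose_input_units,
    encode_task_inputs,
)
from .signals import make_step_signal
from .systems import BalancedRandomNetwork, EchoStateNetwork, FPUTChain, delay_line_states
from .tasks import (
    binary_streams,
    max_classification_delay,
    narma5,
    narma_input,
    one_hot_streams,
    train_readout,
    txor_targets,
    xor_targets,
    xorxor_targets,
)

__all__ = ["ScanSpec", "run_scan", "run_point", "run_esn_tasks", "summarize_table1"]


@dataclass
class ScanSpec:
    """A seeded parameter scan.

    ``axes`` maps parameter names onto value grids; ``base`` holds the fixed
    system parameters.  ``outputs`` selects what to compute per point:
    ``capacity`` and/or ``tasks``.
    """

    system: str                               # esn | fput | brn | delay_line
    axes: dict = field(default_factory=dict)
    base: dict = field(default_factory=dict)
    T: int = 100_000
    delta_s: float = 1.0
    trials: int = 1
    seed: int = 0
    outputs: tuple = ("capacity",)
    estimator: dict = field(default_factory=dict)
    task_T: int = 20_000
    task_washout: int = 100
    task_trials: int = 5

    def grid(self):
        if not self.axes:
            yield {}
            return
        names = list(self.axes)
        for combo in itertools.product(*(self.axes[n] for n in names)):
            yield dict(zip(names, combo))


def _simulate(system: str, params: dict, u, seed: int):
    """Build and run one system; returns the (T, N) state matrix."""
    if system == "esn":
        esn = EchoStateNetwork(
            n_units=params.get("n_units", 50),
            rho=params.get("rho", 0.9),
            iota=params.get("iota", 1.0),
            seed=seed,
        )
        return esn.run(u)
    if system == "delay_line":
        return delay_line_states(params.get("n_taps", 10), u)
    if system == "fput":
        chain = FPUTChain(
            n_osc=params.get("n_osc", 64),
            alpha=params.get("alpha", 0.25),
            tau=params.get("tau", 10.0),
            dt=params.get("dt", 0.1),
            a_max=params.get("a_max", 0.033),
        )
        return chain.run(u)
    if system == "brn":
        brn_keys = {k: v for k, v in params.items()
                    if k in BalancedRandomNetwork().get_params()}
        brn = BalancedRandomNetwork(seed=seed, **brn_keys)
        scheme = params.get("scheme", "amplitude")
        a_max = params.get("a_max", 50.0)
        p = params.get("p", 1.0)
        modality = params.get("modality", "dc")
        if scheme == "spatial":
            ids = np.arange(brn.n_exc)  # spatial encoding clips p to 1
            enc = SpatialEncoder(a_max=a_max, sigma=params.get("sigma", 1.0),
                                 n_units=ids.size, modality=modality)
        else:
            ids = choose_input_units(brn.n_exc, p, seed)
            if scheme == "amplitude":
                enc = AmplitudeEncoder(a_max=a_max, n_units=ids.size, modality=modality)
            elif scheme == "distributed":
                enc = DistributedEncoder(a_max=a_max, n_units=ids.size, seed=seed,
                                         modality=modality)
            else:
                raise ValueError(f"unknown scheme {scheme!r}")
        drive = enc.transform(u)
        drive.input_unit_ids = ids
        return brn.run(drive).states
    raise ValueError(f"unknown system {system!r}")


def run_point(spec: ScanSpec, point: dict, seed: int) -> dict:
    """One grid point, one trial: capacity statistics (and task scores)."""
    params = {**spec.base, **point}
    row: dict = {**point, "seed": seed}
    if "capacity" in spec.outputs:
        u = make_step_signal(spec.T, spec.delta_s, seed=seed)
        X = _simulate(spec.system, params, u, seed)
        est = CapacityEstimator(**spec.estimator)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(X, u)
        records = est.table_.records
        even_mass = records.loc[records["degree"] % 2 == 0, "capacity"].sum()
        row.update(
            total_capacity=est.total_capacity_,
            max_degree=est.max_degree_,
            max_delay=est.max_delay_,
            max_memory=est.max_delay_ * spec.delta_s,
            nonlinear_delay5=est.table_.nonlinear_capacity(min_delay=5),
            even_capacity=float(even_mass),
            cutoff=est.cutoff_,
        )
    if "tasks" in spec.outputs:
        if spec.system != "esn":
            raise NotImplementedError("task scans are implemented for the ESN")
        # task scores are cheap but trial-noisy: average over several input
        # and weight initialisations (capacity statistics are trial-stable)
        trials = []
        for t in range(max(spec.task_trials, 1)):
            trials.append(run_esn_tasks(params, seed + 7919 * t,
                                        T=spec.task_T, washout=spec.task_washout))
        for key in trials[0]:
            row[key] = float(np.mean([tr[key] for tr in trials]))
    return row


def run_esn_tasks(params: dict, seed: int, T: int = 20_000, washout: int = 100) -> dict:
    """XOR family, delayed classification and NARMA5 for one ESN configuration.

    Binary streams drive the network through per-stream random weight
    columns (active value 1, inactive 0, scaled by the input gain); the
    NARMA input is the same uniform signal used for capacity, mapped onto
    [0, 0.5] for the recurrence.
    """
    def fresh():
        return EchoStateNetwork(
            n_units=params.get("n_units", 50),
            rho=params.get("rho", 0.9),
            iota=params.get("iota", 1.0),
            seed=seed,
        )

    out = {}
    S2 = binary_streams(T, 2, seed=seed)
    X = fresh().run(S2)
    out["xor_kappa"] = train_readout(X, xor_targets(S2), "xor", washout=washout).score

    S4 = binary_streams(T, 4, seed=seed + 1)
    X = fresh().run(S4)
    out["xorxor_kappa"] = train_readout(X, xorxor_targets(S4), "xorxor", washout=washout).score

    S1 = binary_streams(T, 1, seed=seed + 2)
    X = fresh().run(S1)
    out["txor_kappa"] = train_readout(
        X[1:], txor_targets(S1[:, 0]), "txor", washout=washout
    ).score

    S10 = one_hot_streams(T, 10, seed=seed + 3)
    X = fresh().run(S10)
    out["classification_delay"] = max_classification_delay(X, S10, washout=washout).score

    u = make_step_signal(T, 1.0, seed=seed + 4)
    X = fresh().run(u)
    y = narma5(narma_input(u))
    out["narma5_r2"] = train_readout(X, y, "narma5", kind="regression", washout=washout).score
    return out


def run_scan(spec: ScanSpec) -> pd.DataFrame:
    """Run the full grid; failures are recorded per row, the scan continues."""
    rows = []
    for idx, point in enumerate(spec.grid()):
        for trial in range(spec.trials):
            seed = spec.seed + 1000 * idx + trial
            try:
                row = run_point(spec, point, seed)
                row["error"] = ""
            except Exception as exc:  # keep scanning on individual failures
                row = {**point, "seed": seed, "error": f"{type(exc).__name__}: {exc}"}
                traceback.print_exc()
            row["point_index"] = idx
            row["trial"] = trial
            rows.append(row)
    return pd.DataFrame(rows)


def aggregate_trials(results: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard deviation over trials for each grid point."""
    num = results.select_dtypes("number").columns.difference(["trial", "seed"])
    grouped = results.groupby("point_index")[list(num)]
    agg = grouped.agg(["mean", "std"])
    agg.columns = [f"{c}_{s}" for c, s in agg.columns]
    return agg.reset_index()


def summarize_table1(results: dict[str, pd.DataFrame], readout_units: dict[str, int]) -> pd.DataFrame:
    """Per-system summary: best task scores and capacity statistics.

    ``results`` maps a system label onto its scan result frame.  For each
    system the summary reports the maximum over the scan of every task
    score and capacity statistic, plus the normalized capacity (total
    capacity as a fraction of the readout-unit count, in percent).
    """
    cols = [
        "xor_kappa", "xorxor_kappa", "txor_kappa", "classification_delay",
        "narma5_r2", "total_capacity", "max_degree", "max_delay",
    ]
    rows = []
    for label, df in results.items():
        ok = df[df.get("error", "") == ""] if "error" in df else df
        row: dict = {"system": label, "readout_units": readout_units.get(label)}
        for col in cols:
            row[col] = float(ok[col].max()) if col in ok and len(ok) else np.nan
        if row.get("total_capacity") is not None and readout_units.get(label):
            row["normalized_capacity_pct"] = 100.0 * row["total_capacity"] / readout_units[label]
        rows.append(row)
    return pd.DataFrame(rows)
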