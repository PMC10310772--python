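"""Encoder-capacity subtraction.

A nonlinear or memory-bearing encoder biases the capacity estimate of the
downstream system: the measured (combined) system can score on nonlinear
targets merely by remembering what the encoder already computed.  This
module estimates the encoder's own capacity from its drive matrix, derives
how much of the encoder output the system retains per delay (its effective
linear memory), and removes every combined record that could be a
remembered encoder computation.  What remains is a conservative lower
bound on the system's own capacity; it never exceeds the combined total
and never contains a record absent from the combined table.

Subtraction rule (full-subtraction lower bound):

* any combined record whose degree tuple equals an above-cutoff encoder
  tuple is removed — at zero shift the system may simply relay the encoder;
* for encoder targets beyond the pure input target D=(1,), i.e. nonlinear
  or delayed ones, the time-shifted versions (i leading zeros prepended)
  are removed as well for every shift i >= 1 at which the system retains
  encoder output (retention fraction f(i) > 0).

The pure input target is exempt from shifting because remembering the raw
input is exactly the system's own linear memory, which the per-delay
differencing already attributes correctly; removing its shifts would wipe
legitimate memory even for a perfectly linear encoder.  With an affine
memoryless encoder the correction therefore reduces to dropping the single
delay-0 linear record.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .capacity import CapacityEstimator, CapacityTable, TargetFunction
from .encoders import EncoderOutput

__all__ = [
    "MemoryFractions",
    "encoder_capacity",
    "linear_memory_difference",
    "subtract_encoder_full",
]


def encoder_capacity(enc: EncoderOutput, u, **estimator_kwargs) -> CapacityTable:
    """Capacity of the encoder itself: the drive matrix is the state matrix.

    Constant drive columns carry no information and are dropped (the
    estimator's basis construction removes them after centering).
    """
    drive = np.asarray(enc.drive, dtype=float)
    keep = drive.std(axis=0) > 0
    if not np.any(keep):
        # zero/constant drive: empty table at the trivial cutoff
        import pandas as pd

        est = CapacityEstimator(**estimator_kwargs)
        records = pd.DataFrame(
            columns=["target", "degree", "delay", "raw", "capacity", "above_cutoff"]
        )
        return CapacityTable(records, N=drive.shape[1], T=drive.shape[0], cutoff=0.0,
                             meta={"provenance": "encoder", "constant_drive": True})
    est = CapacityEstimator(**estimator_kwargs)
    est.fit(drive[:, keep], u)
    table = est.table_
    table.meta["provenance"] = "encoder"
    return table


@dataclass
class MemoryFractions:
    """Per-delay fraction of the encoder output the system retains.

    ``fractions[i]`` (i >= 1) is the system's own linear memory at delay i —
    combined degree-1 capacity minus encoder degree-1 capacity, floored at
    zero — normalized by the encoder's delay-0 linear capacity and clipped
    to [0, 1].  Index 0 is 0 by convention: at zero delay the combined and
    encoder linear capacities coincide for any system that sees the drive.
    """

    fractions: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.fractions, dtype=float)
        if np.any((f < 0) | (f > 1)):
            raise ValueError("fractions must lie in [0, 1]")
        self.fractions = f

    def __getitem__(self, i: int) -> float:
        return float(self.fractions[i]) if i < self.fractions.size else 0.0

    def __len__(self) -> int:
        return self.fractions.size


def linear_memory_difference(combined: CapacityTable, encoder: CapacityTable) -> MemoryFractions:
    """System linear memory per delay, as retention fractions.

    Subtracts the encoder's degree-1 capacity from the combined degree-1
    capacity at each delay (floored at 0) and normalizes by the encoder's
    delay-0 linear capacity.
    """
    enc0 = encoder.capacity_at((1,))
    if enc0 <= 0:
        raise ValueError(
            "encoder has no delay-0 linear capacity; retention fractions undefined"
        )
    max_delay = max(combined.max_delay, encoder.max_delay)
    sys_mem = np.maximum(
        combined.linear_memory(max_delay) - encoder.linear_memory(max_delay), 0.0
    )
    fractions = np.clip(sys_mem / enc0, 0.0, 1.0)
    fractions[0] = 0.0
    return MemoryFractions(fractions)


def subtract_encoder_full(
    combined: CapacityTable,
    encoder: CapacityTable,
    fractions: MemoryFractions | None = None,
) -> CapacityTable:
    """Full-subtraction lower bound on the system's own capacity.

    Removes from ``combined`` every record that could be a remembered
    encoder computation (see module docstring for the rule).  Totals are
    recomputed over the remaining records.
    """
    if fractions is None:
        fractions = linear_memory_difference(combined, encoder)

    enc_above = [TargetFunction.from_label(lbl) for lbl in encoder.above()["target"]]
    banned: set[tuple] = {tf.degrees for tf in enc_above}
    pure_input = (1,)
    max_shift = combined.max_delay + 1
    for tf in enc_above:
        if tf.degrees == pure_input:
            continue  # raw-input memory is genuine system memory
        for i in range(1, max_shift + 1):
            if fractions[i] > 0:
                banned.add(tf.shifted(i).degrees)

    labels = {"-".join(str(d) for d in tup) for tup in banned}
    mask = ~combined.records["target"].isin(labels)
    records = combined.records[mask].reset_index(drop=True)
    meta = dict(combined.meta)
    meta["provenance"] = "encoder_subtracted"
    meta["n_removed"] = int((~mask).sum())
    return CapacityTable(records, N=combined.N, T=combined.T, cutoff=combined.cutoff, meta=meta)
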