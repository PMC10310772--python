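"""Random input signals.

The capacity metric drives a system with a scalar sequence ``u(k)`` drawn
i.i.d. from a uniform distribution on [-1, 1].  For continuous-time systems
the sequence is extended to a piecewise-constant signal ``u(t) = u(k)`` for
``(k-1)*ds <= t < k*ds`` where ``ds`` is the step duration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._rng import rng_for

__all__ = ["StepSignal", "make_step_signal"]


@dataclass(frozen=True)
class StepSignal:
    """A discrete input sequence and its piecewise-constant extension.

    Parameters
    ----------
    values : ndarray of shape (T,)
        Input values, all within the closed interval [-1, 1].
    step_duration : float
        Duration of each step (1 for discrete-time systems).
    seed : int or None
        Root seed the sequence was drawn from (None for user-supplied data).
    """

    values: np.ndarray
    step_duration: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size == 0:
            raise ValueError("values must be a non-empty 1-d sequence")
        if self.step_duration <= 0:
            raise ValueError("step_duration must be positive")
        if np.any(np.abs(values) > 1.0):
            raise ValueError("input values must lie in [-1, 1]")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.size

    @property
    def T(self) -> int:
        return self.values.size

    def at_time(self, t):
        """Sample the continuous extension u(t) on [0, T*step_duration)."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0) or np.any(t >= self.T * self.step_duration):
            raise ValueError("t outside the signal support [0, T*step_duration)")
        idx = np.floor(t / self.step_duration).astype(int)
        return self.values[idx]

    def delayed(self, delay: int) -> np.ndarray:
        """u(k - delay) with zeros before the start (use a washout to avoid them)."""
        if delay == 0:
            return self.values
        out = np.zeros_like(self.values)
        out[delay:] = self.values[:-delay]
        return out

    # -- serialization ------------------------------------------------------

    def to_csv(self, path) -> None:
        header = f"step_duration={self.step_duration!r},seed={self.seed!r}\nu"
        np.savetxt(path, self.values, header=header, comments="# ")

    @classmethod
    def from_csv(cls, path) -> "StepSignal":
        lines = Path(path).read_text().splitlines()
        meta = lines[0].lstrip("# ").strip()
        fields = dict(item.split("=") for item in meta.split(","))
        seed = None if fields.get("seed", "None") == "None" else int(fields["seed"])
        values = np.loadtxt(path, comments="#", skiprows=2 if lines[1].startswith("#") else 1)
        return cls(values=np.atleast_1d(values), step_duration=float(fields["step_duration"]), seed=seed)


def make_step_signal(T: int, delta_s: float = 1.0, seed: int = 0) -> StepSignal:
    """Draw ``T`` i.i.d. uniform values on [-1, 1].

    The same ``seed`` always yields a byte-identical sequence; the draw uses
    the dedicated ``input`` sub-stream so that other seeded components
    (weights, noise, encoders) do not perturb it.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if delta_s <= 0:
        raise ValueError("delta_s must be positive")
    rng = rng_for(seed, "input")
    values = rng.uniform(-1.0, 1.0, size=int(T))
    return StepSignal(values=values, step_duration=float(delta_s), seed=int(seed))
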