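"""Input encoding schemes for continuous-time and spiking systems.

A scalar step signal u(k) in [-1, 1] must be turned into a per-unit drive
a_j(k) before it can enter a physical system.  Three schemes are provided:

* amplitude-value: every input unit receives the same affinely rescaled
  signal a(k) = (u(k)+1)/2 * a_max.  This encoder is linear and memoryless,
  so it does not distort the downstream capacity estimate.
* distributed-value: a(k) is multiplied by a per-unit weight w_j drawn once
  from U(-1, 1), so each unit sees a differently scaled copy.
* spatial-value: the value of u(k) selects the position of an unnormalized
  Gaussian bump of peak a_max and spread sigma across the input units
  (center mu(k) = (u(k)+1)/2 * N_inp, no periodic wrap so the two extremes
  remain distinguishable).  This encoder is nonlinear but memoryless.

The drive can be delivered as a direct current (amplitudes in pA) or as the
piecewise-constant rates of independent inhomogeneous Poisson generators
(amplitudes in spikes/s).  The drive matrix itself doubles as the encoder's
own state matrix when estimating encoder capacity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from ._rng import rng_for
from .signals import StepSignal

__all__ = [
    "EncoderOutput",
    "AmplitudeEncoder",
    "DistributedEncoder",
    "SpatialEncoder",
    "amplitude_encode",
    "distributed_encode",
    "spatial_encode",
    "to_poisson_spikes",
    "background_noise",
    "encode_task_inputs",
]


@dataclass
class EncoderOutput:
    """Per-step, per-unit drive produced by an encoder.

    ``drive`` has shape (T, N_inp); ``modality`` is ``"dc"`` (amplitudes are
    currents, may be negative) or ``"poisson_rate"`` (amplitudes are firing
    rates, non-negative after clipping).  ``input_unit_ids`` maps drive
    columns onto unit indices of the receiving system.
    """

    drive: np.ndarray
    modality: str = "dc"
    input_unit_ids: np.ndarray | None = None
    step_duration: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.drive = np.atleast_2d(np.asarray(self.drive, dtype=float))
        if self.input_unit_ids is None:
            self.input_unit_ids = np.arange(self.drive.shape[1])

    @property
    def n_units(self) -> int:
        return self.drive.shape[1]

    @property
    def T(self) -> int:
        return self.drive.shape[0]


def _signal_values(u):
    return np.asarray(getattr(u, "values", u), dtype=float)


def _step_duration(u, default=1.0):
    return float(getattr(u, "step_duration", default))


def choose_input_units(n_candidates: int, p: float, seed: int) -> np.ndarray:
    """Seeded sample without replacement of round(p * n_candidates) input units."""
    if not 0 < p <= 1:
        raise ValueError("input density p must be in (0, 1]")
    n_inp = int(round(p * n_candidates))
    if n_inp < 1:
        raise ValueError("p * N < 1: no input units")
    rng = rng_for(seed, "encoder-units")
    return np.sort(rng.choice(n_candidates, size=n_inp, replace=False))


class AmplitudeEncoder(BaseEstimator, TransformerMixin):
    """Affine amplitude-value encoding: a(k) = (u(k)+1)/2 * a_max to all units.

    The map is bijective and memoryless, so the encoder's own capacity is a
    single degree-1 delay-0 record; it serves as the linear reference encoder.
    """

    def __init__(self, a_max: float = 1.0, n_units: int = 1, modality: str = "dc"):
        self.a_max = a_max
        self.n_units = n_units
        self.modality = modality

    def fit(self, u=None, y=None):
        if self.a_max <= 0:
            raise ValueError("a_max must be positive")
        return self

    def transform(self, u) -> EncoderOutput:
        self.fit(u)
        values = _signal_values(u)
        a = (values + 1.0) / 2.0 * self.a_max
        drive = np.repeat(a[:, None], self.n_units, axis=1)
        return EncoderOutput(drive, modality=self.modality, step_duration=_step_duration(u),
                             meta={"scheme": "amplitude", "a_max": self.a_max})


class DistributedEncoder(BaseEstimator, TransformerMixin):
    """Distributed-value encoding: a_j(k) = a(k) * w_j, w_j ~ U(-1, 1).

    Weights are drawn once per run from the ``encoder`` seed stream and kept
    fixed, so two encoders with the same seed agree exactly.
    """

    def __init__(self, a_max: float = 1.0, n_units: int = 1, seed: int = 0, modality: str = "dc"):
        self.a_max = a_max
        self.n_units = n_units
        self.seed = seed
        self.modality = modality

    def fit(self, u=None, y=None):
        if self.a_max <= 0:
            raise ValueError("a_max must be positive")
        if self.n_units < 1:
            raise ValueError("need at least one input unit (p*N < 1?)")
        rng = rng_for(self.seed, "encoder")
        self.weights_ = rng.uniform(-1.0, 1.0, size=self.n_units)
        return self

    def transform(self, u) -> EncoderOutput:
        if not hasattr(self, "weights_"):
            self.fit(u)
        values = _signal_values(u)
        a = (values + 1.0) / 2.0 * self.a_max
        drive = a[:, None] * self.weights_[None, :]
        if self.modality == "poisson_rate":
            drive = np.clip(drive, 0.0, None)  # rates cannot be negative
        return EncoderOutput(drive, modality=self.modality, step_duration=_step_duration(u),
                             meta={"scheme": "distributed", "a_max": self.a_max, "seed": self.seed})


class SpatialEncoder(BaseEstimator, TransformerMixin):
    """Spatial-value encoding: a Gaussian bump positioned by the input value.

    Unit j receives a_j(k) = a_max * exp(-(j - mu(k))^2 / (2 sigma^2)) with
    mu(k) = (u(k)+1)/2 * N_inp.  No periodic boundary is used, so u = -1 and
    u = +1 excite opposite ends of the population and stay distinguishable.
    The profile depends only on the current input value: the encoder is
    nonlinear but introduces no memory.
    """

    def __init__(self, a_max: float = 1.0, sigma: float = 1.0, n_units: int = 10, modality: str = "dc"):
        self.a_max = a_max
        self.sigma = sigma
        self.n_units = n_units
        self.modality = modality

    def fit(self, u=None, y=None):
        if self.a_max <= 0:
            raise ValueError("a_max must be positive")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.n_units < 2:
            raise ValueError("spatial encoding needs at least 2 units")
        return self

    def transform(self, u) -> EncoderOutput:
        self.fit(u)
        values = _signal_values(u)
        mu = (values + 1.0) / 2.0 * self.n_units
        j = np.arange(self.n_units, dtype=float)
        drive = self.a_max * np.exp(-((j[None, :] - mu[:, None]) ** 2) / (2.0 * self.sigma**2))
        return EncoderOutput(drive, modality=self.modality, step_duration=_step_duration(u),
                             meta={"scheme": "spatial", "a_max": self.a_max, "sigma": self.sigma})


# -- functional wrappers ----------------------------------------------------


def amplitude_encode(u, a_max: float, n_units: int = 1, modality: str = "dc") -> EncoderOutput:
    return AmplitudeEncoder(a_max=a_max, n_units=n_units, modality=modality).transform(u)


def distributed_encode(u, a_max: float, n_units: int, seed: int = 0, modality: str = "dc") -> EncoderOutput:
    return DistributedEncoder(a_max=a_max, n_units=n_units, seed=seed, modality=modality).transform(u)


def spatial_encode(u, a_max: float, sigma: float, n_units: int, modality: str = "dc") -> EncoderOutput:
    return SpatialEncoder(a_max=a_max, sigma=sigma, n_units=n_units, modality=modality).transform(u)


# -- spike generation -------------------------------------------------------


def to_poisson_spikes(enc: EncoderOutput, dt: float, seed: int = 0) -> list[np.ndarray]:
    """Inhomogeneous Poisson spike trains with piecewise-constant rates.

    The rate of unit j during step k is ``enc.drive[k, j]`` in spikes per
    unit of ``enc.step_duration``'s time base.  Returns one sorted spike-time
    array per unit.  Rates must be non-negative (distributed-scheme DC drive
    must be clipped before conversion).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    rates = enc.drive
    if np.any(rates < 0):
        raise ValueError("negative rates: clip the drive before Poisson conversion")
    rng = rng_for(seed, "poisson-input")
    T, n_units = rates.shape
    ds = enc.step_duration
    trains: list[list[float]] = [[] for _ in range(n_units)]
    for k in range(T):
        t0 = k * ds
        counts = rng.poisson(rates[k] * ds)
        for j in np.nonzero(counts)[0]:
            times = t0 + rng.uniform(0.0, ds, size=counts[j])
            trains[j].extend(times.tolist())
    return [np.sort(np.asarray(tr)) for tr in trains]


def background_noise(
    n_neurons: int,
    nu_noise: float,
    delta_s: float,
    T: int,
    kind: str = "frozen",
    seed: int = 0,
) -> list[np.ndarray]:
    """Per-neuron Poisson background spike trains over T input steps.

    ``frozen``: one Poisson pattern of length ``delta_s`` is drawn per neuron
    and repeated every step, making the background deterministic across
    steps.  ``changing``: fresh Poisson spikes every step.  ``none`` or a
    zero rate yield empty trains.  Times are in the same unit as delta_s;
    rates in spikes per unit time.
    """
    if nu_noise < 0:
        raise ValueError("noise rate must be non-negative")
    if kind not in ("frozen", "changing", "none"):
        raise ValueError("kind must be frozen|changing|none")
    rng = rng_for(seed, "noise")
    if kind == "none" or nu_noise == 0:
        return [np.empty(0) for _ in range(n_neurons)]
    if kind == "frozen":
        trains = []
        for _ in range(n_neurons):
            n_sp = rng.poisson(nu_noise * delta_s)
            base = np.sort(rng.uniform(0.0, delta_s, size=n_sp))
            times = (base[None, :] + (np.arange(T) * delta_s)[:, None]).ravel()
            trains.append(times)
        return trains
    trains = []
    for _ in range(n_neurons):
        counts = rng.poisson(nu_noise * delta_s, size=T)
        total = int(counts.sum())
        offsets = rng.uniform(0.0, delta_s, size=total)
        starts = np.repeat(np.arange(T) * delta_s, counts)
        trains.append(np.sort(starts + offsets))
    return trains


# -- task-input encoding ----------------------------------------------------


def encode_task_inputs(streams, scheme: str, a_max: float = 1.0, n_units: int = 10,
                       sigma: float = 1.0, seed: int = 0, modality: str = "dc") -> EncoderOutput:
    """Encode n binary input streams for task benchmarks.

    ``streams`` is a (T, n) binary matrix.  Under the distributed scheme each
    stream gets its own U(-1,1) weight vector and an active stream
    contributes a_max through it; under the spatial scheme stream i places a
    Gaussian bump at mean (i+1) * n_units / (n+1) (means evenly distributed
    over the population) when active.  Simultaneously active streams add.
    """
    S = np.asarray(streams)
    if S.ndim == 1:
        S = S[:, None]
    if not np.isin(S, (0, 1)).all():
        raise ValueError("task streams must be binary")
    T, n = S.shape
    if scheme == "distributed":
        rng = rng_for(seed, "encoder")
        W = rng.uniform(-1.0, 1.0, size=(n, n_units))
        drive = (S * a_max) @ W
        if modality == "poisson_rate":
            drive = np.clip(drive, 0.0, None)
    elif scheme == "spatial":
        j = np.arange(n_units, dtype=float)
        means = (np.arange(n) + 1.0) * n_units / (n + 1.0)
        profiles = a_max * np.exp(-((j[None, :] - means[:, None]) ** 2) / (2.0 * sigma**2))
        drive = S.astype(float) @ profiles
    elif scheme == "amplitude":
        drive = np.repeat(S.sum(axis=1, keepdims=True).astype(float) * a_max, n_units, axis=1)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return EncoderOutput(drive, modality=modality, meta={"scheme": scheme, "task": True})
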