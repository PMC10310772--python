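"""Reference dynamical systems.

Each system maps an input (a step signal or an encoded drive) onto a state
matrix: one row per input step, one column per readout variable, sampled at
the end of each step.  Provided systems:

* :class:`EchoStateNetwork` — discrete-time tanh recurrent network with an
  orthogonalized recurrent matrix scaled by a feedback gain rho and input
  weights scaled by an input gain iota.
* :class:`FPUTChain` — damped, input-driven alpha-Fermi-Pasta-Ulam-Tsingou
  oscillator chain (quadratic nearest-neighbour nonlinearity), integrated
  with a semi-implicit velocity-Verlet scheme and fixed ends.
* :class:`BalancedRandomNetwork` — excitatory/inhibitory leaky
  integrate-and-fire network with delta synapses, fixed in-degrees and
  Poisson background noise (frozen or changing), readout = excitatory
  membrane potentials at step ends.
* :func:`delay_line_states` — a pure delay line used as an analytically
  tractable oracle (capacity exactly 1 per delay up to its length).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg
from sklearn.base import BaseEstimator

from ._rng import rng_for
from .encoders import EncoderOutput
from .signals import StepSignal

__all__ = [
    "EchoStateNetwork",
    "FPUTChain",
    "BalancedRandomNetwork",
    "delay_line_states",
]


def _values(u):
    return np.asarray(getattr(u, "values", u), dtype=float)


# ---------------------------------------------------------------------------
# echo state network
# ---------------------------------------------------------------------------


class EchoStateNetwork(BaseEstimator):
    """Discrete-time echo state network.

    x(k+1) = tanh(rho * W x(k) + iota * V u(k)) with W a random matrix
    orthogonalized (QR of a U(-1,1) matrix) and rescaled to unit spectral
    radius before the feedback gain rho is applied; input weights V are
    drawn from U(-1, 1).  All units receive the input.  For task benchmarks
    several input streams can drive the network, each through its own
    weight column.
    """

    def __init__(self, n_units: int = 50, rho: float = 0.9, iota: float = 1.0, seed: int = 0):
        self.n_units = n_units
        self.rho = rho
        self.iota = iota
        self.seed = seed

    def _build(self, n_streams: int = 1):
        rng = rng_for(self.seed, "weights")
        A = rng.uniform(-1.0, 1.0, size=(self.n_units, self.n_units))
        Q, R = np.linalg.qr(A)
        # fix the sign ambiguity so the matrix is a deterministic function of A
        Q = Q * np.sign(np.diag(R))[None, :]
        radius = np.max(np.abs(np.linalg.eigvals(Q)))
        self.W_ = Q / radius
        self.V_ = rng.uniform(-1.0, 1.0, size=(self.n_units, n_streams))
        return self

    def run(self, u, x0=None) -> np.ndarray:
        """Drive the network and return the (T, N) state matrix.

        ``u`` may be a StepSignal / 1-d array (single stream) or a (T, n)
        matrix of stream values.
        """
        U = _values(u)
        if U.ndim == 1:
            U = U[:, None]
        T, n_streams = U.shape
        if not hasattr(self, "W_") or self.V_.shape[1] != n_streams:
            self._build(n_streams)
        x = np.zeros(self.n_units) if x0 is None else np.asarray(x0, dtype=float)
        X = np.empty((T, self.n_units))
        W = self.rho * self.W_
        Vin = self.iota * self.V_
        for k in range(T):
            x = np.tanh(W @ x + Vin @ U[k])
            X[k] = x
        if not np.all(np.isfinite(X)):
            raise FloatingPointError("ESN produced non-finite states")
        return X


# ---------------------------------------------------------------------------
# FPUT chain
# ---------------------------------------------------------------------------


class FPUTChain(BaseEstimator):
    """Damped, driven alpha-FPUT oscillator chain with fixed ends.

    xdd_i = (x_{i+1} + x_{i-1} - 2 x_i)
            + alpha ((x_{i+1}-x_i)^2 - (x_{i-1}-x_i)^2)
            - xd_i / tau - a(t)

    The external field a(t) couples to all oscillators equally and is held
    piecewise constant over each input step.  The input mapping is
    mean-zero, a(t) = a_max * u(t), because the field couples with zero
    temporal mean.  Integration uses velocity Verlet with the damping term
    handled semi-implicitly; positions at the end of each input step form
    the state matrix.
    """

    def __init__(self, n_osc: int = 64, alpha: float = 0.25, tau: float = 10.0,
                 dt: float = 0.1, a_max: float = 0.033, divergence_limit: float = 1e6):
        self.n_osc = n_osc
        self.alpha = alpha
        self.tau = tau
        self.dt = dt
        self.a_max = a_max
        self.divergence_limit = divergence_limit

    def _spring_force(self, x: np.ndarray) -> np.ndarray:
        xp = np.concatenate(([0.0], x, [0.0]))  # fixed boundary oscillators
        right = xp[2:] - xp[1:-1]
        left = xp[1:-1] - xp[:-2]
        return right - left + self.alpha * (right**2 - left**2)

    def run(self, u, x0=None, v0=None, return_velocities: bool = False):
        """Integrate the chain; returns the (T, n_osc) position state matrix."""
        if self.alpha < 0 or self.tau <= 0 or self.dt <= 0:
            raise ValueError("need alpha >= 0, tau > 0, dt > 0")
        values = _values(u)
        ds = float(getattr(u, "step_duration", 1.0))
        n_sub = ds / self.dt
        if abs(n_sub - round(n_sub)) > 1e-9:
            raise ValueError("step duration must be an integer multiple of dt")
        n_sub = int(round(n_sub))
        T = values.size
        x = np.zeros(self.n_osc) if x0 is None else np.array(x0, dtype=float)
        v = np.zeros(self.n_osc) if v0 is None else np.array(v0, dtype=float)
        X = np.empty((T, self.n_osc))
        Vel = np.empty((T, self.n_osc)) if return_velocities else None
        dt = self.dt
        damp = dt / (2.0 * self.tau)
        for k in range(T):
            a_field = self.a_max * values[k]
            # overflow in a diverging trajectory is caught by the finite check
            with np.errstate(over="ignore", invalid="ignore"):
                for _ in range(n_sub):
                    acc = self._spring_force(x) - v / self.tau - a_field
                    x = x + v * dt + 0.5 * acc * dt * dt
                    # semi-implicit velocity update: damping evaluated at both ends
                    acc_new_nodamp = self._spring_force(x) - a_field
                    v = (v + 0.5 * dt * (acc + acc_new_nodamp)) / (1.0 + damp)
            if not np.all(np.isfinite(x)) or np.max(np.abs(x)) > self.divergence_limit:
                raise FloatingPointError(
                    f"FPUT trajectory diverged at step {k} (|x| > {self.divergence_limit:g}); "
                    "reduce a_max or dt"
                )
            X[k] = x
            if return_velocities:
                Vel[k] = v
        return (X, Vel) if return_velocities else X

    def energy(self, x: np.ndarray, v: np.ndarray) -> float:
        """Total mechanical energy (kinetic + quadratic/cubic spring potential)."""
        xp = np.concatenate(([0.0], np.asarray(x), [0.0]))
        d = np.diff(xp)
        return float(0.5 * np.sum(np.asarray(v) ** 2) + np.sum(0.5 * d**2 + self.alpha * d**3 / 3.0))


# ---------------------------------------------------------------------------
# balanced random LIF network
# ---------------------------------------------------------------------------


@dataclass
class BRNResult:
    """States plus diagnostics from a balanced-random-network run."""

    states: np.ndarray            # (T, N_exc) excitatory membrane potentials at step ends
    n_spikes: int
    mean_rate: float              # spikes/s per neuron (times in ms)


class BalancedRandomNetwork(BaseEstimator):
    """Balanced random network of leaky integrate-and-fire neurons.

    N_exc excitatory and N_inh inhibitory neurons with delta synapses,

        tau_m dV/dt = -(V - E_L) + (tau_m / C_m) I(t),

    fixed in-degrees C_exc/C_inh, inhibitory weight w_inh = -g * w_exc, a
    synaptic delay d, threshold/reset with refractory clamp, membrane
    potentials initialized uniformly in [V_min, V_max].  Every neuron
    receives one background Poisson train at rate nu_noise through weight
    w_exc (frozen: the same one-step pattern repeated each input step;
    changing: fresh spikes each step).  Times in ms, potentials in mV,
    currents in pA, capacitance in pF; w_exc is a synaptic charge in pA*ms
    so one spike jumps the potential by w_exc / C_m.

    Readout: membrane potentials of all excitatory neurons at the end of
    each input step (refractory neurons report V_reset).
    """

    def __init__(
        self,
        n_exc: int = 1000,
        n_inh: int = 250,
        c_exc: int = 100,
        c_inh: int = 25,
        g: float = 5.0,
        w_exc: float = 25.0,      # pA*ms -> 0.1 mV jump at C_m = 250 pF
        delay: float = 1.5,       # ms
        tau_m: float = 20.0,      # ms
        c_m: float = 250.0,       # pF
        e_l: float = 0.0,         # mV
        v_th: float = 20.0,       # mV
        v_reset: float = 10.0,    # mV
        tau_ref: float = 2.0,     # ms
        v_min: float = 0.0,       # mV
        v_max: float = 20.0,      # mV
        nu_noise: float = 12.0,   # background spikes per ms (pooled external drive)
        noise_kind: str = "frozen",
        dt: float = 0.1,          # ms
        seed: int = 0,
    ):
        self.n_exc = n_exc
        self.n_inh = n_inh
        self.c_exc = c_exc
        self.c_inh = c_inh
        self.g = g
        self.w_exc = w_exc
        self.delay = delay
        self.tau_m = tau_m
        self.c_m = c_m
        self.e_l = e_l
        self.v_th = v_th
        self.v_reset = v_reset
        self.tau_ref = tau_ref
        self.v_min = v_min
        self.v_max = v_max
        self.nu_noise = nu_noise
        self.noise_kind = noise_kind
        self.dt = dt
        self.seed = seed

    # -- wiring -------------------------------------------------------------

    def _build(self):
        rng = rng_for(self.seed, "weights")
        N = self.n_exc + self.n_inh
        jump_exc = self.w_exc / self.c_m           # mV per presynaptic spike
        jump_inh = -self.g * jump_exc
        pre_exc = np.empty((N, self.c_exc), dtype=np.int64)
        pre_inh = np.empty((N, self.c_inh), dtype=np.int64)
        for i in range(N):
            pre_exc[i] = rng.choice(self.n_exc, size=self.c_exc, replace=False)
            pre_inh[i] = self.n_exc + rng.choice(self.n_inh, size=self.c_inh, replace=False)
        # invert to outgoing adjacency for fast spike propagation
        targets: list[list[int]] = [[] for _ in range(N)]
        weights: list[list[float]] = [[] for _ in range(N)]
        for post in range(N):
            for pre in pre_exc[post]:
                targets[pre].append(post)
                weights[pre].append(jump_exc)
            for pre in pre_inh[post]:
                targets[pre].append(post)
                weights[pre].append(jump_inh)
        self.pre_exc_, self.pre_inh_ = pre_exc, pre_inh
        self.targets_ = [np.asarray(t, dtype=np.int64) for t in targets]
        self.weights_ = [np.asarray(w) for w in weights]
        self.jump_exc_ = jump_exc
        return self

    def in_degrees(self) -> tuple[np.ndarray, np.ndarray]:
        """Afferent (excitatory, inhibitory) counts per neuron; fixed by design."""
        if not hasattr(self, "pre_exc_"):
            self._build()
        N = self.n_exc + self.n_inh
        return (np.full(N, self.c_exc), np.full(N, self.c_inh))

    # -- simulation ---------------------------------------------------------

    def run(self, drive: EncoderOutput | None, T: int | None = None,
            delta_s: float | None = None, record_spikes: bool = False):
        """Simulate T input steps of length delta_s (ms) and return a BRNResult.

        ``drive`` supplies the per-step per-unit input: DC drive is added to
        the synaptic current of its target excitatory units; Poisson-rate
        drive (rates in spikes/s) is converted to spike jumps through w_exc.
        ``drive=None`` runs the network on background noise alone.
        """
        if drive is not None:
            T = drive.T
            delta_s = drive.step_duration
        if T is None or delta_s is None:
            raise ValueError("need T and delta_s when no drive is given")
        dt = self.dt
        n_sub = delta_s / dt
        if abs(n_sub - round(n_sub)) > 1e-9:
            raise ValueError("delta_s must be an integer multiple of dt")
        n_sub = int(round(n_sub))
        if not hasattr(self, "targets_"):
            self._build()

        N = self.n_exc + self.n_inh
        rng_init = rng_for(self.seed, "init")
        rng_noise = rng_for(self.seed, "noise")
        rng_drive = rng_for(self.seed, "poisson-input")

        V = rng_init.uniform(self.v_min, self.v_max, size=N)
        refr = np.zeros(N, dtype=np.int64)           # remaining refractory substeps
        ref_steps = int(round(self.tau_ref / dt))
        delay_steps = max(int(round(self.delay / dt)), 1)
        ring = np.zeros((delay_steps, N))            # delayed synaptic jumps (mV)

        decay = np.exp(-dt / self.tau_m)
        # DC current I (pA) shifts the steady state by tau_m/c_m * I (mV)
        dc_gain = (self.tau_m / self.c_m) * (1.0 - decay)

        drive_dc = None
        drive_rates = None
        drive_ids = None
        if drive is not None:
            drive_ids = np.asarray(drive.input_unit_ids, dtype=np.int64)  # excitatory indices
            if drive.modality == "dc":
                drive_dc = drive.drive
            elif drive.modality == "poisson_rate":
                if np.any(drive.drive < 0):
                    raise ValueError("Poisson-rate drive must be non-negative")
                drive_rates = drive.drive * 1e-3      # spikes/s -> spikes/ms
            else:
                raise ValueError(f"unknown drive modality {drive.modality!r}")

        if self.noise_kind not in ("frozen", "changing", "none"):
            raise ValueError("noise_kind must be frozen|changing|none")
        frozen_counts = None
        if self.noise_kind == "frozen" and self.nu_noise > 0:
            frozen_counts = rng_noise.poisson(self.nu_noise * dt, size=(n_sub, N))

        states = np.empty((T, self.n_exc))
        spikes_out: list[tuple[float, int]] = []
        total_spikes = 0
        e_l = self.e_l
        ptr = 0
        for k in range(T):
            if self.noise_kind == "changing" and self.nu_noise > 0:
                noise_counts = rng_noise.poisson(self.nu_noise * dt, size=(n_sub, N))
            else:
                noise_counts = frozen_counts
            step_rates = None
            if drive_rates is not None:
                step_rates = drive_rates[k]
            for s in range(n_sub):
                # membrane decay toward E_L plus DC steady-state shift
                V = e_l + (V - e_l) * decay
                if drive_dc is not None:
                    V[drive_ids] += dc_gain * drive_dc[k]
                # delayed recurrent + immediate external jumps
                V += ring[ptr]
                ring[ptr] = 0.0
                if noise_counts is not None:
                    V += self.jump_exc_ * noise_counts[s]
                if step_rates is not None:
                    counts = rng_drive.poisson(step_rates * dt)
                    np.add.at(V, drive_ids, self.jump_exc_ * counts)
                # refractory clamp
                active = refr > 0
                V[active] = self.v_reset
                refr[active] -= 1
                # threshold crossings (ties fire)
                sp = np.nonzero((V >= self.v_th) & ~active)[0]
                if sp.size:
                    total_spikes += sp.size
                    V[sp] = self.v_reset
                    refr[sp] = ref_steps
                    # ring[ptr] was already read and zeroed this substep, so a
                    # write here is next read exactly delay_steps substeps later
                    slot = ptr
                    for idx in sp:
                        tgt = self.targets_[idx]
                        if tgt.size:
                            np.add.at(ring[slot], tgt, self.weights_[idx])
                    if record_spikes:
                        t_now = (k * n_sub + s + 1) * dt
                        spikes_out.extend((t_now, int(idx)) for idx in sp)
                ptr = (ptr + 1) % delay_steps
            states[k] = V[: self.n_exc]
        if total_spikes == 0:
            warnings.warn("silent network: no spikes over the whole run", stacklevel=2)
        duration_ms = T * delta_s
        rate = total_spikes / N / (duration_ms * 1e-3) if duration_ms > 0 else 0.0
        result = BRNResult(states=states, n_spikes=total_spikes, mean_rate=rate)
        if record_spikes:
            result.spikes = np.asarray(spikes_out)  # type: ignore[attr-defined]
        return result


# ---------------------------------------------------------------------------
# oracle systems
# ---------------------------------------------------------------------------


def delay_line_states(n_taps: int, u) -> np.ndarray:
    """Pure delay line: column i holds u(k - i), zeros before the start.

    Its capacity is exactly 1 for each degree-1 target at delays
    0..n_taps-1 and 0 elsewhere, which makes it the standard oracle for the
    capacity estimator.
    """
    values = _values(u)
    T = values.size
    X = np.zeros((T, n_taps))
    for i in range(n_taps):
        X[i:, i] = values[: T - i]
    return X
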