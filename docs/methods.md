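# Methods

This note documents the models, the estimation procedure, the defaults and
the numerical choices behind `ipcap`, and what the test suite does and does
not establish.

## Capacity estimation

**Model.** The system under study is driven by a scalar sequence
u(k) drawn i.i.d. from U(−1, 1) (continuous-time systems see the piecewise
constant extension u(t) = u(k) for (k−1)Δs ≤ t < kΔs). Its states are
collected into a T×N matrix X, one row per input step, sampled at the step
end. A target function is a product of Legendre polynomials of delayed
inputs, identified by its degree tuple D = (d₀, …, d_m) with d_m > 0. Under
the uniform input the targets form an orthogonal family, so the per-target
squared correlations between the target and its least-squares
reconstruction from X sum to at most N. The capacity profile — mass by
total degree and by maximum delay — is the object of interest: degree
measures nonlinearity, delay measures memory, and their trade-off is the
central phenomenon the metric exposes.

**Computation.** Columns of X are mean-centered (the covariance form of the
score is translation invariant and centering stabilizes the pseudoinverse)
and an orthonormal basis Q of the column space is obtained by a
rank-revealing SVD; rank deficiency is tolerated with a warning, since the
score depends only on the column space. Each target y is centered and its
capacity computed as ‖Qᵀy‖²/‖y‖², which equals the squared correlation with
the least-squares reconstruction. Targets are evaluated in batches against
cached Legendre transforms of the input, so one target costs a single
N-dimensional projection.

**Washout.** The first W steps are excluded from all regressions so every
explored target has a fully defined history (no zero padding). Default
W = min(max_delay, T/5); the effective sample size T−W is what enters the
cutoff. The maximum explorable delay is bounded by W.

**Chance level and cutoff.** In-sample capacities of irrelevant targets are
chi-squared distributed with mean ≈ N/T. The cutoff is
c = factor · χ²₍N₎(upper tail_p quantile) / (T−W) with factor = 6 and
tail_p = 10⁻⁴; capacities below c are zeroed, and totals, maximum degree
and maximum delay are computed over surviving records only. The safety
factor absorbs the unknown dependence corrections for correlated state
variables. Only the upper tail quantile filters chance capacity; the
literal lower-quantile reading is available via `tail="lower"` for
comparison but is near zero and filters nothing. Calibration is part of
the test suite: on a pure-noise state matrix (N = 50, T = 10⁵) none of
1000 random targets survives the cutoff.

**Exploration.** The target space is infinite, so exploration assumes
capacity decays with complexity. Degree-1 targets (pure delays) are scanned
delay by delay until `delay_stall` (default 3) consecutive below-cutoff
results. For each total degree ≥ 2, all canonical tuples with a given
maximum delay form one block; blocks are scanned by increasing delay with
the same stall rule, and degree growth stops after `degree_stall`
consecutive degree levels without any above-cutoff capacity. The default
`degree_stall = 2` is deliberate: systems with a parity symmetry (a tanh
network driven by a symmetric input has exactly zero even-degree capacity)
would otherwise terminate at degree 2 and miss all higher odd degrees.
Hard caps (degree 20, delay 200, optional factor-count cap) bound the
worst case and are recorded in the table metadata. Capacities are computed
in-sample on the full record — the chance-level cutoff exists precisely to
correct in-sample bias — so no train/test split is used for the metric.

## Encoders

* **Amplitude-value**: a(k) = (u(k)+1)/2 · a_max to every input unit. An
  affine bijection of the input — linear, memoryless, the reference encoder
  that leaves the capacity estimate undistorted.
* **Distributed-value**: a(k)·w_j with w_j ~ U(−1, 1) drawn once per run.
* **Spatial-value**: unit j receives a_max · exp(−(j−μ(k))²/(2σ²)) with
  μ(k) = (u(k)+1)/2 · N_inp, no periodic wrap-around, so the two input
  extremes excite opposite ends of the population. The printed source form
  of this profile mixes a normal-density prefactor with a linear term and
  is dimensionally inconsistent; the unnormalized Gaussian with peak a_max
  matches the intended bump picture and the requirement that u = ±1 stay
  distinguishable, and σ keeps its meaning as spatial spread. The profile
  depends only on the current input value: this encoder is nonlinear but
  has no memory.

Delivery is either direct current (amplitudes in pA; negative
distributed-scheme amplitudes are delivered as-is, hyperpolarizing) or
inhomogeneous Poisson rates (amplitudes in spikes/s; negative rates are
clipped to zero, since rates cannot be negative). Background noise for
spiking networks is per-neuron Poisson at ν_noise, either *changing*
(fresh each step) or *frozen* (a single pattern of length Δs repeated
every step, which makes the background deterministic across steps and is
expected to preserve more capacity).

Multidimensional binary task inputs are split into streams: distributed —
each stream has its own weight matrix and contributes a_max when active;
spatial — stream i of n places its bump at (i+1)·N_inp/(n+1), evenly
spaced; simultaneously active streams add. Additivity is a design choice;
it makes multi-stream encoding the linear superposition of the
single-stream encodings.

## Reference systems

**Echo state network** (N = 50 default): x(k+1) = tanh(ρWx(k) + ιVu(k)).
W is the QR orthogonalization of a U(−1,1) matrix (sign-fixed for
determinism) rescaled to unit spectral radius before ρ applies; V ~
U(−1,1). All units receive the input; states are exact, so runs are
bit-reproducible.

**α-FPUT chain** (64 oscillators, α = 0.25, τ = 10 default): fixed-end
boundary conditions (the classical setting; the source is silent on this),
field drive a(t) = a_max·u(t) coupled equally to all oscillators — the
mean-zero mapping, since the field couples with zero temporal mean.
Integration is velocity Verlet with the damping handled semi-implicitly,
dt = 0.1 time units by default; Δs must be an integer multiple of dt.
Convergence is checked by dt-halving, and the α = 0 chain is verified
against the exact matrix-exponential propagator of the damped linear
system. Readout: positions at step ends (velocities are available but not
part of the default state matrix).

**Balanced random network** (1000 excitatory + 250 inhibitory LIF default):
exact exponential propagation of the membrane equation on a dt = 0.1 ms
grid, delta synapses as voltage jumps w/C_m delivered after the synaptic
delay through a ring buffer, fixed in-degrees C_exc/C_inh, w_inh = −g·w_exc,
threshold ties fire (V ≥ V_th), refractory neurons are clamped to V_reset
and report V_reset in the state matrix. The neuron and wiring defaults are
classical balanced-network values (τ_m = 20 ms, V_th = 20 mV over a 0 mV
rest, V_reset = 10 mV, τ_ref = 2 ms, d = 1.5 ms, g = 5, C_exc = 100,
C_inh = 25, C_m = 250 pF, w_exc = 25 pA·ms → 0.1 mV jumps), every one
overridable. The pooled background train default is ν_noise = 12 spikes/ms,
placing the mean drive slightly above threshold. Readout: excitatory
membrane potentials at step ends.

**Delay line**: x_i(k) = u(k−i+1). Its capacity table is known exactly
(capacity 1 per delay up to its length, nothing else), making it the
estimator's primary oracle.

## Encoder subtraction

The encoder's own capacity is estimated by using its drive matrix as the
state matrix. The system's effective linear memory at delay i ≥ 1 is the
combined degree-1 capacity minus the encoder degree-1 capacity, floored at
zero; divided by the encoder's delay-0 linear capacity it gives the
retention fraction f(i) ∈ [0, 1]. At i = 0 the difference is zero by
construction for any system that sees the drive, so f(0) = 0.

The full-subtraction lower bound then removes from the combined table:
(1) every record whose tuple equals an above-cutoff encoder tuple (the
system may simply relay the encoder at zero shift), and (2) for encoder
targets beyond the pure input target D = (1,), their i-step-shifted
versions for every i ≥ 1 with f(i) > 0. The pure input target is exempt
from shifting: remembering the raw input *is* the system's own linear
memory, already attributed by the differencing, and removing its shifts
would wipe legitimate memory even behind a perfectly linear encoder. With
an affine memoryless encoder the correction therefore reduces to dropping
the single delay-0 linear record; behind a nonlinear encoder a pure relay
system is reduced to zero. This is a conservative bound — any capacity
that could *partly* stem from remembered encoder output is removed
entirely. An exact per-target attribution would need additional
information gathered during reconstruction; the API reserves a strategy
switch for such a mode, which is out of scope here.

## Tasks

Linear least-squares readouts on the state matrix, trained on a contiguous
80% split after a 100-step washout and scored on the held-out 20%. Binary
tasks threshold at 0.5 and report Cohen's kappa; NARMA5 reports the squared
Pearson correlation; delayed classification fits ten one-vs-all readouts
per delay, classifies by argmax, and reports the largest delay whose
held-out accuracy beats chance (one-sided binomial test against p = 0.1 at
α = 0.01), scanning stopping at the first failure. Task input length
defaults to T = 20,000. The NARMA5 input is mapped to [0, 0.5] — the
standard stability range for this recurrence — and the recurrence treats
history before t = 0 as zero. For the ESN, binary streams enter through
per-stream U(−1,1) weight columns with active value 1 and inactive 0,
scaled by the input gain.

Two protocol details deserve emphasis. Task scores (especially nested XOR)
vary noticeably across weight/input initialisations, so scan points
average them over five trials, mirroring the multi-trial averaging used in
this literature; capacity statistics are single-trial, their trial
variance being negligible by comparison. And the measured maximum
classification delay is highly sensitive to the operational "above chance"
criterion: near the memory limit the accuracy curve decays very flatly
(e.g. 0.134 at delay 26 vs 0.112 at delay 35, chance 0.1), so small
changes in test-set size or significance level move the reported maximum
by many steps. The binomial criterion above is the package's fixed,
documented choice.

## Scans

Grids are config-driven; every run's parameters and seed are logged in the
result row, each grid point derives its seed from the root seed and the
point index (serial and parallel execution agree), and individual failures
are recorded without aborting the scan. The bundled ESN reference scan
uses ι ∈ {2⁻⁸, 2⁻⁶, 2⁻⁴, 2⁻², 1, 2.5} at ρ = 0.9: log-2 spacing from the
effectively linear regime (capacity statistics become gain-invariant as
ι → 0, so lower values add nothing) up to the strongly saturated regime
where the maximum capacity degree reaches 11. Problem sizes in the test
suite: the ESN runs at full scale (T = 10⁵); the spiking network and the
oscillator chain run scaled down (100 excitatory neurons at T = 5000;
T = 4000 chain steps) — at these sizes the qualitative effects (frozen
noise preserving more capacity than changing noise; longer steps trading
memory for nonlinearity) are stable, while full-scale runs belong on a
cluster, not in a test suite.

## Seeding

A single root seed fans out into named substreams (input, weights, noise,
encoder units, Poisson drive, initial potentials) via hashed
`SeedSequence` spawn keys, so frozen noise, input randomisation and wiring
are independently controllable and every run is bit-reproducible.

## What the synthetic setting does and does not show

All inputs are synthetic i.i.d. uniform sequences — that is what the
metric's orthogonality requires, and the package deliberately supports
nothing else. Passing tests therefore certify the estimator, the encoders,
the simulators and their interplay under the metric's own assumptions;
they do not certify behaviour under autocorrelated or structured natural
inputs, non-uniform input distributions (the Legendre family would no
longer be orthogonal), or spike-timing codes beyond rate/DC delivery.
The balanced network here uses classical parameter values rather than a
fitted biological configuration, and the encoder correction yields a lower
bound, not an exact attribution: a corrected capacity of zero does not
prove the system computes nothing of its own.

## Known limitations

* Exploration cost grows combinatorially with simultaneous high degree and
  long delay; the stall rules keep realistic systems tractable, but
  adversarial profiles (large capacity at high degree *and* long delay)
  can be expensive. `max_factors` bounds the worst case at the price of
  missing many-factor products.
* The estimator is single-input, as is the metric's standard formulation;
  multidimensional inputs appear only in the task suite.
* Membrane potentials are read at step ends only; refractory neurons
  report the reset potential, discarding within-refractory structure.
* Capacities are in-sample with a cutoff correction, not cross-validated;
  at very small T/N the ×6 safety factor is the only guard against
  dependence-induced bias, and totals near the readout bound should be
  read with the cutoff in mind.
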