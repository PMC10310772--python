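import numpy as np
import pytest
from scipy.linalg import expm

import ipcap
from ipcap.encoders import AmplitudeEncoder
from ipcap.signals import StepSignal, make_step_signal
from ipcap.systems import BalancedRandomNetwork, EchoStateNetwork, FPUTChain, delay_line_states


def signal(values, ds=1.0):
    return StepSignal(values=np.asarray(values, dtype=float), step_duration=ds)


class TestESN:
    def test_zero_input_gain_keeps_states_at_zero(self):
        u = make_step_signal(100, 1.0, seed=1)
        X = EchoStateNetwork(n_units=20, rho=0.9, iota=0.0, seed=1).run(u)
        np.testing.assert_array_equal(X, 0.0)

    def test_recurrent_matrix_has_unit_spectral_radius(self):
        esn = EchoStateNetwork(n_units=50, seed=3)
        esn._build()
        radius = np.max(np.abs(np.linalg.eigvals(esn.W_)))
        assert radius == pytest.approx(1.0, abs=1e-9)

    def test_zero_feedback_is_memoryless(self):
        u = make_step_signal(20_000, 1.0, seed=5)
        esn = EchoStateNetwork(n_units=20, rho=0.0, iota=1.0, seed=5)
        X = esn.run(u)
        # closed form: x(k+1) = tanh(iota * v * u(k))
        expected = np.tanh(esn.iota * esn.V_[:, 0][None, :] * u.values[:, None])
        np.testing.assert_allclose(X, expected, atol=1e-12)
        est = ipcap.CapacityEstimator()
        # all memory must sit at delay 0 (capacities at delay >= 1 below cutoff)
        est.fit(X, u)
        assert est.max_delay_ == 0
        assert est.total_capacity_ > 0.9

    def test_states_bounded_and_deterministic(self):
        u = make_step_signal(500, 1.0, seed=7)
        a = EchoStateNetwork(n_units=30, rho=0.95, iota=1.0, seed=7).run(u)
        b = EchoStateNetwork(n_units=30, rho=0.95, iota=1.0, seed=7).run(u)
        np.testing.assert_array_equal(a, b)
        assert np.max(np.abs(a)) < 1.0


class TestFPUT:
    def test_rest_is_a_fixed_point(self):
        u = signal([0.0] * 20, ds=5.0)
        chain = FPUTChain(n_osc=16, a_max=0.1)
        X = chain.run(u)
        np.testing.assert_array_equal(X, 0.0)

    def test_energy_decays_without_drive(self):
        chain = FPUTChain(n_osc=16, alpha=0.25, tau=10.0, dt=0.05, a_max=0.0)
        rng = np.random.default_rng(0)
        x0 = 0.1 * rng.normal(size=16)
        v0 = 0.1 * rng.normal(size=16)
        u = signal([0.0] * 40, ds=5.0)
        X, V = chain.run(u, x0=x0, v0=v0, return_velocities=True)
        energies = [chain.energy(X[k], V[k]) for k in range(len(X))]
        assert energies[0] < chain.energy(x0, v0)
        diffs = np.diff(energies)
        assert np.all(diffs <= 1e-10)

    def test_linear_chain_matches_exact_propagator(self):
        # alpha = 0 is a damped driven linear system solvable with expm
        n, tau, ds, a_max = 8, 10.0, 2.0, 0.05
        u = make_step_signal(30, ds, seed=9)
        chain = FPUTChain(n_osc=n, alpha=0.0, tau=tau, dt=0.005, a_max=a_max)
        X = chain.run(u)

        K = -2.0 * np.eye(n) + np.diag(np.ones(n - 1), 1) + np.diag(np.ones(n - 1), -1)
        A = np.block([[np.zeros((n, n)), np.eye(n)], [K, -np.eye(n) / tau]])
        E = expm(A * ds)
        z = np.zeros(2 * n)
        ref = np.empty((30, n))
        for k in range(30):
            b = np.concatenate([np.zeros(n), -a_max * u.values[k] * np.ones(n)])
            z = E @ z + np.linalg.solve(A, (E - np.eye(2 * n)) @ b)
            ref[k] = z[:n]
        scale = np.max(np.abs(ref))
        assert np.max(np.abs(X - ref)) < 1e-3 * scale

    def test_integrator_converges_under_dt_halving(self):
        u = make_step_signal(20, 2.0, seed=11)
        runs = {}
        for dt in (0.2, 0.1, 0.05):
            runs[dt] = FPUTChain(n_osc=12, alpha=0.25, dt=dt, a_max=0.05).run(u)
        err_coarse = np.max(np.abs(runs[0.2] - runs[0.05]))
        err_fine = np.max(np.abs(runs[0.1] - runs[0.05]))
        assert err_fine < err_coarse
        assert err_fine < 1e-3

    def test_divergence_raises(self):
        u = signal([1.0] * 200, ds=10.0)
        chain = FPUTChain(n_osc=8, alpha=5.0, tau=1e6, dt=0.5, a_max=50.0,
                          divergence_limit=1e3)
        with pytest.raises(FloatingPointError):
            chain.run(u)

    def test_step_duration_must_align_with_dt(self):
        with pytest.raises(ValueError):
            FPUTChain(dt=0.3).run(signal([0.0], ds=1.0))


class TestBRN:
    def quiet(self, **kw):
        base = dict(n_exc=2, n_inh=1, c_exc=1, c_inh=1, nu_noise=0.0,
                    noise_kind="none", v_min=5.0, v_max=5.0, seed=13)
        base.update(kw)
        return BalancedRandomNetwork(**base)

    def test_subthreshold_exponential_decay(self):
        brn = self.quiet()
        with pytest.warns(UserWarning, match="silent"):
            res = brn.run(None, T=10, delta_s=1.0)
        k = np.arange(1, 11)
        expected = 5.0 * np.exp(-k * 1.0 / brn.tau_m)
        np.testing.assert_allclose(res.states[:, 0], expected, atol=1e-9)
        assert res.n_spikes == 0

    def test_dc_drive_steady_state(self):
        brn = self.quiet(v_min=0.0, v_max=0.0)
        I = 100.0  # pA -> steady state tau_m/C_m * I = 8 mV, subthreshold
        drive = AmplitudeEncoder(a_max=2 * I, n_units=2).transform(
            signal([0.0] * 300, ds=1.0)
        )
        with pytest.warns(UserWarning, match="silent"):
            res = brn.run(drive)
        target = brn.e_l + brn.tau_m / brn.c_m * I
        np.testing.assert_allclose(res.states[-1], target, atol=1e-5)

    def test_delta_synapse_jump_size_and_delay(self):
        # drive one excitatory neuron over threshold with DC; with the
        # refractory period shorter than the synaptic delay, the self-spike
        # arrives as a discrete jump of exactly w_exc / C_m after `delay`
        common = dict(n_exc=1, n_inh=1, c_exc=1, c_inh=1, nu_noise=0.0,
                      noise_kind="none", v_min=0.0, v_max=0.0, tau_ref=0.5,
                      delay=1.5, seed=17)
        I = 375.0  # steady state 30 mV > threshold -> periodic firing
        u = signal([0.0] * 400, ds=0.1)  # sample every grid point

        def run(w):
            brn = BalancedRandomNetwork(w_exc=w, **common)
            drive = AmplitudeEncoder(a_max=2 * I, n_units=1).transform(u)
            return brn.run(drive, record_spikes=True)

        with_syn = run(25.0)
        no_syn = run(1e-12)
        dv = with_syn.states[:, 0] - no_syn.states[:, 0]
        first = np.argmax(np.abs(dv) > 1e-9)
        t_jump = (first + 1) * 0.1
        t_spike = with_syn.spikes[0, 0]
        assert t_jump - t_spike == pytest.approx(1.5, abs=0.051)
        assert dv[first] == pytest.approx(25.0 / 250.0, abs=1e-9)

    def test_fixed_in_degrees(self):
        brn = BalancedRandomNetwork(n_exc=40, n_inh=10, c_exc=8, c_inh=3, seed=19)
        brn._build()
        assert brn.pre_exc_.shape == (50, 8)
        assert brn.pre_inh_.shape == (50, 3)
        for row in brn.pre_exc_:
            assert np.unique(row).size == 8
            assert row.max() < 40
        for row in brn.pre_inh_:
            assert np.unique(row).size == 3
            assert row.min() >= 40
        exc_deg, inh_deg = brn.in_degrees()
        assert np.all(exc_deg == 8) and np.all(inh_deg == 3)

    def test_same_seed_is_bit_identical(self):
        u = make_step_signal(50, 10.0, seed=21)
        kw = dict(n_exc=30, n_inh=8, c_exc=5, c_inh=2, nu_noise=8.0,
                  noise_kind="frozen", seed=21)
        enc = AmplitudeEncoder(a_max=80.0, n_units=30)
        r1 = BalancedRandomNetwork(**kw).run(enc.transform(u))
        r2 = BalancedRandomNetwork(**kw).run(enc.transform(u))
        np.testing.assert_array_equal(r1.states, r2.states)

    def test_poisson_rate_drive_runs(self):
        u = make_step_signal(40, 10.0, seed=23)
        enc = AmplitudeEncoder(a_max=500.0, n_units=30, modality="poisson_rate")
        brn = BalancedRandomNetwork(n_exc=30, n_inh=8, c_exc=5, c_inh=2,
                                    nu_noise=8.0, noise_kind="changing", seed=23)
        res = brn.run(enc.transform(u))
        assert res.states.shape == (40, 30)
        assert np.all(np.isfinite(res.states))


class TestDelayLine:
    def test_row_contents(self):
        X = delay_line_states(3, signal([0.5, -0.2, 0.9]))
        np.testing.assert_allclose(X[2], [0.9, -0.2, 0.5])

    def test_degree_two_targets_below_cutoff(self):
        u = make_step_signal(30_000, 1.0, seed=25)
        table = ipcap.explore_capacities(delay_line_states(4, u), u)
        deg2 = table.records[table.records["degree"] == 2]
        assert len(deg2) > 0
        assert not deg2["above_cutoff"].any()
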