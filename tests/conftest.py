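"""Shared fixtures.

The heavy simulations (the full-scale ESN input-gain scan, the scaled-down
spiking-network and oscillator-chain runs) are session-scoped so the
acceptance checks that share them pay for each run once.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import ipcap
from ipcap.scans import ScanSpec, run_scan

# Input-gain grid for the ESN reference scan (rho = 0.9, N = 50).  Log-2
# spaced from the linear regime up to the saturating regime; the upper edge
# is where the scan's endpoint statistics (maximum capacity degree, nested-
# XOR score) sit in the reference operating range.
ESN_IOTA_GRID = [2**-8, 2**-6, 2**-4, 2**-2, 1.0, 2.5]
ESN_SCAN_SEED = 1
ESN_T = 100_000


@pytest.fixture(scope="session")
def esn_scan():
    """Full-scale ESN capacity + task scan over the input gain."""
    spec = ScanSpec(
        system="esn",
        axes={"iota": ESN_IOTA_GRID},
        base={"rho": 0.9, "n_units": 50},
        T=ESN_T,
        trials=1,
        seed=ESN_SCAN_SEED,
        outputs=("capacity", "tasks"),
    )
    df = run_scan(spec)
    assert (df["error"] == "").all(), df["error"].tolist()
    return df


@pytest.fixture(scope="session")
def delay_line_run():
    """Delay line oracle (N = 10 taps) at full input length."""
    u = ipcap.make_step_signal(100_000, 1.0, seed=7)
    X = ipcap.delay_line_states(10, u)
    est = ipcap.CapacityEstimator()
    est.fit(X, u)
    return est


@pytest.fixture(scope="session")
def brn_noise_pair():
    """Scaled-down balanced random network under frozen vs changing noise."""
    out = {}
    u = ipcap.make_step_signal(5000, 10.0, seed=3)
    for kind in ("frozen", "changing"):
        brn = ipcap.BalancedRandomNetwork(
            n_exc=100, n_inh=25, c_exc=20, c_inh=5, nu_noise=12.0,
            noise_kind=kind, seed=3,
        )
        enc = ipcap.AmplitudeEncoder(a_max=100.0, n_units=100)
        res = brn.run(enc.transform(u))
        est = ipcap.CapacityEstimator(max_delay=40, washout=40)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(res.states, u)
        out[kind] = est
    return out


@pytest.fixture(scope="session")
def fput_step_pair():
    """Scaled-down FPUT chain at a short and a long step duration."""
    out = {}
    for ds in (2.0, 20.0):
        u = ipcap.make_step_signal(4000, ds, seed=4)
        X = ipcap.FPUTChain(a_max=0.033).run(u)
        est = ipcap.CapacityEstimator(max_delay=60, washout=60)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(X, u)
        out[ds] = est
    return out
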