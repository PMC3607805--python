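"""Shared fixtures.

The expensive session fixtures run the full 2000-neuron network: five
default trials (the scaled-down trial count used for pooled statistics),
one low-drive trial and one trial per alternative GABA decay constant.
Everything downstream (spectra, frontiers, classifications) is derived from
these shared results.
"""

from __future__ import annotations

import numpy as np
import pytest

from gammamodes import firing_modes as fm
from gammamodes import observables as obs
from gammamodes.network_sim import ExternalDriveParams, NetworkConfig, run_simulation
from gammamodes.neuron_model import NeuronParams, find_rheobase

DEFAULT_SEEDS = (1, 2, 3, 4, 5)


@pytest.fixture(scope="session")
def default_results():
    """Five 3 s trials of the default network (8500 spikes/s drive)."""
    cfg = NetworkConfig()
    return [run_simulation(cfg, seed=s) for s in DEFAULT_SEEDS]


@pytest.fixture(scope="session")
def default_result(default_results):
    return default_results[0]


@pytest.fixture(scope="session")
def low_drive_result():
    """One trial with the external mean rate lowered to 5000 spikes/s."""
    cfg = NetworkConfig().with_(drive=ExternalDriveParams(mean_rate=5000.0))
    return run_simulation(cfg, seed=7)


@pytest.fixture(scope="session")
def taud_results():
    """One default-drive trial per alternative GABA decay constant."""
    out = {}
    for j, tau_d in enumerate((2.5, 10.0, 30.0)):
        cfg = NetworkConfig().with_tau_d_gaba(tau_d)
        out[tau_d] = run_simulation(cfg, seed=11 + j)
    return out


@pytest.fixture(scope="session")
def pooled_exc_rates(default_results):
    return np.concatenate(
        [obs.instantaneous_rates(r, "exc") for r in default_results]
    )


@pytest.fixture(scope="session")
def default_frontier(pooled_exc_rates):
    return fm.find_mode_frontier(pooled_exc_rates, seed=0)


@pytest.fixture(scope="session")
def rheobase():
    """Rheobase currents of both presets (shared: bisection is expensive)."""
    return {
        "exc": find_rheobase(NeuronParams.excitatory(), tol=1e-3),
        "inh": find_rheobase(NeuronParams.inhibitory(), tol=1e-3),
    }
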