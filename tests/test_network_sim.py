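"""Network construction, external drive, synapses and the simulation loop."""

import numpy as np
import pytest
from scipy.stats import ks_2samp

from gammamodes import network_sim as ns
from gammamodes import observables as obs
from gammamodes.neuron_model import NeuronParams


class TestConnectivity:
    def test_mean_out_degree(self):
        rng = np.random.default_rng(0)
        g = ns.build_connectivity(2000, 0.8, 0.1, ns.DelayParams(), rng)
        mean_k = g.out_degree().mean()
        # binomial(1999, 0.1): population s.e. of the mean over 2000 neurons
        se = np.sqrt(199.9 * 0.9 / 2000)
        assert abs(mean_k - 199.9) < 4 * se

    def test_no_self_connections(self):
        rng = np.random.default_rng(1)
        g = ns.build_connectivity(300, 0.8, 0.2, ns.DelayParams(), rng)
        pre = np.repeat(np.arange(300), g.out_degree())
        assert np.all(pre != g.targets)

    def test_empty_graph_for_p_zero(self):
        g = ns.build_connectivity(100, 0.8, 0.0, ns.DelayParams(), np.random.default_rng(0))
        assert g.n_edges == 0

    def test_delay_moments(self):
        d = ns.DelayParams(mean=2.0, variance=4.0)
        assert d.shape == pytest.approx(1.0)
        assert d.scale == pytest.approx(2.0)
        s = d.sample(100000, np.random.default_rng(2))
        assert s.mean() == pytest.approx(2.0, abs=3 * 2.0 / np.sqrt(1e5))
        assert s.var() == pytest.approx(4.0, rel=0.05)
        assert np.all(s >= 0)

    def test_too_small_network_rejected(self):
        with pytest.raises(ValueError):
            ns.build_connectivity(1, 0.8, 0.1, ns.DelayParams(), np.random.default_rng(0))


class TestOURatePath:
    def test_zero_sigma_constant(self):
        p = ns.ExternalDriveParams(sigma=0.0)
        lam = ns.ou_rate_path(p, 1000.0, 0.05, np.random.default_rng(0))
        assert np.all(lam == p.mean_rate)

    def test_autocorrelation_time(self):
        # mean far above sigma so the zero-rate clipping never engages
        p = ns.ExternalDriveParams(mean_rate=1000.0, sigma=1.0)
        dt = 0.5
        lam = ns.ou_rate_path(p, 100_000.0, dt, np.random.default_rng(3))
        x = lam - lam.mean()
        # integrated autocorrelation up to 10 tau estimates tau itself
        n_lags = int(10 * p.tau_ou / dt)
        var = np.dot(x, x) / len(x)
        acf = np.array(
            [np.dot(x[:-k], x[k:]) / (len(x) - k) / var for k in range(1, n_lags)]
        )
        tau_est = dt * (0.5 + acf.sum())
        assert tau_est == pytest.approx(16.0, rel=0.2)

    def test_stationary_std_and_clipping(self):
        p = ns.ExternalDriveParams(mean_rate=100.0, sigma=40.0)
        lam = ns.ou_rate_path(p, 200_000.0, 0.5, np.random.default_rng(4))
        assert np.all(lam >= 0.0)
        # clipping is rare at mean/sigma = 2.5, std close to nominal
        assert np.std(lam) == pytest.approx(40.0, rel=0.15)

    def test_dt_must_resolve_tau(self):
        with pytest.raises(ValueError):
            ns.ou_rate_path(ns.ExternalDriveParams(), 100.0, 5.0, np.random.default_rng(0))

    def test_cutoff_frequency(self):
        assert ns.ExternalDriveParams().cutoff_hz == pytest.approx(9.9, abs=0.06)


class TestExternalSpikeTrains:
    def test_poisson_count(self):
        lam = np.full(20000, 8500.0)  # 1 s at dt = 0.05 ms
        trains = ns.external_spike_trains(lam, 0.05, 3, np.random.default_rng(5))
        for t in trains:
            assert abs(len(t) - 8500) < 3 * np.sqrt(8500)

    def test_zero_rate_no_events(self):
        trains = ns.external_spike_trains(np.zeros(1000), 0.05, 2, np.random.default_rng(0))
        assert all(len(t) == 0 for t in trains)

    def test_independent_realizations_share_rate(self):
        lam = np.full(20000, 3000.0)
        t1, t2 = ns.external_spike_trains(lam, 0.05, 2, np.random.default_rng(6))
        assert not np.array_equal(t1, t2)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            ns.external_spike_trains(np.array([-1.0]), 0.05, 1, np.random.default_rng(0))


class TestSynapses:
    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            ns.SynapseParams(2.0, 2.0, 0.0, 1.0, "AMPA")

    def test_single_event_peak_time(self):
        syn = ns.SynapseParams.ampa_recurrent()
        t_star = syn.peak_time
        assert t_star == pytest.approx(0.924, abs=1e-3)
        t = np.linspace(0, 10, 10001)
        k = syn.kernel(t)
        assert t[np.argmax(k)] == pytest.approx(t_star, abs=2e-3)

    def test_reversal_zero_current(self):
        syn = ns.SynapseParams.gaba()
        st = ns.SynapseState(syn)
        st.deliver(1.0)
        assert ns.synaptic_current(st, syn.e_syn) == pytest.approx(0.0)

    def test_superposition(self):
        syn = ns.SynapseParams.ampa_recurrent()
        one, two = ns.SynapseState(syn), ns.SynapseState(syn)
        one.deliver(1.0)
        two.deliver(2.0)
        for _ in range(40):
            one.decay(0.05)
            two.decay(0.05)
        assert two.g == pytest.approx(2.0 * one.g, rel=1e-12)

    def test_event_driven_update_matches_closed_form(self):
        syn = ns.SynapseParams.gaba()
        st = ns.SynapseState(syn)
        st.deliver(1.0)
        dt = 0.05
        for k in range(1, 400):
            st.decay(dt)
            expected = syn.kernel(k * dt)
            assert st.g == pytest.approx(float(expected), rel=1e-10)
        assert st.g >= 0


class TestPSPAmplitude:
    def test_zero_conductance_zero_psp(self):
        syn = ns.SynapseParams(0.5, 2.0, 0.0, 0.0, "AMPA")
        assert ns.psp_amplitude(NeuronParams.excitatory(), syn) == pytest.approx(0.0, abs=1e-9)

    def test_monotone_in_conductance(self):
        peaks = [
            ns.psp_amplitude(
                NeuronParams.excitatory(), ns.SynapseParams(0.5, 2.0, 0.0, g, "AMPA")
            )
            for g in (1.0, 2.5, 5.0)
        ]
        assert peaks[0] < peaks[1] < peaks[2]


class TestRunSimulation:
    def test_silent_without_input(self):
        cfg = ns.NetworkConfig(
            n_neurons=40,
            duration=200.0,
            drive=ns.ExternalDriveParams(mean_rate=0.0, sigma=0.0),
        )
        res = ns.run_simulation(cfg, seed=0)
        assert len(res.spike_times) == 0

    def test_deterministic_given_seed(self):
        cfg = ns.NetworkConfig(n_neurons=80, duration=300.0)
        a = ns.run_simulation(cfg, seed=3)
        b = ns.run_simulation(cfg, seed=3)
        assert np.array_equal(a.spike_times, b.spike_times)
        assert np.array_equal(a.spike_neurons, b.spike_neurons)
        assert np.array_equal(a.i_input, b.i_input)
        c = ns.run_simulation(cfg, seed=4)
        assert not np.array_equal(a.spike_times, c.spike_times)

    def test_spike_times_within_duration(self):
        cfg = ns.NetworkConfig(n_neurons=80, duration=300.0)
        res = ns.run_simulation(cfg, seed=3)
        assert len(res.spike_times) > 0
        assert res.spike_times.min() >= 0
        assert res.spike_times.max() <= 300.0
        assert np.all(np.isfinite(res.i_input))


class TestFullNetworkStatistics:
    """Properties of the default 2000-neuron trials (session fixtures)."""

    def test_synchronous_irregular_state(self, default_results):
        # gamma-band collective rhythm with strongly irregular single units
        res = default_results[0]
        table = obs.isi_table(res, "exc")
        by_neuron = table.groupby("neuron_id")["isi_ms"]
        cv = (by_neuron.std() / by_neuron.mean()).dropna()
        assert cv[by_neuron.count() >= 10].mean() > 0.8

    def test_inhibitory_rate_exceeds_excitatory(self, default_results):
        for res in default_results:
            exc = res.is_exc[res.spike_neurons]
            n_exc = res.is_exc.sum()
            n_inh = len(res.is_exc) - n_exc
            rate_e = exc.sum() / n_exc
            rate_i = (~exc).sum() / n_inh
            assert rate_i > rate_e

    def test_balance_of_excitation_and_inhibition(self, default_results, rheobase):
        # the mean external current alone exceeds the spiking threshold,
        # while the net synaptic current stays below it
        res = default_results[0]
        ext = res.mean_ext_current.mean()
        exc_rows = np.isin(res.rec_indices, np.nonzero(res.is_exc)[0])
        net = res.i_input[exc_rows].mean()
        assert ext > rheobase["exc"]
        assert net < rheobase["exc"]

    def test_trials_statistically_exchangeable(self, default_results):
        # pooled excitatory ISI distributions of different seeds agree (KS)
        a = obs.isi_table(default_results[0], "exc")["isi_ms"]
        b = obs.isi_table(default_results[1], "exc")["isi_ms"]
        assert ks_2samp(a, b).pvalue > 0.01
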