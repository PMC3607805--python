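"""Frontier detection, spike classification, STA and phase locking."""

import numpy as np
import pytest

from gammamodes import firing_modes as fm
from gammamodes import network_sim as ns
from gammamodes.fixtures import make_bimodal_isi_train, make_locked_spiketrain
from gammamodes.spectral import PhaseTrace

from test_observables import fake_result


class TestFindModeFrontier:
    def test_recovers_symmetric_mixture_minimum(self):
        # equal-weight modes at 30 and 120 spikes/s: density minimum at the
        # geometric mean, 60 spikes/s
        train = make_bimodal_isi_train(30.0, 120.0, weight_slow=0.5, n_isi=10000, seed=0)
        fr = fm.find_mode_frontier(train.rates_hz, seed=0)
        assert train.true_frontier_hz == pytest.approx(60.0, abs=0.5)
        assert fr.frontier_hz == pytest.approx(60.0, abs=5.0)

    def test_recovers_weighted_mixture_within_ten_percent(self):
        train = make_bimodal_isi_train(30.0, 120.0, weight_slow=0.64, n_isi=10000, seed=1)
        fr = fm.find_mode_frontier(train.rates_hz, seed=0)
        assert fr.frontier_hz == pytest.approx(train.true_frontier_hz, rel=0.10)

    def test_unimodal_rates_rejected(self):
        rng = np.random.default_rng(2)
        rates = 1000.0 / rng.exponential(20.0, 5000)
        with pytest.raises(fm.UnimodalError):
            fm.find_mode_frontier(rates, seed=0)

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError):
            fm.find_mode_frontier(np.full(100, 10.0))

    def test_frontier_recovery_property(self):
        # randomized mode locations: the estimate stays within half the
        # inter-mode distance of the analytic minimum in >= 19/20 cases
        rng = np.random.default_rng(3)
        hits = 0
        for i in range(20):
            slow = rng.uniform(10.0, 40.0)
            fast = slow * rng.uniform(3.0, 6.0)
            train = make_bimodal_isi_train(
                slow, fast, weight_slow=rng.uniform(0.4, 0.75),
                n_isi=5000, seed=100 + i,
            )
            fr = fm.find_mode_frontier(train.rates_hz, seed=0)
            if abs(fr.frontier_hz - train.true_frontier_hz) < (fast - slow) / 2:
                hits += 1
        assert hits >= 19


class TestClassifySpikes:
    def test_burst_rule_example(self):
        # frontier 58.31 spikes/s (interval 17.15 ms): spikes at 0, 5, 10 ms
        # are fast with the first opening the burst; 100 and 200 ms are slow
        res = fake_result([0] * 5, [0.0, 5.0, 10.0, 100.0, 200.0])
        cls = fm.classify_spikes(res, 58.31)
        assert list(cls.label) == [1, 1, 1, -1, -1]
        assert list(cls.burst_first) == [True, False, False, False, False]

    def test_all_slow_train(self):
        res = fake_result([0] * 4, [0.0, 100.0, 220.0, 370.0])
        cls = fm.classify_spikes(res, 58.31)
        assert np.all(cls.label == -1)
        assert not np.any(cls.burst_first)

    def test_single_spike_unclassified(self):
        res = fake_result([0, 1], [50.0, 80.0])
        cls = fm.classify_spikes(res, 58.31)
        assert np.all(cls.label == 0)

    def test_isi_partition_is_exhaustive(self, default_result, default_frontier):
        cls = fm.classify_spikes(default_result, default_frontier.frontier_hz, "exc")
        slow = cls.slow_isi_fraction
        fast = cls.isi_fast.mean()
        assert slow + fast == pytest.approx(1.0, abs=1e-12)

    def test_mode_spike_selectors(self):
        res = fake_result([0] * 5, [0.0, 5.0, 10.0, 100.0, 200.0])
        cls = fm.classify_spikes(res, 58.31)
        assert list(cls.spikes("fast", first_only=True)) == [0.0]
        # slow first spikes open each long ISI
        assert list(cls.spikes("slow", first_only=True)) == [10.0, 100.0]


class TestSpikeTriggeredAverage:
    def test_constant_signal(self):
        sta = fm.spike_triggered_average(
            np.full(2000, 3.5), np.array([500.0, 900.0, 1300.0])
        )
        assert np.allclose(sta.mean, 3.5)
        assert sta.n_spikes == 3

    def test_known_phase_construction(self):
        # spikes planted at the maxima of a sinusoid: the STA reproduces one
        # oscillation cycle peaking at lag 0
        t = np.arange(20000)
        signal = np.cos(2 * np.pi * 45.0 * t / 1000.0)
        period = 1000.0 / 45.0
        spikes = np.arange(30, 880) * period
        sta = fm.spike_triggered_average(signal, spikes)
        assert sta.at_lag(0.0) == pytest.approx(1.0, abs=0.02)
        assert sta.at_lag(period / 2) == pytest.approx(-1.0, abs=0.05)

    def test_min_separation_filter(self):
        t = np.arange(2000, dtype=float)
        neurons = np.array([0, 0, 0, 1])
        spikes = np.array([500.0, 520.0, 600.0, 520.0])
        sta = fm.spike_triggered_average(t, spikes, spike_neurons=neurons)
        # 520 (same neuron, 20 ms after 500) is dropped; other three qualify
        assert sta.n_spikes == 3

    def test_sem_shrinks_with_spike_count(self):
        rng = np.random.default_rng(0)
        signal = rng.standard_normal(200000)
        spikes = rng.uniform(100.0, 199900.0, 4000)
        sta_all = fm.spike_triggered_average(signal, spikes)
        sta_quarter = fm.spike_triggered_average(signal, spikes[:1000])
        ratio = sta_quarter.sem.mean() / sta_all.sem.mean()
        assert ratio == pytest.approx(2.0, rel=0.15)

    def test_no_valid_spikes_rejected(self):
        with pytest.raises(ValueError):
            fm.spike_triggered_average(np.zeros(100), np.array([10.0]))


class TestPhaseLocking:
    @pytest.mark.parametrize("kappa", [1.0, 2.0])
    def test_preferred_phase_recovery(self, kappa):
        train = make_locked_spiketrain(
            rate_hz=30.0, kappa=kappa, preferred_phase=np.pi,
            duration_ms=60000.0, seed=int(kappa),
        )
        spikes = train.spike_times[
            (train.spike_times > 0) & (train.spike_times < train.phase.t[-1])
        ]
        assert len(spikes) >= 1000
        hist = fm.phase_locking_histogram(spikes, train.phase)
        err = np.angle(np.exp(1j * (hist.circular_mean - np.pi)))
        assert abs(err) < (0.2 if kappa >= 1.0 else 0.3)

    def test_uncovered_spikes_rejected(self):
        ph = PhaseTrace(np.arange(100.0), np.zeros(100), (45, 45), 1000.0)
        with pytest.raises(ValueError):
            fm.phase_locking_histogram(np.array([500.0]), ph)

    def test_density_normalized(self):
        train = make_locked_spiketrain(duration_ms=20000.0, seed=5)
        hist = fm.phase_locking_histogram(
            train.spike_times[train.spike_times < train.phase.t[-1]], train.phase
        )
        assert hist.density.sum() == pytest.approx(1.0)


class TestExternalRateCodingScatter:
    def test_constant_rate_abscissae(self):
        cfg = ns.NetworkConfig(
            n_neurons=100,
            duration=600.0,
            drive=ns.ExternalDriveParams(mean_rate=8500.0, sigma=0.0),
        )
        res = ns.run_simulation(cfg, seed=1)
        scatter = fm.external_rate_coding_scatter(res)
        assert len(scatter) > 0
        assert np.allclose(scatter["ext_rate_mean"], 8500.0)

    def test_rate_code_lives_in_fast_mode(self):
        # visible external-rate fluctuations (sigma_scale amplifies the
        # printed OU sigma): fast-mode rates track the external rate while
        # slow-mode abscissae converge to the mean rate
        cfg = ns.NetworkConfig(
            duration=2000.0,
            drive=ns.ExternalDriveParams(mean_rate=8500.0, sigma=0.6, sigma_scale=1000.0),
        )
        res = ns.run_simulation(cfg, seed=21)
        rates = np.asarray(
            fm.external_rate_coding_scatter(res)["rate_hz"], dtype=float
        )
        frontier = fm.find_mode_frontier(rates, seed=0)
        scatter = fm.external_rate_coding_scatter(res, frontier.frontier_hz)
        corr = fm.rate_coding_correlations(scatter)
        # the rate code is concentrated in the fast mode; the slow mode
        # keeps only a weak residual coupling (its mid-length ISIs are
        # comparable to the OU correlation time)
        assert corr["fast"]["rho"] > 0.2
        assert abs(corr["slow"]["rho"]) < 0.15
        assert corr["fast"]["rho"] > 2.0 * abs(corr["slow"]["rho"])
        slow = scatter[scatter["mode"] == "slow"]
        assert slow["ext_rate_mean"].mean() == pytest.approx(8500.0, rel=0.02)
        # long-ISI points average many fluctuations: tighter spread than fast
        fast = scatter[scatter["mode"] == "fast"]
        assert slow["ext_rate_mean"].std() < 0.5 * fast["ext_rate_mean"].std()
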