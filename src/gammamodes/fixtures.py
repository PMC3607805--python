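"""Synthetic data generators with known ground truth.

Each generator emulates one statistical structure that the analysis chain
assumes — a gamma line over a 1/f^2 background, von-Mises phase locking to
a known oscillation, a bimodal ISI mixture with a controllable inter-mode
gap, or an OU-rate Poisson train — and returns its own ground truth
alongside the data, so that analysis tests assert recovery rather than
re-deriving the truth from the generator's internals.  The fixtures do not
emulate conductance dynamics, only the statistics the analyses consume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import i0

from .network_sim import ExternalDriveParams, external_spike_trains, ou_rate_path
from .spectral import PhaseTrace

__all__ = [
    "ToyLFP",
    "LockedSpikeTrain",
    "BimodalISITrain",
    "make_toy_lfp",
    "make_locked_spiketrain",
    "make_bimodal_isi_train",
    "make_ou_poisson",
]


@dataclass
class ToyLFP:
    """1/f^2 background plus an optional sinusoidal gamma line.

    ``snr`` is the ratio of the line's RMS amplitude to the background
    standard deviation; ``trough_times`` are the exact trough times of the
    noiseless line.
    """

    t: np.ndarray
    trace: np.ndarray
    freq_hz: float
    snr: float
    fs_hz: float
    trough_times: np.ndarray


def make_toy_lfp(
    freq_hz: float = 45.0,
    snr: float = 2.0,
    duration_ms: float = 3000.0,
    fs_hz: float = 1000.0,
    seed: int = 0,
) -> ToyLFP:
    """Synthetic LFP: Brownian (1/f^2) background plus a sinusoid."""
    if freq_hz >= fs_hz / 2:
        raise ValueError("line frequency must be below Nyquist")
    rng = np.random.default_rng(seed)
    n = int(round(duration_ms * fs_hz / 1000.0))
    t = np.arange(n) * 1000.0 / fs_hz
    background = np.cumsum(rng.standard_normal(n))
    background -= background.mean()
    std = background.std()
    if std > 0:
        background /= std
    line = np.sqrt(2.0) * np.cos(2.0 * np.pi * freq_hz * t / 1000.0)  # unit RMS
    trace = background + snr * line
    period = 1000.0 / freq_hz
    trough_times = np.arange(period / 2.0, duration_ms, period)
    return ToyLFP(t, trace, freq_hz, snr, fs_hz, trough_times)


@dataclass
class LockedSpikeTrain:
    """Inhomogeneous Poisson spikes locked to a known oscillation.

    Intensity is ``rate * exp(kappa cos(phase - preferred)) / I0(kappa)``,
    i.e. a von Mises modulation whose time average equals ``rate_hz``.
    ``phase`` is the exact oscillation phase trace (not estimated).
    """

    spike_times: np.ndarray
    phase: PhaseTrace
    freq_hz: float
    kappa: float
    preferred_phase: float
    rate_hz: float


def make_locked_spiketrain(
    rate_hz: float = 20.0,
    freq_hz: float = 45.0,
    kappa: float = 2.0,
    preferred_phase: float = np.pi,
    duration_ms: float = 10000.0,
    seed: int = 0,
    dt_ms: float = 0.1,
) -> LockedSpikeTrain:
    """Spike train with von-Mises-type locking to a ``freq_hz`` oscillation."""
    if rate_hz <= 0:
        raise ValueError("rate must be positive")
    if kappa < 0:
        raise ValueError("kappa must be nonnegative")
    rng = np.random.default_rng(seed)
    n = int(round(duration_ms / dt_ms))
    t = np.arange(n) * dt_ms
    phase = np.mod(2.0 * np.pi * freq_hz * t / 1000.0, 2.0 * np.pi)
    lam = rate_hz * np.exp(kappa * np.cos(phase - preferred_phase)) / i0(kappa)
    counts = rng.poisson(lam * dt_ms * 1e-3)
    spike_times = np.repeat(t, counts)
    # exact phase on a 1 ms grid for the analysis side
    t_grid = np.arange(int(round(duration_ms))) * 1.0
    ph_grid = np.mod(2.0 * np.pi * freq_hz * t_grid / 1000.0, 2.0 * np.pi)
    return LockedSpikeTrain(
        spike_times,
        PhaseTrace(t_grid, ph_grid, (freq_hz, freq_hz), 1000.0),
        freq_hz,
        kappa,
        preferred_phase,
        rate_hz,
    )


@dataclass
class BimodalISITrain:
    """ISI sequence from a two-component lognormal mixture.

    On the log-rate axis the instantaneous rates follow a two-Gaussian
    mixture; ``true_frontier_hz`` is the analytic density minimum between
    the component means (NaN for a single component).
    """

    spike_times: np.ndarray
    isis_ms: np.ndarray
    rates_hz: np.ndarray
    true_frontier_hz: float
    weight_slow: float
    mode_slow_hz: float
    mode_fast_hz: float
    sigma_log: float


def _lognormal_mixture_minimum(mu1, mu2, w1, sigma):
    """Location of the density minimum of a two-Gaussian mixture between
    its means (on the axis where components are Gaussian)."""

    def neg_density(x):
        return -(
            w1 * np.exp(-0.5 * ((x - mu1) / sigma) ** 2)
            + (1 - w1) * np.exp(-0.5 * ((x - mu2) / sigma) ** 2)
        )

    res = minimize_scalar(
        lambda x: -neg_density(x), bounds=(mu1, mu2), method="bounded"
    )
    return res.x


def make_bimodal_isi_train(
    mode_slow_hz: float = 30.0,
    mode_fast_hz: float = 120.0,
    weight_slow: float = 0.64,
    sigma_log: float = 0.3,
    n_isi: int = 10000,
    seed: int = 0,
) -> BimodalISITrain:
    """ISIs drawn i.i.d. from a lognormal mixture with a known rate-axis gap.

    ``weight_slow`` is the probability of the slow component; 1 gives a
    unimodal train (frontier detection must then fail).
    """
    if weight_slow < 1.0 and mode_fast_hz < 2.0 * mode_slow_hz:
        raise ValueError("mode rates must be separated by a factor >= 2")
    if not 0.0 <= weight_slow <= 1.0:
        raise ValueError("weight must be in [0, 1]")
    rng = np.random.default_rng(seed)
    slow = rng.random(n_isi) < weight_slow
    mu = np.where(slow, np.log(mode_slow_hz), np.log(mode_fast_hz))
    log_rate = rng.normal(mu, sigma_log)
    rates = np.exp(log_rate)
    isis = 1000.0 / rates
    if 0.0 < weight_slow < 1.0:
        x_min = _lognormal_mixture_minimum(
            np.log(mode_slow_hz), np.log(mode_fast_hz), weight_slow, sigma_log
        )
        frontier = float(np.exp(x_min))
    else:
        frontier = float("nan")
    return BimodalISITrain(
        spike_times=np.concatenate(([0.0], np.cumsum(isis))),
        isis_ms=isis,
        rates_hz=rates,
        true_frontier_hz=frontier,
        weight_slow=weight_slow,
        mode_slow_hz=mode_slow_hz,
        mode_fast_hz=mode_fast_hz,
        sigma_log=sigma_log,
    )


def make_ou_poisson(
    mean_rate: float = 8500.0,
    sigma: float = 0.6,
    tau_ou: float = 16.0,
    n_neurons: int = 1,
    duration_ms: float = 1000.0,
    dt_ms: float = 0.05,
    seed: int = 0,
):
    """OU-rate heterogeneous Poisson trains plus their shared rate path."""
    rng = np.random.default_rng(seed)
    params = ExternalDriveParams(mean_rate=mean_rate, sigma=sigma, tau_ou=tau_ou)
    lam = ou_rate_path(params, duration_ms, dt_ms, rng)
    trains = external_spike_trains(lam[:-1], dt_ms, n_neurons, rng)
    return lam, trains
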