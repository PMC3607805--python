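"""Random balanced network of excitatory and inhibitory conductance-based
neurons with double-exponential synapses, transmission delays and a
rate-modulated external Poisson drive.

Network composition follows a classic cortical balance setup: N = 2000
cells, 80% excitatory / 20% inhibitory, every ordered pair connected
independently with probability 0.1 (mean out-degree 200, no imposed
architecture, no self-connections).  Recurrent spikes arrive after a delay
drawn per connection from a gamma distribution (mean 2 ms, variance 4 ms^2);
the external drive is delivered without delay.

Each synaptic contact contributes a conductance transient

    g_syn(t) = g' / (tau_d - tau_r) * [exp(-(t-t_j)/tau_d) - exp(-(t-t_j)/tau_r)]

summed over presynaptic arrival times t_j, and a current
``I_syn = -g_syn(t) (V - E_syn)`` entering the membrane equation, so AMPA
(E_syn = 0 mV) depolarizes from rest and GABA (E_syn = -70 mV)
hyperpolarizes.  The sum over arrivals is integrated exactly by a pair of
exponentially decaying accumulators (rise and decay) per synapse type.

All cells additionally receive an independent Poisson train of AMPA events
whose shared instantaneous rate lambda(t) fluctuates around its mean as an
Ornstein-Uhlenbeck process.  The coupled neuron equations are advanced with
the (stochastic) Heun predictor-corrector scheme at dt = 0.05 ms.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
from scipy.signal import lfilter

from .neuron_model import (
    BLOWUP_LIMIT,
    SPIKE_LOCKOUT,
    SPIKE_THRESHOLD,
    IntegrationError,
    NeuronParams,
    alpha_h,
    alpha_n,
    beta_h,
    beta_n,
    gate_steady_state,
    m_infinity,
    resting_state,
)

__all__ = [
    "SynapseParams",
    "SynapseState",
    "DelayParams",
    "ExternalDriveParams",
    "ConnectivityGraph",
    "RecordingConfig",
    "NetworkConfig",
    "SimulationResult",
    "build_connectivity",
    "ou_rate_path",
    "external_spike_trains",
    "synaptic_current",
    "psp_amplitude",
    "run_simulation",
]


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SynapseParams:
    """Kinetics and strength of one synapse type.

    ``g_prime`` is the conductance scale of the double-exponential transient
    in nS (converted to uS internally so that g*V is in nA).
    """

    tau_r: float
    tau_d: float
    e_syn: float
    g_prime: float
    kind: str

    def __post_init__(self) -> None:
        if not self.tau_d > self.tau_r > 0:
            raise ValueError("require tau_d > tau_r > 0")

    @classmethod
    def ampa_recurrent(cls, tau_d: float = 2.0) -> "SynapseParams":
        return cls(0.5, tau_d, 0.0, 2.5, "AMPA_recurrent")

    @classmethod
    def ampa_external(cls) -> "SynapseParams":
        return cls(0.5, 2.0, 0.0, 3.2, "AMPA_external")

    @classmethod
    def gaba(cls, tau_d: float = 5.0) -> "SynapseParams":
        return cls(2.0, tau_d, -70.0, 240.0, "GABA")

    @property
    def g_prime_us(self) -> float:
        """Conductance scale in uS."""
        return self.g_prime * 1e-3

    @property
    def peak_time(self) -> float:
        """Time of the conductance maximum after an isolated event (ms)."""
        return (
            self.tau_d * self.tau_r / (self.tau_d - self.tau_r)
            * np.log(self.tau_d / self.tau_r)
        )

    def kernel(self, t):
        """Conductance (uS) of a single event ``t`` ms after arrival."""
        t = np.asarray(t, dtype=float)
        out = (
            self.g_prime_us / (self.tau_d - self.tau_r)
            * (np.exp(-t / self.tau_d) - np.exp(-t / self.tau_r))
        )
        return np.where(t >= 0, out, 0.0)


class SynapseState:
    """Rise/decay accumulator pair integrating one synapse type exactly.

    The summed double-exponential conductance is ``g = a * (x_d - x_r)``
    with ``a = g'/(tau_d - tau_r)``; both accumulators decay exponentially
    with their own time constant and are incremented by the number of
    arriving events.  This event-driven update reproduces the closed-form
    transient of an isolated event to machine precision.
    """

    def __init__(self, params: SynapseParams, n: int = 1):
        self.params = params
        self.x_r = np.zeros(n)
        self.x_d = np.zeros(n)
        self.amp = params.g_prime_us / (params.tau_d - params.tau_r)

    def decay(self, dt: float) -> None:
        self.x_r *= np.exp(-dt / self.params.tau_r)
        self.x_d *= np.exp(-dt / self.params.tau_d)

    def deliver(self, counts) -> None:
        self.x_r += counts
        self.x_d += counts

    @property
    def g(self):
        """Instantaneous conductance (uS), nonnegative since x_d >= x_r."""
        return self.amp * (self.x_d - self.x_r)


@dataclass(frozen=True)
class DelayParams:
    """Gamma-distributed recurrent transmission delay, moment matched."""

    mean: float = 2.0
    variance: float = 4.0

    @property
    def shape(self) -> float:
        return self.mean**2 / self.variance

    @property
    def scale(self) -> float:
        return self.variance / self.mean

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.gamma(self.shape, self.scale, n)


@dataclass(frozen=True)
class ExternalDriveParams:
    """Rate-modulated external Poisson drive shared by all neurons.

    The instantaneous rate is ``lambda(t) = mean_rate + x(t)`` where x is a
    zero-mean Ornstein-Uhlenbeck process with standard deviation
    ``sigma * sigma_scale`` and correlation time ``tau_ou``; negative
    excursions are clipped to zero.  ``sigma_scale`` exposes the amplitude
    of the rate fluctuations relative to the printed default without
    touching ``sigma`` itself.
    """

    mean_rate: float = 8500.0
    sigma: float = 0.6
    tau_ou: float = 16.0
    sigma_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.tau_ou <= 0:
            raise ValueError("tau_ou must be positive")

    @property
    def cutoff_hz(self) -> float:
        """Corner frequency of the rate spectrum, 1/(2 pi tau) in Hz."""
        return 1000.0 / (2.0 * np.pi * self.tau_ou)


@dataclass
class ConnectivityGraph:
    """Directed random graph in CSR form (presynaptic -> postsynaptic)."""

    n: int
    indptr: np.ndarray       # (n+1,) into targets/delays
    targets: np.ndarray      # postsynaptic indices
    delays: np.ndarray       # per-edge delay, ms
    is_exc: np.ndarray       # (n,) bool population labels

    @property
    def n_edges(self) -> int:
        return len(self.targets)

    def out_degree(self) -> np.ndarray:
        return np.diff(self.indptr)


@dataclass(frozen=True)
class RecordingConfig:
    """What to record besides the spike raster.

    Currents are averaged into ``bin_ms`` bins on the fly; ``record_subset``
    selects the neurons whose per-cell net input and GABA currents are kept
    (None records every neuron).  ``v_subset`` lists neurons whose voltage
    trace is stored at full resolution binning.
    """

    bin_ms: float = 1.0
    record_subset: tuple | None = None
    v_subset: tuple = ()


@dataclass(frozen=True)
class NetworkConfig:
    """Complete description of one simulation."""

    n_neurons: int = 2000
    frac_exc: float = 0.8
    p_connect: float = 0.1
    exc: NeuronParams = field(default_factory=NeuronParams.excitatory)
    inh: NeuronParams = field(default_factory=NeuronParams.inhibitory)
    ampa_recurrent: SynapseParams = field(default_factory=SynapseParams.ampa_recurrent)
    ampa_external: SynapseParams = field(default_factory=SynapseParams.ampa_external)
    gaba: SynapseParams = field(default_factory=SynapseParams.gaba)
    delay: DelayParams = field(default_factory=DelayParams)
    drive: ExternalDriveParams = field(default_factory=ExternalDriveParams)
    duration: float = 3000.0
    dt: float = 0.05
    i_bias: float = 0.0
    electrode_resistance: float = 1.0  # MOhm, LFP proxy scale
    recording: RecordingConfig = field(default_factory=RecordingConfig)

    def with_(self, **kwargs) -> "NetworkConfig":
        return replace(self, **kwargs)

    def with_tau_d_gaba(self, tau_d: float) -> "NetworkConfig":
        return replace(self, gaba=replace(self.gaba, tau_d=tau_d))

    @property
    def n_exc(self) -> int:
        return int(round(self.n_neurons * self.frac_exc))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["recording"] = {
            "bin_ms": self.recording.bin_ms,
            "record_subset": list(self.recording.record_subset)
            if self.recording.record_subset is not None
            else None,
            "v_subset": list(self.recording.v_subset),
        }
        return d

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class SimulationResult:
    """Raster, recorded currents and bookkeeping of one trial.

    Current traces are averaged into ``bin_ms`` bins.  ``mean_abs_ampa`` and
    ``mean_abs_gaba`` are population means over excitatory cells of the
    absolute AMPA (external + recurrent) and GABA currents, i.e. the two
    ingredients of the LFP proxy.  ``i_input`` is the net input current
    (synaptic + bias) per recorded neuron; ``i_gaba`` the recorded cells'
    own inhibitory current.
    """

    config: NetworkConfig
    seed: int
    spike_neurons: np.ndarray
    spike_times: np.ndarray
    is_exc: np.ndarray
    bin_ms: float
    t_bins: np.ndarray
    lam: np.ndarray
    mean_abs_ampa: np.ndarray
    mean_abs_gaba: np.ndarray
    mean_ext_current: np.ndarray
    rec_indices: np.ndarray
    i_input: np.ndarray
    i_gaba: np.ndarray
    v_indices: np.ndarray
    v_traces: np.ndarray

    @property
    def config_hash(self) -> str:
        return self.config.hash()

    @property
    def duration(self) -> float:
        return self.config.duration

    def spikes_of(self, neuron: int) -> np.ndarray:
        return np.sort(self.spike_times[self.spike_neurons == neuron])


# ---------------------------------------------------------------------------
# Network construction and external drive
# ---------------------------------------------------------------------------

def build_connectivity(
    n: int,
    frac_exc: float,
    p_connect: float,
    delay_params: DelayParams,
    rng: np.random.Generator,
) -> ConnectivityGraph:
    """Independent-Bernoulli random digraph with gamma-distributed delays.

    Every ordered pair (i, j), i != j, is connected with probability
    ``p_connect``; targets are drawn from both populations and no structure
    is imposed beyond the population sizes.
    """
    if n < 2:
        raise ValueError("need at least two neurons")
    if not 0 <= p_connect < 1:
        raise ValueError("p_connect must be in [0, 1)")
    indptr = np.zeros(n + 1, dtype=np.int64)
    rows = []
    for i in range(n):
        tgt = np.nonzero(rng.random(n) < p_connect)[0]
        tgt = tgt[tgt != i]
        rows.append(tgt)
        indptr[i + 1] = indptr[i] + len(tgt)
    targets = np.concatenate(rows) if rows else np.empty(0, dtype=np.int64)
    delays = delay_params.sample(len(targets), rng)
    is_exc = np.arange(n) < int(round(n * frac_exc))
    return ConnectivityGraph(n, indptr, targets, delays, is_exc)


def ou_rate_path(
    params: ExternalDriveParams,
    duration: float,
    dt: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Rate path lambda(t) on the integration grid (spikes/s).

    The zero-mean fluctuation obeys ``dx/dt = [-x + s*sqrt(2 tau) eta]/tau``
    (s = sigma * sigma_scale) and is advanced with the stochastic Heun
    scheme, using the same Wiener increment in predictor and corrector;
    for this linear drift the recursion is a one-pole filter, evaluated
    with an initial condition drawn from the stationary law.  Negative total
    rates are clipped to zero.
    """
    if dt > params.tau_ou / 10.0:
        raise ValueError("dt must resolve the OU correlation time (tau/10)")
    n_steps = int(round(duration / dt))
    s = params.sigma * params.sigma_scale
    z = dt / params.tau_ou
    a = 1.0 - z + 0.5 * z**2                      # deterministic Heun factor
    b = s * np.sqrt(2.0 / params.tau_ou) * (1.0 - 0.5 * z) * np.sqrt(dt)
    x0 = rng.normal(0.0, s) if s > 0 else 0.0
    dw = rng.standard_normal(n_steps)
    # x[k+1] = a x[k] + b dW[k]
    x = lfilter([b], [1.0, -a], dw, zi=[a * x0])[0]
    path = params.mean_rate + np.concatenate(([x0], x))
    return np.clip(path, 0.0, None)


def external_spike_trains(
    lam: np.ndarray,
    dt: float,
    n_neurons: int,
    rng: np.random.Generator,
):
    """Independent inhomogeneous Poisson event trains sharing one rate path.

    Event counts per time bin are Poisson with mean ``lam * dt / 1000``
    (lam in spikes/s, dt in ms), drawn independently per neuron, which makes
    the count over any window exactly Poisson with mean equal to the
    integrated rate.  Returns a list of per-neuron event-time arrays (bin
    left edges).
    """
    lam = np.asarray(lam, dtype=float)
    if np.any(lam < 0):
        raise ValueError("rates must be nonnegative")
    mu = lam * dt * 1e-3
    counts = rng.poisson(mu[None, :].repeat(n_neurons, axis=0))
    t = np.arange(len(lam)) * dt
    return [np.repeat(t, counts[i]) for i in range(n_neurons)]


def synaptic_current(state: SynapseState, v_post, params: SynapseParams | None = None):
    """Current contributed to the membrane equation: -g_syn (V - E_syn), nA."""
    p = params or state.params
    return -state.g * (np.asarray(v_post, dtype=float) - p.e_syn)


# ---------------------------------------------------------------------------
# Single-event PSP
# ---------------------------------------------------------------------------

def psp_amplitude(
    post_params: NeuronParams,
    syn: SynapseParams,
    duration: float = 100.0,
    dt: float = 0.05,
) -> float:
    """Peak voltage deflection (mV, absolute) of a single synaptic event
    delivered to a neuron at its resting fixed point.

    The conductance transient is evaluated in closed form; the membrane is
    advanced with Heun at the network time step.
    """
    v_rest, n0, h0 = resting_state(post_params)
    n_steps = int(round(duration / dt))
    v, n, h = float(v_rest), float(n0), float(h0)
    t_on = 5.0
    peak = 0.0
    p = post_params
    for k in range(n_steps):
        t = k * dt
        g1 = float(syn.kernel(t - t_on))
        g2 = float(syn.kernel(t + dt - t_on))

        def deriv(v_, n_, h_, g_):
            m = m_infinity(v_)
            i_ion = (
                -p.g_k * n_**4 * (v_ - p.v_k)
                - p.g_na * m**3 * h_ * (v_ - p.v_na)
                - p.g_l * (v_ - p.v_l)
            )
            i_syn = -g_ * (v_ - syn.e_syn)
            dv = (i_ion + i_syn) / p.c_m
            dn = p.phi * (alpha_n(v_) * (1 - n_) - beta_n(v_) * n_)
            dh = p.phi * (alpha_h(v_) * (1 - h_) - beta_h(v_) * h_)
            return dv, dn, dh

        dv1, dn1, dh1 = deriv(v, n, h, g1)
        dv2, dn2, dh2 = deriv(v + dt * dv1, n + dt * dn1, h + dt * dh1, g2)
        v += 0.5 * dt * (dv1 + dv2)
        n += 0.5 * dt * (dn1 + dn2)
        h += 0.5 * dt * (dh1 + dh2)
        peak = max(peak, abs(v - v_rest))
    return peak


# ---------------------------------------------------------------------------
# Full network integration
# ---------------------------------------------------------------------------

def run_simulation(config: NetworkConfig, seed: int = 0) -> SimulationResult:
    """Integrate the network for ``config.duration`` ms.

    Connectivity, initial-condition jitter, the OU rate path and every
    neuron's external Poisson realization are all derived from ``seed``
    through independent child generators, so identical seeds give bitwise
    identical results.  Recurrent spikes are enqueued on a ring buffer at
    (spike time + edge delay) snapped to the integration grid; external
    events are applied with zero delay.
    """
    cfg = config
    dt = cfg.dt
    n = cfg.n_neurons
    n_exc = cfg.n_exc
    n_steps = int(round(cfg.duration / dt))
    ss = np.random.SeedSequence(seed)
    rng_conn, rng_ou, rng_sim = (np.random.default_rng(s) for s in ss.spawn(3))

    graph = build_connectivity(n, cfg.frac_exc, cfg.p_connect, cfg.delay, rng_conn)
    is_exc = graph.is_exc
    delay_steps = np.maximum(np.round(graph.delays / dt).astype(np.int64), 0)
    ring_len = int(delay_steps.max(initial=0)) + 2
    ring_rec = np.zeros((ring_len, n))
    ring_gaba = np.zeros((ring_len, n))

    lam = ou_rate_path(cfg.drive, cfg.duration, dt, rng_ou)

    # per-neuron membrane constants (populations share all but C_m here,
    # but keep full per-neuron arrays so presets can diverge)
    p_e, p_i = cfg.exc, cfg.inh
    c_m = np.where(is_exc, p_e.c_m, p_i.c_m)
    phi = np.where(is_exc, p_e.phi, p_i.phi)
    g_k = np.where(is_exc, p_e.g_k, p_i.g_k)
    g_na = np.where(is_exc, p_e.g_na, p_i.g_na)
    g_l = np.where(is_exc, p_e.g_l, p_i.g_l)
    v_k = np.where(is_exc, p_e.v_k, p_i.v_k)
    v_na = np.where(is_exc, p_e.v_na, p_i.v_na)
    v_l = np.where(is_exc, p_e.v_l, p_i.v_l)

    # initial conditions: V jittered in [V_L - 5, V_L], gates at steady state
    v = v_l - 5.0 * rng_sim.random(n)
    gate_n = gate_steady_state(v, "n")
    gate_h = gate_steady_state(v, "h")

    syn_ext, syn_rec, syn_gaba = cfg.ampa_external, cfg.ampa_recurrent, cfg.gaba
    states = {
        "ext": SynapseState(syn_ext, n),
        "rec": SynapseState(syn_rec, n),
        "gaba": SynapseState(syn_gaba, n),
    }
    decays = {
        key: (
            np.exp(-dt / st.params.tau_r),
            np.exp(-dt / st.params.tau_d),
        )
        for key, st in states.items()
    }
    e_gaba = syn_gaba.e_syn

    lockout_steps = int(round(SPIKE_LOCKOUT / dt))
    last_spike = np.full(n, -lockout_steps - 1, dtype=np.int64)
    spike_neurons: list[np.ndarray] = []
    spike_steps: list[np.ndarray] = []

    # recording
    rec_cfg = cfg.recording
    bin_ms = rec_cfg.bin_ms
    steps_per_bin = int(round(bin_ms / dt))
    n_bins = n_steps // steps_per_bin
    rec_idx = (
        np.arange(n)
        if rec_cfg.record_subset is None
        else np.asarray(rec_cfg.record_subset, dtype=np.int64)
    )
    v_idx = np.asarray(rec_cfg.v_subset, dtype=np.int64)
    acc_abs_ampa = np.zeros(n_bins)
    acc_abs_gaba = np.zeros(n_bins)
    acc_ext = np.zeros(n_bins)
    acc_lam = np.zeros(n_bins)
    acc_input = np.zeros((len(rec_idx), n_bins), dtype=np.float64)
    acc_gaba = np.zeros((len(rec_idx), n_bins), dtype=np.float64)
    acc_v = np.zeros((len(v_idx), n_bins), dtype=np.float64)

    x_ext_r, x_ext_d = states["ext"].x_r, states["ext"].x_d
    x_rec_r, x_rec_d = states["rec"].x_r, states["rec"].x_d
    x_gab_r, x_gab_d = states["gaba"].x_r, states["gaba"].x_d
    amp_ext, amp_rec, amp_gab = (
        states["ext"].amp, states["rec"].amp, states["gaba"].amp,
    )
    (dr_ext, dd_ext), (dr_rec, dd_rec), (dr_gab, dd_gab) = (
        decays["ext"], decays["rec"], decays["gaba"],
    )

    exc_sel = slice(0, n_exc)
    bias = cfg.i_bias

    def derivatives(v_, n_, h_, g_ampa, g_gaba):
        m = m_infinity(v_)
        i_syn = -g_ampa * v_ - g_gaba * (v_ - e_gaba)
        i_ion = (
            -g_k * n_**4 * (v_ - v_k)
            - g_na * m**3 * h_ * (v_ - v_na)
            - g_l * (v_ - v_l)
        )
        dv = (i_ion + i_syn + bias) / c_m
        dn = phi * (alpha_n(v_) * (1 - n_) - beta_n(v_) * n_)
        dh = phi * (alpha_h(v_) * (1 - h_) - beta_h(v_) * h_)
        return dv, dn, dh

    for k in range(n_steps):
        slot = k % ring_len
        # recurrent arrivals scheduled for this step
        arr_rec = ring_rec[slot]
        arr_gab = ring_gaba[slot]
        if arr_rec.any():
            x_rec_r += arr_rec
            x_rec_d += arr_rec
        if arr_gab.any():
            x_gab_r += arr_gab
            x_gab_d += arr_gab
        ring_rec[slot] = 0.0
        ring_gaba[slot] = 0.0
        # external events, zero delay
        counts = rng_sim.poisson(lam[k] * dt * 1e-3, n)
        if counts.any():
            x_ext_r += counts
            x_ext_d += counts

        g_ext = amp_ext * (x_ext_d - x_ext_r)
        g_rec = amp_rec * (x_rec_d - x_rec_r)
        g_gab = amp_gab * (x_gab_d - x_gab_r)

        dv1, dn1, dh1 = derivatives(v, gate_n, gate_h, g_ext + g_rec, g_gab)
        vp = v + dt * dv1
        np_ = gate_n + dt * dn1
        hp = gate_h + dt * dh1
        # conductances at t+dt: exact decay, arrivals applied next step
        g_ext2 = amp_ext * (x_ext_d * dd_ext - x_ext_r * dr_ext)
        g_rec2 = amp_rec * (x_rec_d * dd_rec - x_rec_r * dr_rec)
        g_gab2 = amp_gab * (x_gab_d * dd_gab - x_gab_r * dr_gab)
        dv2, dn2, dh2 = derivatives(vp, np_, hp, g_ext2 + g_rec2, g_gab2)
        v_new = v + 0.5 * dt * (dv1 + dv2)
        gate_n = gate_n + 0.5 * dt * (dn1 + dn2)
        gate_h = gate_h + 0.5 * dt * (dh1 + dh2)

        crossed = (v < SPIKE_THRESHOLD) & (v_new >= SPIKE_THRESHOLD)
        if crossed.any():
            ok = crossed & (k + 1 - last_spike > lockout_steps)
            spikers = np.nonzero(ok)[0]
            if len(spikers):
                last_spike[spikers] = k + 1
                spike_neurons.append(spikers)
                spike_steps.append(np.full(len(spikers), k + 1, dtype=np.int64))
                for i in spikers:
                    lo, hi_ = graph.indptr[i], graph.indptr[i + 1]
                    if hi_ == lo:
                        continue
                    tgt = graph.targets[lo:hi_]
                    slots = (k + 1 + delay_steps[lo:hi_]) % ring_len
                    if is_exc[i]:
                        ring_rec[slots, tgt] += 1.0
                    else:
                        ring_gaba[slots, tgt] += 1.0
        v = v_new
        if k % 200 == 0 and np.abs(v).max() > BLOWUP_LIMIT:
            raise IntegrationError("membrane potential blow-up in network run")

        # decay accumulators to t+dt
        x_ext_r *= dr_ext
        x_ext_d *= dd_ext
        x_rec_r *= dr_rec
        x_rec_d *= dd_rec
        x_gab_r *= dr_gab
        x_gab_d *= dd_gab

        # recording (state at beginning of the step, conductances g at t_k)
        b = k // steps_per_bin
        if b < n_bins:
            i_ampa = -(g_ext + g_rec) * v
            i_gaba_all = -g_gab * (v - e_gaba)
            acc_abs_ampa[b] += np.abs(i_ampa[exc_sel]).mean()
            acc_abs_gaba[b] += np.abs(i_gaba_all[exc_sel]).mean()
            acc_ext[b] += (-g_ext[exc_sel] * v[exc_sel]).mean()
            acc_lam[b] += lam[k]
            acc_input[:, b] += (i_ampa + i_gaba_all + bias)[rec_idx]
            acc_gaba[:, b] += i_gaba_all[rec_idx]
            if len(v_idx):
                acc_v[:, b] += v[v_idx]

    for acc in (acc_abs_ampa, acc_abs_gaba, acc_ext, acc_lam, acc_input, acc_gaba, acc_v):
        acc /= steps_per_bin

    if spike_neurons:
        spk_n = np.concatenate(spike_neurons)
        spk_t = np.concatenate(spike_steps) * dt
        order = np.argsort(spk_t, kind="stable")
        spk_n, spk_t = spk_n[order], spk_t[order]
    else:
        spk_n = np.empty(0, dtype=np.int64)
        spk_t = np.empty(0)

    t_bins = (np.arange(n_bins) + 0.5) * bin_ms
    return SimulationResult(
        config=cfg,
        seed=seed,
        spike_neurons=spk_n,
        spike_times=spk_t,
        is_exc=is_exc,
        bin_ms=bin_ms,
        t_bins=t_bins,
        lam=acc_lam,
        mean_abs_ampa=acc_abs_ampa,
        mean_abs_gaba=acc_abs_gaba,
        mean_ext_current=acc_ext,
        rec_indices=rec_idx,
        i_input=acc_input,
        i_gaba=acc_gaba,
        v_indices=v_idx,
        v_traces=acc_v,
    )
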