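"""Single-compartment conductance-based neuron model and its characterization.

The membrane potential of each cell follows a Hodgkin-Huxley-type equation

    C_m dV/dt = -g_K n^4 (V - V_K) - g_Na m^3 h (V - V_Na) - g_L (V - V_L) + I_syn

with the sodium activation gate ``m`` replaced by its voltage-dependent
steady state ``m_inf(V)`` (it is much faster than the other gates), and the
remaining gates obeying first-order kinetics

    dx/dt = phi * [alpha_x(V) (1 - x) - beta_x(V) x],    x in {n, h}

where ``phi = 3**((T - 6.3) / 10)`` is a temperature factor.  With the
default parameters the model is type I excitable: firing emerges through a
saddle-node-on-invariant-circle bifurcation, so the f-I curve rises
continuously from zero frequency.

Units are fixed throughout the package: mV, ms, nA, uS (microsiemens) and
nF, so that ``g * V`` is in nA and ``I / C_m`` is in mV/ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "NeuronParams",
    "NeuronState",
    "RateConstants",
    "FICurve",
    "PRCResult",
    "SingleNeuronTrace",
    "gating_rates",
    "m_infinity",
    "gate_steady_state",
    "membrane_derivatives",
    "resting_state",
    "simulate_single",
    "f_i_curve",
    "find_rheobase",
    "period_for_current",
    "find_current_for_period",
    "phase_response_curve",
]

#: Spike detection threshold (mV): upward crossing of 0 mV counts as a spike.
SPIKE_THRESHOLD = 0.0
#: Refractory lockout for spike detection (ms).
SPIKE_LOCKOUT = 2.0
#: Integration is aborted when |V| exceeds this bound (mV).
BLOWUP_LIMIT = 200.0


class IntegrationError(RuntimeError):
    """Numerical blow-up during integration."""


@dataclass(frozen=True)
class NeuronParams:
    """Biophysical parameters of one cell class.

    Conductances in uS, potentials in mV, capacitance in nF, temperature in
    degrees Celsius.  ``phi`` is derived from the temperature unless given
    explicitly.
    """

    g_k: float = 4.74
    g_na: float = 12.5
    g_l: float = 0.025
    v_k: float = -80.0
    v_na: float = 40.0
    v_l: float = -65.0
    c_m: float = 0.25
    temperature: float = 34.0
    phi: float = field(default=None)  # type: ignore[assignment]
    label: str = "excitatory"

    def __post_init__(self) -> None:
        if self.phi is None:
            object.__setattr__(
                self, "phi", 3.0 ** ((self.temperature - 6.3) / 10.0)
            )
        if self.c_m <= 0 or min(self.g_k, self.g_na, self.g_l) <= 0:
            raise ValueError("conductances and capacitance must be positive")

    @property
    def tau_m(self) -> float:
        """Passive membrane time constant C_m / g_L (ms)."""
        return self.c_m / self.g_l

    @classmethod
    def excitatory(cls) -> "NeuronParams":
        return cls(c_m=0.25, label="excitatory")

    @classmethod
    def inhibitory(cls) -> "NeuronParams":
        return cls(c_m=0.125, label="inhibitory")

    def with_(self, **kwargs) -> "NeuronParams":
        return replace(self, **kwargs)


@dataclass
class NeuronState:
    """Dynamical state (V, n, h) of one neuron; m is slaved to m_inf(V)."""

    v: float
    n: float
    h: float


@dataclass(frozen=True)
class RateConstants:
    """Voltage-dependent opening/closing rates (1/ms) of one gate."""

    alpha: float
    beta: float
    gate: str


@dataclass
class FICurve:
    """Steady firing rate (spikes/s) versus injected current (nA)."""

    currents: np.ndarray
    frequencies: np.ndarray


@dataclass
class PRCResult:
    """Phase response curve of a tonically firing neuron.

    ``phase_shift[i] = 1 - T(tau_i)/T0`` where ``T(tau_i)`` is the cycle
    length when a brief pulse is injected a fraction ``phases[i]`` into the
    unperturbed period ``T0``.  Positive values are phase advances.
    """

    period_t0: float
    phases: np.ndarray
    phase_shift: np.ndarray
    drive_current: float


@dataclass
class SingleNeuronTrace:
    """Voltage trajectory and detected spike times of a single-cell run."""

    t: np.ndarray
    v: np.ndarray
    n: np.ndarray
    h: np.ndarray
    spike_times: np.ndarray


# ---------------------------------------------------------------------------
# Gating kinetics
# ---------------------------------------------------------------------------

_SINGULAR_EPS = 1e-6


def _linexp(v, v0, slope, scale):
    """scale * (v - v0) / (1 - exp(-(v - v0)/slope)) with the removable
    singularity at v = v0 evaluated by its analytic limit scale*slope."""
    x = np.asarray(v, dtype=float) - v0
    small = np.abs(x) < _SINGULAR_EPS
    safe = np.where(small, 1.0, x)
    with np.errstate(over="ignore"):
        out = scale * safe / (1.0 - np.exp(-safe / slope))
    # first-order series around the singularity: scale*slope*(1 + x/(2*slope))
    return np.where(small, scale * slope * (1.0 + x / (2.0 * slope)), out)


def alpha_n(v):
    return _linexp(v, -20.0, 10.0, 0.01)


def beta_n(v):
    return 0.125 * np.exp(-(np.asarray(v, dtype=float) + 30.0) / 80.0)


def alpha_m(v):
    return _linexp(v, -16.0, 10.0, 0.1)


def beta_m(v):
    return 4.0 * np.exp(-(np.asarray(v, dtype=float) + 41.0) / 18.0)


def alpha_h(v):
    return 0.07 * np.exp(-(np.asarray(v, dtype=float) + 30.0) / 20.0)


def beta_h(v):
    return 1.0 / (1.0 + np.exp(-np.asarray(v, dtype=float) / 10.0))


_RATES = {
    "n": (alpha_n, beta_n),
    "m": (alpha_m, beta_m),
    "h": (alpha_h, beta_h),
}


def gating_rates(v: float, gate: str) -> RateConstants:
    """Opening/closing rates of a gate at membrane potential ``v`` (mV)."""
    if not np.all(np.isfinite(v)):
        raise ValueError("membrane potential must be finite")
    try:
        a_fn, b_fn = _RATES[gate]
    except KeyError:
        raise ValueError(f"unknown gate {gate!r}; expected one of n, m, h")
    return RateConstants(float(a_fn(v)), float(b_fn(v)), gate)


def m_infinity(v):
    """Steady-state sodium activation alpha_m / (alpha_m + beta_m)."""
    if not np.all(np.isfinite(v)):
        raise ValueError("membrane potential must be finite")
    a, b = alpha_m(v), beta_m(v)
    return a / (a + b)


def gate_steady_state(v, gate: str):
    """x_inf = alpha/(alpha+beta) for gate ``x`` at potential ``v``."""
    a_fn, b_fn = _RATES[gate]
    a, b = a_fn(v), b_fn(v)
    return a / (a + b)


# ---------------------------------------------------------------------------
# Membrane dynamics
# ---------------------------------------------------------------------------

def ionic_current(v, n, h, p: NeuronParams):
    """Total intrinsic current (nA): K, Na (with m = m_inf) and leak."""
    m = m_infinity(v)
    return (
        -p.g_k * n**4 * (v - p.v_k)
        - p.g_na * m**3 * h * (v - p.v_na)
        - p.g_l * (v - p.v_l)
    )


def membrane_derivatives(state, i_syn, params: NeuronParams):
    """Time derivatives (dV/dt, dn/dt, dh/dt) at one instant.

    ``state`` may be a NeuronState or a (v, n, h) tuple of arrays; ``i_syn``
    is the total applied current in nA (synaptic plus any injected bias).
    """
    if isinstance(state, NeuronState):
        v, n, h = state.v, state.n, state.h
    else:
        v, n, h = state
    dv = (ionic_current(v, n, h, params) + i_syn) / params.c_m
    dn = params.phi * (alpha_n(v) * (1.0 - n) - beta_n(v) * n)
    dh = params.phi * (alpha_h(v) * (1.0 - h) - beta_h(v) * h)
    return dv, dn, dh


def resting_state(params: NeuronParams, bracket=(-75.0, -55.0)):
    """Resting fixed point (V*, n_inf(V*), h_inf(V*)) for zero input."""

    def balance(v):
        n = gate_steady_state(v, "n")
        h = gate_steady_state(v, "h")
        return ionic_current(v, n, h, params)

    v_rest = brentq(balance, *bracket, xtol=1e-10)
    return v_rest, gate_steady_state(v_rest, "n"), gate_steady_state(v_rest, "h")


# ---------------------------------------------------------------------------
# Heun integration of one (or a batch of) isolated neurons
# ---------------------------------------------------------------------------

def _heun_batch(
    params: NeuronParams,
    i_of_step,
    n_steps: int,
    dt: float,
    v0,
    n0,
    h0,
    record: bool = False,
):
    """Heun (explicit trapezoid) integration of a batch of independent cells.

    ``i_of_step(k)`` returns the applied current (nA, scalar or batch array)
    held constant over step k.  Returns final state, spike-time lists per
    batch element and (optionally) full trajectories.
    """
    v = np.atleast_1d(np.asarray(v0, dtype=float)).copy()
    n = np.atleast_1d(np.asarray(n0, dtype=float)).copy()
    h = np.atleast_1d(np.asarray(h0, dtype=float)).copy()
    m = v.shape[0]
    lockout_steps = int(round(SPIKE_LOCKOUT / dt))
    last_spike = np.full(m, -lockout_steps - 1, dtype=np.int64)
    spikes: list[list[float]] = [[] for _ in range(m)]
    if record:
        traj_v = np.empty((n_steps + 1, m))
        traj_n = np.empty((n_steps + 1, m))
        traj_h = np.empty((n_steps + 1, m))
        traj_v[0], traj_n[0], traj_h[0] = v, n, h
    for k in range(n_steps):
        i_app = i_of_step(k)
        dv1, dn1, dh1 = membrane_derivatives((v, n, h), i_app, params)
        vp = v + dt * dv1
        np_ = n + dt * dn1
        hp = h + dt * dh1
        i_app2 = i_of_step(k + 1)
        dv2, dn2, dh2 = membrane_derivatives((vp, np_, hp), i_app2, params)
        v_new = v + 0.5 * dt * (dv1 + dv2)
        n = n + 0.5 * dt * (dn1 + dn2)
        h = h + 0.5 * dt * (dh1 + dh2)
        crossed = (v < SPIKE_THRESHOLD) & (v_new >= SPIKE_THRESHOLD)
        if np.any(crossed):
            ok = crossed & (k + 1 - last_spike > lockout_steps)
            for idx in np.nonzero(ok)[0]:
                spikes[idx].append((k + 1) * dt)
            last_spike[ok] = k + 1
        v = v_new
        if np.any(np.abs(v) > BLOWUP_LIMIT):
            raise IntegrationError(
                f"membrane potential exceeded +/-{BLOWUP_LIMIT} mV at "
                f"t = {(k + 1) * dt:.3f} ms"
            )
        if record:
            traj_v[k + 1], traj_n[k + 1], traj_h[k + 1] = v, n, h
    spike_arrays = [np.asarray(s) for s in spikes]
    if record:
        return (v, n, h), spike_arrays, (traj_v, traj_n, traj_h)
    return (v, n, h), spike_arrays, None


def _initial_state(params: NeuronParams, v0=None):
    if v0 is None:
        v0 = params.v_l
    return v0, gate_steady_state(v0, "n"), gate_steady_state(v0, "h")


def simulate_single(
    params: NeuronParams,
    i_const: float,
    duration: float,
    dt: float = 0.05,
    v0: float | None = None,
) -> SingleNeuronTrace:
    """Integrate one neuron under constant current injection.

    Spikes are detected as upward crossings of 0 mV with a 2 ms lockout.
    Initial conditions default to the leak reversal with gates at their
    steady state there, which makes single-cell runs deterministic.
    """
    if dt <= 0 or duration <= dt:
        raise ValueError("require dt > 0 and duration >> dt")
    n_steps = int(round(duration / dt))
    v, n, h = _initial_state(params, v0)
    current = lambda k: i_const  # noqa: E731
    _, spikes, traj = _heun_batch(
        params, current, n_steps, dt, [v], [n], [h], record=True
    )
    t = np.arange(n_steps + 1) * dt
    return SingleNeuronTrace(t, traj[0][:, 0], traj[1][:, 0], traj[2][:, 0], spikes[0])


def _steady_frequencies(spike_lists, transient: float, t_end: float) -> np.ndarray:
    """Steady firing rate (spikes/s) from spikes after the transient."""
    freqs = np.zeros(len(spike_lists))
    for i, s in enumerate(spike_lists):
        s = s[s >= transient]
        if len(s) >= 2:
            freqs[i] = 1000.0 * (len(s) - 1) / (s[-1] - s[0])
    return freqs


def f_i_curve(
    params: NeuronParams,
    currents,
    duration: float = 2000.0,
    dt: float = 0.05,
    transient: float = 500.0,
) -> FICurve:
    """Steady-state firing frequency over a grid of injected currents.

    The first ``transient`` ms of each run are discarded; the frequency is
    the inverse mean inter-spike interval of the remaining spikes (zero when
    fewer than two spikes survive).  All currents are integrated together as
    one batch.
    """
    currents = np.asarray(currents, dtype=float)
    if np.any(np.diff(currents) < 0):
        raise ValueError("current grid must be sorted ascending")
    n_steps = int(round(duration / dt))
    v, n, h = _initial_state(params)
    m = len(currents)
    _, spikes, _ = _heun_batch(
        params,
        lambda k: currents,
        n_steps,
        dt,
        np.full(m, v),
        np.full(m, n),
        np.full(m, h),
    )
    return FICurve(currents, _steady_frequencies(spikes, transient, duration))


def _sustained_spiking(params, currents, duration, dt, transient):
    """Boolean mask: does each current elicit >= 2 spikes after transient?"""
    freqs = f_i_curve(params, currents, duration, dt, transient).frequencies
    return freqs > 0


def find_rheobase(
    params: NeuronParams,
    tol: float = 1e-3,
    bracket=(0.0, 1.0),
    duration: float = 2000.0,
    dt: float = 0.05,
) -> float:
    """Minimal constant current (nA) producing sustained spiking.

    Bisection on the predicate "produces sustained spiking over the run",
    evaluated in batches of candidate currents to narrow the bracket by 16x
    per round until its width is below ``tol``.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    lo, hi = bracket
    spk = _sustained_spiking(params, [lo, hi], duration, dt, 500.0)
    if spk[0] or not spk[1]:
        raise ValueError(
            f"bracket {bracket} does not straddle the spiking threshold"
        )
    while hi - lo > tol:
        grid = np.linspace(lo, hi, 17)
        spiking = _sustained_spiking(params, grid[1:-1], duration, dt, 500.0)
        j = int(np.argmax(spiking)) if np.any(spiking) else len(grid) - 2
        if np.any(spiking):
            lo, hi = grid[j], grid[j + 1]
        else:
            lo = grid[-2]
    return 0.5 * (lo + hi)


def period_for_current(
    params: NeuronParams,
    i_drive: float,
    duration: float = 800.0,
    dt: float = 0.05,
    transient: float = 400.0,
) -> float:
    """Unperturbed tonic period T0 (ms) at a suprathreshold drive."""
    trace = simulate_single(params, i_drive, duration, dt)
    s = trace.spike_times[trace.spike_times >= transient]
    if len(s) < 3:
        raise ValueError("drive current does not produce tonic firing")
    return float(np.mean(np.diff(s)))


def find_current_for_period(
    params: NeuronParams,
    target_period: float,
    tol: float = 0.01,
    bracket=(0.1, 3.0),
    dt: float = 0.05,
) -> float:
    """Drive current whose tonic period matches ``target_period`` ms.

    The period decreases monotonically with current (type I), so plain
    bisection on the period applies.
    """
    lo, hi = bracket

    def err(i):
        try:
            return period_for_current(params, i, dt=dt) - target_period
        except ValueError:
            return np.inf  # subthreshold: period effectively infinite

    e_lo, e_hi = err(lo), err(hi)
    if not (e_lo > 0 > e_hi):
        raise ValueError("bracket does not straddle the target period")
    while True:
        mid = 0.5 * (lo + hi)
        e = err(mid)
        if abs(e) < tol:
            return mid
        if e > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-7:
            return mid


def phase_response_curve(
    params: NeuronParams,
    i_drive: float,
    pulse_amp: float = 1.0,
    pulse_dur: float = 0.2,
    n_phases: int = 32,
    dt: float = 0.05,
) -> PRCResult:
    """Phase response to a brief depolarizing pulse during tonic firing.

    For each fraction tau/T0 of the unperturbed period, a rectangular pulse
    of ``pulse_amp`` nA lasting ``pulse_dur`` ms is injected and the
    perturbed cycle length T(tau) is measured; the curve reports
    ``1 - T(tau)/T0``.  All phases are integrated as one batch.  Type I
    neurons advance their phase for every perturbation time.
    """
    if n_phases < 16:
        raise ValueError("n_phases must be at least 16")
    transient = 1000.0  # the limit cycle settles slowly near the SNIC
    trace = simulate_single(params, i_drive, transient + 200.0, dt)
    s = trace.spike_times[trace.spike_times >= transient]
    if len(s) < 3:
        raise ValueError("drive current is not in the tonic regime")
    isis = np.diff(s)
    if np.std(isis) / np.mean(isis) > 0.01:
        raise ValueError("base regime is not tonic (irregular ISIs)")
    t0_nominal = float(np.mean(isis))
    t_ref = float(s[0])
    # phases strictly inside (0, 1): the pulse never coincides with the
    # reference action potential itself
    phases = (np.arange(n_phases) + 1.0) / (n_phases + 1.0)
    pulse_start = t_ref + phases * t0_nominal
    pulse_end = pulse_start + pulse_dur
    n_steps = int(round((t_ref + 3.0 * t0_nominal) / dt))
    v, n, h = _initial_state(params)
    m = n_phases + 1  # last batch element is the unperturbed reference

    def current(k):
        t = k * dt
        active = (t >= pulse_start) & (t < pulse_end)
        return i_drive + pulse_amp * np.concatenate((active, [False]))

    _, spikes, _ = _heun_batch(
        params,
        current,
        n_steps,
        dt,
        np.full(m, v),
        np.full(m, n),
        np.full(m, h),
    )

    def next_interval(spk):
        nxt = spk[spk > t_ref + 0.25 * dt]
        if len(nxt) == 0:
            raise ValueError("no spike found after the perturbation")
        return nxt[0] - t_ref

    # measuring T0 the same way as T(tau), on the grid, cancels the spike
    # detection quantization in the shift
    t0 = next_interval(spikes[-1])
    shift = np.array([1.0 - next_interval(spk) / t0 for spk in spikes[:-1]])
    return PRCResult(float(t0), phases, shift, i_drive)
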