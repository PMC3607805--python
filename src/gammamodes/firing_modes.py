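"""Slow/fast firing-mode analysis of network activity.

During gamma oscillations the pooled instantaneous firing rates (1/ISI) of
the network's neurons are bimodal: a slow, sparse-firing mode and a fast,
burst-firing mode separated by a band of quasi-forbidden rates.  This
module locates the inter-mode frontier from a kernel density estimate of
the pooled rates, classifies every spike as slow or fast, and relates the
two modes to the collective rhythm via spike-triggered averages, spike-LFP
phase histograms and the external-rate coding scatter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde, spearmanr

from ._dip import dip_test
from .network_sim import NetworkConfig, SimulationResult, run_simulation
from .observables import compute_lfp, isi_table
from .spectral import (
    GAMMA_BAND,
    PhaseTrace,
    SpectrumConfig,
    bandpass,
    hilbert_phase,
    multitaper_psd,
    spectral_peak,
)

__all__ = [
    "UnimodalError",
    "ModeFrontier",
    "ModeClassification",
    "STAResult",
    "PhaseHistogram",
    "SweepSummary",
    "find_mode_frontier",
    "classify_spikes",
    "spike_triggered_average",
    "sta_of_lfp",
    "sta_of_local_inhibition",
    "phase_locking_histogram",
    "external_rate_coding_scatter",
    "tau_d_sweep",
]


class UnimodalError(ValueError):
    """The pooled rate distribution shows no significant second mode."""


@dataclass
class ModeFrontier:
    """Inter-mode minimum of the instantaneous-rate density.

    ``frontier_hz`` is the rate at the density minimum between the two
    largest modes (``mode_slow_hz`` < ``mode_fast_hz``); ``dip`` and
    ``dip_pvalue`` report the unimodality test backing the split.
    """

    frontier_hz: float
    mode_slow_hz: float
    mode_fast_hz: float
    dip: float
    dip_pvalue: float
    n_events: int

    @property
    def frontier_isi_ms(self) -> float:
        return 1000.0 / self.frontier_hz


def find_mode_frontier(
    rates,
    min_events: int = 500,
    alpha: float = 0.05,
    grid_size: int = 512,
    seed: int = 0,
) -> ModeFrontier:
    """Locate the slow/fast frontier of pooled instantaneous rates.

    A Gaussian kernel density with Silverman bandwidth is evaluated on the
    log-rate axis (instantaneous rates span two decades, and the histogram
    modes are log-separated); the frontier is the density minimum between
    the two highest local maxima.  A dip test of unimodality gates the
    procedure: if the pooled rates are compatible with a unimodal law at
    level ``alpha`` a :class:`UnimodalError` is raised.
    """
    rates = np.asarray(rates, dtype=float)
    rates = rates[rates > 0]
    if len(rates) < min_events:
        raise ValueError(f"need at least {min_events} rate events, got {len(rates)}")
    log_r = np.log(rates)
    dip, pval = dip_test(log_r, seed=seed)
    if pval >= alpha:
        raise UnimodalError(
            f"rate distribution not significantly bimodal (dip p = {pval:.3f})"
        )
    kde = gaussian_kde(log_r, bw_method="silverman")
    grid = np.linspace(log_r.min(), log_r.max(), grid_size)
    dens = kde(grid)
    interior = np.nonzero(
        (dens[1:-1] >= dens[:-2]) & (dens[1:-1] >= dens[2:])
    )[0] + 1
    if len(interior) < 2:
        raise UnimodalError("kernel density estimate has fewer than two modes")
    top2 = interior[np.argsort(dens[interior])[-2:]]
    i_lo, i_hi = np.sort(top2)
    between = slice(i_lo, i_hi + 1)
    i_min = i_lo + int(np.argmin(dens[between]))
    return ModeFrontier(
        frontier_hz=float(np.exp(grid[i_min])),
        mode_slow_hz=float(np.exp(grid[i_lo])),
        mode_fast_hz=float(np.exp(grid[i_hi])),
        dip=dip,
        dip_pvalue=pval,
        n_events=len(rates),
    )


@dataclass
class ModeClassification:
    """Per-spike slow/fast labels for one population's raster.

    ``label`` is +1 for fast, -1 for slow, 0 for unclassified (spikes
    flanking no ISI).  A spike is fast when either flanking ISI is shorter
    than the frontier interval; a fast spike whose preceding ISI is slow or
    absent opens a burst (``burst_first``).  ``isi_fast`` labels the ISIs
    themselves, in the row order of ``isi``.
    """

    spike_neurons: np.ndarray
    spike_times: np.ndarray
    label: np.ndarray
    burst_first: np.ndarray
    frontier_hz: float
    isi: pd.DataFrame
    isi_fast: np.ndarray

    @property
    def slow_isi_fraction(self) -> float:
        """Fraction of ISIs on the slow side of the frontier."""
        return float(1.0 - self.isi_fast.mean())

    def spikes(self, mode: str, first_only: bool = False) -> np.ndarray:
        """Spike times of one mode.

        For the fast mode ``first_only`` restricts to burst-first spikes;
        for the slow mode it selects the spike opening each slow ISI (these
        are the events whose timing carries the phase code).
        """
        if mode == "fast":
            mask = self.burst_first if first_only else self.label == 1
            return self.spike_times[mask]
        if mode == "slow":
            if first_only:
                slow = self.isi.loc[~self.isi_fast.astype(bool), "t_start"]
                return slow.to_numpy()
            return self.spike_times[self.label == -1]
        raise ValueError("mode must be 'slow' or 'fast'")


def classify_spikes(
    result: SimulationResult,
    frontier_hz: float,
    population: str = "all",
) -> ModeClassification:
    """Label every spike of a population as slow or fast firing.

    An ISI shorter than the frontier interval ``1000/frontier_hz`` ms marks
    both flanking spikes as fast; spikes flanking only longer ISIs are
    slow; spikes with no neighbor in the raster remain unclassified.
    """
    from .observables import _population_mask

    mask = _population_mask(result, population)
    nrn = result.spike_neurons[mask]
    t = result.spike_times[mask]
    order = np.lexsort((t, nrn))
    nrn, t = nrn[order], t[order]
    threshold_ms = 1000.0 / frontier_hz

    same = nrn[1:] == nrn[:-1]
    isi = t[1:] - t[:-1]
    fast_isi = same & (isi < threshold_ms)
    label = np.zeros(len(t), dtype=np.int8)
    has_isi = np.zeros(len(t), dtype=bool)
    has_isi[1:] |= same
    has_isi[:-1] |= same
    fast = np.zeros(len(t), dtype=bool)
    fast[1:] |= fast_isi
    fast[:-1] |= fast_isi
    label[fast] = 1
    label[has_isi & ~fast] = -1
    prev_fast = np.zeros(len(t), dtype=bool)
    prev_fast[1:] = fast_isi
    burst_first = fast & ~prev_fast

    table = isi_table(result, population)
    isi_fast_tab = (table["isi_ms"] < threshold_ms).to_numpy()
    return ModeClassification(
        spike_neurons=nrn,
        spike_times=t,
        label=label,
        burst_first=burst_first,
        frontier_hz=frontier_hz,
        isi=table,
        isi_fast=isi_fast_tab,
    )


# ---------------------------------------------------------------------------
# Spike-triggered averages
# ---------------------------------------------------------------------------

@dataclass
class STAResult:
    """Lag-aligned mean of a signal around selected spikes."""

    lags_ms: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_spikes: int
    signal_kind: str

    def at_lag(self, lag_ms: float) -> float:
        return float(np.interp(lag_ms, self.lags_ms, self.mean))


def _select_isolated(neurons, times, min_separation: float) -> np.ndarray:
    """Mask of spikes whose same-neuron predecessor is sufficiently old."""
    order = np.lexsort((times, neurons))
    n_s, t_s = neurons[order], times[order]
    ok_sorted = np.ones(len(t_s), dtype=bool)
    same = n_s[1:] == n_s[:-1]
    ok_sorted[1:] = ~same | (t_s[1:] - t_s[:-1] >= min_separation)
    ok = np.empty(len(t_s), dtype=bool)
    ok[order] = ok_sorted
    return ok


def spike_triggered_average(
    signal: np.ndarray,
    spike_times: np.ndarray,
    fs_hz: float = 1000.0,
    window_ms: tuple = (-50.0, 20.0),
    spike_neurons: np.ndarray | None = None,
    min_separation_ms: float = 50.0,
    signal_kind: str = "LFP",
) -> STAResult:
    """Mean of ``signal`` in a fixed window around each qualifying spike.

    Spikes qualify when the whole window lies inside the recording and,
    if ``spike_neurons`` is given, the same neuron's previous spike is at
    least ``min_separation_ms`` earlier (other neurons' spikes are not
    constrained).  Lag 0 is the spike time.
    """
    signal = np.asarray(signal, dtype=float)
    spike_times = np.asarray(spike_times, dtype=float)
    if spike_neurons is not None:
        keep = _select_isolated(
            np.asarray(spike_neurons), spike_times, min_separation_ms
        )
        spike_times = spike_times[keep]
    dt = 1000.0 / fs_hz
    lo = int(round(window_ms[0] / dt))
    hi = int(round(window_ms[1] / dt))
    idx = np.round(spike_times / dt).astype(np.int64)
    valid = (idx + lo >= 0) & (idx + hi < len(signal))
    idx = idx[valid]
    if len(idx) == 0:
        raise ValueError("no spikes with a full analysis window")
    lags = np.arange(lo, hi + 1)
    segments = signal[idx[:, None] + lags[None, :]]
    return STAResult(
        lags_ms=lags * dt,
        mean=segments.mean(axis=0),
        sem=segments.std(axis=0, ddof=1) / np.sqrt(len(idx))
        if len(idx) > 1
        else np.zeros(len(lags)),
        n_spikes=len(idx),
        signal_kind=signal_kind,
    )


def _mode_spike_selection(classification: ModeClassification, mode: str):
    """Spike (neuron, time) pairs entering a mode's STA: slow spikes or
    burst-first fast spikes."""
    if mode == "fast":
        mask = classification.burst_first
    elif mode == "slow":
        mask = classification.label == -1
    else:
        raise ValueError("mode must be 'slow' or 'fast'")
    return classification.spike_neurons[mask], classification.spike_times[mask]


def sta_of_lfp(
    result: SimulationResult,
    classification: ModeClassification,
    mode: str,
    window_ms: tuple = (-50.0, 20.0),
) -> STAResult:
    """STA of the global LFP around slow or burst-first fast spikes."""
    lfp = compute_lfp(result)
    nrn, t = _mode_spike_selection(classification, mode)
    return spike_triggered_average(
        lfp.lfp, t, lfp.fs_hz, window_ms, spike_neurons=nrn, signal_kind="LFP"
    )


def sta_of_local_inhibition(
    result: SimulationResult,
    classification: ModeClassification,
    mode: str,
    window_ms: tuple = (-50.0, 20.0),
) -> STAResult:
    """STA of each spiking neuron's own GABA input current (local measure).

    Segments are drawn from the spiking neuron's recorded ``I_GABA`` trace,
    then averaged across all qualifying spikes of the mode.
    """
    if result.i_gaba.size == 0:
        raise ValueError("no per-neuron GABA current was recorded")
    nrn, t = _mode_spike_selection(classification, mode)
    keep = _select_isolated(nrn, t, 50.0)
    nrn, t = nrn[keep], t[keep]
    rec_pos = {int(v): i for i, v in enumerate(result.rec_indices)}
    fs = 1000.0 / result.bin_ms
    dt = result.bin_ms
    lo = int(round(window_ms[0] / dt))
    hi = int(round(window_ms[1] / dt))
    lags = np.arange(lo, hi + 1)
    n_bins = result.i_gaba.shape[1]
    segs = []
    for neuron, time in zip(nrn, t):
        pos = rec_pos.get(int(neuron))
        if pos is None:
            continue
        i0 = int(round(time / dt))
        if i0 + lo < 0 or i0 + hi >= n_bins:
            continue
        segs.append(result.i_gaba[pos, i0 + lags])
    if not segs:
        raise ValueError("no qualifying spikes with recorded GABA current")
    segs = np.asarray(segs)
    return STAResult(
        lags_ms=lags * dt,
        mean=segs.mean(axis=0),
        sem=segs.std(axis=0, ddof=1) / np.sqrt(len(segs))
        if len(segs) > 1
        else np.zeros(len(lags)),
        n_spikes=len(segs),
        signal_kind="I_GABA",
    )


# ---------------------------------------------------------------------------
# Spike-LFP phase locking
# ---------------------------------------------------------------------------

@dataclass
class PhaseHistogram:
    """Normalized distribution of LFP phases at spike times.

    Phase pi corresponds to LFP troughs under the package's Hilbert-phase
    convention.  ``density`` sums to one over the bins.
    """

    bin_edges: np.ndarray
    density: np.ndarray
    circular_mean: float
    resultant_length: float
    n_spikes: int
    mode: str


def phase_locking_histogram(
    spike_times: np.ndarray,
    phase: PhaseTrace,
    n_bins: int = 24,
    mode: str = "",
) -> PhaseHistogram:
    """Histogram of instantaneous LFP phase at the given spike times.

    Phases are assigned by linear interpolation of the unwrapped phase.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    inside = (spike_times >= phase.t[0]) & (spike_times <= phase.t[-1])
    if not np.all(inside):
        raise ValueError("phase trace does not cover all spike times")
    ph = phase.at(spike_times)
    edges = np.linspace(0.0, 2.0 * np.pi, n_bins + 1)
    counts, _ = np.histogram(ph, bins=edges)
    total = counts.sum()
    density = counts / total if total else counts.astype(float)
    z = np.exp(1j * ph).mean() if len(ph) else 0.0
    return PhaseHistogram(
        bin_edges=edges,
        density=density,
        circular_mean=float(np.mod(np.angle(z), 2.0 * np.pi)),
        resultant_length=float(np.abs(z)),
        n_spikes=int(total),
        mode=mode,
    )


def gamma_phase_trace(
    result: SimulationResult,
    center_hz: float | None = None,
    half_width_hz: float = 5.0,
    zero_phase: bool = True,
) -> PhaseTrace:
    """Band-passed LFP phase around the gamma peak of this simulation."""
    lfp = compute_lfp(result)
    if center_hz is None:
        spec = multitaper_psd(lfp.lfp, SpectrumConfig(fs_hz=lfp.fs_hz))
        center_hz = spectral_peak(spec).freq_hz
    filtered = bandpass(
        lfp.lfp, center_hz, half_width_hz, fs_hz=lfp.fs_hz, zero_phase=zero_phase
    )
    ph = hilbert_phase(filtered, lfp.fs_hz, (center_hz - half_width_hz, center_hz + half_width_hz))
    return ph


# ---------------------------------------------------------------------------
# External-rate coding scatter
# ---------------------------------------------------------------------------

def external_rate_coding_scatter(
    result: SimulationResult,
    frontier_hz: float | None = None,
) -> pd.DataFrame:
    """Instantaneous rate of each excitatory ISI vs the mean external rate
    over that ISI.

    Columns: ``neuron_id, isi_ms, rate_hz, ext_rate_mean`` plus ``mode``
    (slow/fast) when a frontier is supplied.  Long-ISI points average the
    external rate over many fluctuations, so their abscissae converge to
    the mean external rate, while fast-mode points track its excursions.
    """
    if result.lam.size == 0:
        raise ValueError("external rate path was not recorded")
    table = isi_table(result, "exc")
    bin_ms = result.bin_ms
    csum = np.concatenate(([0.0], np.cumsum(result.lam)))
    lo = np.ceil(table["t_start"].to_numpy() / bin_ms).astype(np.int64)
    hi = np.floor(table["t_end"].to_numpy() / bin_ms).astype(np.int64)
    hi = np.minimum(hi, len(result.lam))
    ok = hi > lo
    mean_ext = np.full(len(table), np.nan)
    mean_ext[ok] = (csum[hi[ok]] - csum[lo[ok]]) / (hi[ok] - lo[ok])
    out = pd.DataFrame(
        {
            "neuron_id": table["neuron_id"],
            "isi_ms": table["isi_ms"],
            "rate_hz": table["rate_hz"],
            "ext_rate_mean": mean_ext,
        }
    ).dropna()
    if frontier_hz is not None:
        out["mode"] = np.where(out["rate_hz"] >= frontier_hz, "fast", "slow")
    return out


def rate_coding_correlations(scatter: pd.DataFrame) -> dict:
    """Spearman rank correlation of instantaneous vs external rate, per mode."""
    out = {}
    for mode, grp in scatter.groupby("mode"):
        rho, p = spearmanr(grp["ext_rate_mean"], grp["rate_hz"])
        out[mode] = {"rho": float(rho), "p": float(p), "n": len(grp)}
    return out


# ---------------------------------------------------------------------------
# GABA decay-time sweep
# ---------------------------------------------------------------------------

@dataclass
class SweepSummary:
    """Headline numbers of one GABA decay-time condition."""

    tau_d: float
    gamma_peak_hz: float
    has_gamma_peak: bool
    frontier_hz: float | None
    slow_fraction: float
    fast_fraction: float
    forbidden_gap_ms: float
    n_isi: int


def forbidden_gap_width(
    rates,
    frontier: ModeFrontier,
    rel_threshold: float = 0.5,
    grid_size: int = 512,
) -> float:
    """Width (ms) of the quasi-forbidden band of firing periods.

    The band is the contiguous interval around the inter-mode minimum of
    the kernel density of log rates where the density stays below
    ``rel_threshold`` times the lower of the two mode peaks (a
    full-width-at-half-minor-peak convention).  It is reported on the
    period (ISI) axis — the natural measure for a depression whose duration
    is set by the inhibitory decay time: slower GABA forbids a longer range
    of firing periods even as the band's location slides to lower rates.
    Zero when the density never drops that far.
    """
    rates = np.asarray(rates, dtype=float)
    log_r = np.log(rates[rates > 0])
    kde = gaussian_kde(log_r, bw_method="silverman")
    grid = np.linspace(log_r.min(), log_r.max(), grid_size)
    dens = kde(grid)
    lo_m = np.log(frontier.mode_slow_hz)
    hi_m = np.log(frontier.mode_fast_hz)
    peak_ref = min(kde([lo_m])[0], kde([hi_m])[0])
    mid = np.log(frontier.frontier_hz)
    below = dens < rel_threshold * peak_ref
    inside = (grid > lo_m) & (grid < hi_m)
    ok = below & inside
    i_mid = int(np.argmin(np.abs(grid - mid)))
    if not ok[i_mid]:
        return 0.0
    i0 = i_mid
    while i0 > 0 and ok[i0 - 1]:
        i0 -= 1
    i1 = i_mid
    while i1 < len(grid) - 1 and ok[i1 + 1]:
        i1 += 1
    r_lo, r_hi = float(np.exp(grid[i0])), float(np.exp(grid[i1]))
    return 1000.0 / r_lo - 1000.0 / r_hi


def summarize_condition(
    results: list[SimulationResult],
    tau_d: float,
    reference_frontier_hz: float = 58.31,
    seed: int = 0,
) -> SweepSummary:
    """Frontier, mode fractions and gamma peak for one set of trials."""
    lfps = [compute_lfp(r).lfp for r in results]
    spec = multitaper_psd(lfps, SpectrumConfig())
    peak = spectral_peak(spec, GAMMA_BAND)
    rates = np.concatenate([isi_table(r, "exc")["rate_hz"].to_numpy() for r in results])
    gap = 0.0
    try:
        frontier = find_mode_frontier(rates, seed=seed)
        frontier_hz = frontier.frontier_hz
        gap = forbidden_gap_width(rates, frontier)
    except (UnimodalError, ValueError):
        frontier = None
        frontier_hz = None
    ref = frontier_hz if frontier_hz is not None else reference_frontier_hz
    slow = float((rates < ref).mean()) if len(rates) else float("nan")
    return SweepSummary(
        tau_d=tau_d,
        gamma_peak_hz=peak.freq_hz,
        has_gamma_peak=peak.has_peak,
        frontier_hz=frontier_hz,
        slow_fraction=slow,
        fast_fraction=1.0 - slow,
        forbidden_gap_ms=gap,
        n_isi=len(rates),
    )


def tau_d_sweep(
    config: NetworkConfig,
    tau_d_values=(2.5, 5.0, 10.0, 30.0),
    n_trials: int = 1,
    seed: int = 0,
) -> list[SweepSummary]:
    """Re-run the full pipeline for several GABA decay time constants.

    Everything else is held fixed; trial seeds are derived from ``seed``.
    """
    out = []
    for j, tau_d in enumerate(tau_d_values):
        cfg = config.with_tau_d_gaba(tau_d)
        results = [
            run_simulation(cfg, seed=seed + 1000 * j + i) for i in range(n_trials)
        ]
        out.append(summarize_condition(results, tau_d, seed=seed))
    return out
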