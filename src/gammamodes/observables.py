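"""Population-level observables derived from a simulation.

The LFP proxy is the population average, over excitatory cells, of the
absolute synaptic currents they receive, scaled by a nominal electrode
resistance:

    LFP(t) = R_e * < |I_AMPA| + |I_GABA| >_exc

with I_AMPA including both the external Poisson drive and the recurrent
excitatory current.  The time-resolved population firing rate is the spike
histogram per unit time divided by the number of neurons.  Per-neuron
activity is summarized by the inter-spike-interval (ISI) table, whose
reciprocal intervals are the instantaneous firing rates that exhibit the
slow/fast bimodality analyzed in :mod:`gammamodes.firing_modes`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network_sim import SimulationResult

__all__ = [
    "LFPTrace",
    "PopulationRate",
    "compute_lfp",
    "population_rate",
    "isi_table",
    "instantaneous_rates",
    "embedded_fi_scatter",
]


@dataclass
class LFPTrace:
    """LFP proxy on the recording grid (mV = MOhm * nA)."""

    t: np.ndarray
    lfp: np.ndarray
    r_e: float
    fs_hz: float

    def __post_init__(self) -> None:
        assert np.all(self.lfp >= 0), "LFP proxy is a sum of absolute currents"


@dataclass
class PopulationRate:
    """Spikes per second per neuron in fixed time bins."""

    edges: np.ndarray
    rate: np.ndarray
    population: str
    n_neurons: int

    @property
    def t(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def fs_hz(self) -> float:
        return 1000.0 / (self.edges[1] - self.edges[0])


def compute_lfp(result: SimulationResult, r_e: float | None = None) -> LFPTrace:
    """Assemble the LFP proxy from the recorded population-mean currents."""
    if result.mean_abs_ampa.size == 0:
        raise ValueError("simulation did not record synaptic currents")
    r_e = result.config.electrode_resistance if r_e is None else r_e
    lfp = r_e * (result.mean_abs_ampa + result.mean_abs_gaba)
    return LFPTrace(result.t_bins, lfp, r_e, 1000.0 / result.bin_ms)


def _population_mask(result: SimulationResult, population: str) -> np.ndarray:
    exc = result.is_exc[result.spike_neurons]
    if population == "exc":
        return exc
    if population == "inh":
        return ~exc
    if population == "all":
        return np.ones(len(exc), dtype=bool)
    raise ValueError("population must be 'exc', 'inh' or 'all'")


def _population_size(result: SimulationResult, population: str) -> int:
    n_exc = int(result.is_exc.sum())
    n = len(result.is_exc)
    return {"exc": n_exc, "inh": n - n_exc, "all": n}[population]


def population_rate(
    result: SimulationResult,
    bin_ms: float = 1.0,
    population: str = "all",
) -> PopulationRate:
    """Time-resolved firing rate: spike histogram / (bin * N), in spikes/s."""
    if bin_ms <= 0:
        raise ValueError("bin_ms must be positive")
    mask = _population_mask(result, population)
    n_pop = _population_size(result, population)
    edges = np.arange(0.0, result.duration + bin_ms / 2, bin_ms)
    counts, _ = np.histogram(result.spike_times[mask], bins=edges)
    rate = counts / (n_pop * bin_ms * 1e-3)
    return PopulationRate(edges, rate, population, n_pop)


def isi_table(
    result: SimulationResult,
    population: str = "all",
) -> pd.DataFrame:
    """One row per consecutive spike pair of each neuron.

    Columns: ``neuron_id, population, t_start, t_end, isi_ms, rate_hz``
    where ``rate_hz = 1000 / isi_ms`` is the instantaneous firing rate.
    """
    mask = _population_mask(result, population)
    nrn = result.spike_neurons[mask]
    t = result.spike_times[mask]
    order = np.lexsort((t, nrn))
    nrn, t = nrn[order], t[order]
    same = nrn[1:] == nrn[:-1]
    t0, t1 = t[:-1][same], t[1:][same]
    ids = nrn[:-1][same]
    isi = t1 - t0
    return pd.DataFrame(
        {
            "neuron_id": ids,
            "population": np.where(result.is_exc[ids], "exc", "inh"),
            "t_start": t0,
            "t_end": t1,
            "isi_ms": isi,
            "rate_hz": 1000.0 / isi,
        }
    )


def instantaneous_rates(result: SimulationResult, population: str = "all") -> np.ndarray:
    """Pooled instantaneous firing rates (spikes/s), one per ISI."""
    return isi_table(result, population)["rate_hz"].to_numpy()


def embedded_fi_scatter(
    result: SimulationResult,
    population: str = "all",
    spike_blank_ms: float = 1.0,
) -> pd.DataFrame:
    """Network-embedded f-I points: instantaneous rate vs mean input current.

    For every ISI of a recorded neuron the net input current (synaptic plus
    any bias) is averaged over the open interval between the two spikes,
    excluding ``spike_blank_ms`` around each spike peak so that the fast
    intrinsic spike currents do not contaminate the drive estimate.  ISIs
    whose blanked interior is empty are dropped.
    """
    if result.i_input.size == 0:
        raise ValueError("no per-neuron input current was recorded")
    table = isi_table(result, population)
    rec_pos = {int(n): i for i, n in enumerate(result.rec_indices)}
    bin_ms = result.bin_ms
    n_bins = result.i_input.shape[1]
    csum = np.concatenate(
        [np.zeros((result.i_input.shape[0], 1)), np.cumsum(result.i_input, axis=1)],
        axis=1,
    )
    rows = []
    for row in table.itertuples():
        pos = rec_pos.get(int(row.neuron_id))
        if pos is None:
            continue
        lo = int(np.ceil((row.t_start + spike_blank_ms) / bin_ms))
        hi = int(np.floor((row.t_end - spike_blank_ms) / bin_ms))
        if hi <= lo or hi > n_bins:
            continue
        mean_i = (csum[pos, hi] - csum[pos, lo]) / (hi - lo)
        rows.append(
            (row.neuron_id, row.population, row.isi_ms, row.rate_hz, mean_i)
        )
    return pd.DataFrame(
        rows,
        columns=["neuron_id", "population", "isi_ms", "rate_hz", "mean_current_na"],
    )
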