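"""Result persistence: HDF5 trace bundles and CSV exports."""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .config import config_from_dict, config_to_dict
from .network_sim import SimulationResult

__all__ = [
    "save_result",
    "load_result",
    "raster_to_csv",
    "raster_from_csv",
    "spectrum_to_csv",
]


def save_result(result: SimulationResult, path) -> None:
    """Write one trial's raster, traces and configuration to HDF5."""
    with h5py.File(path, "w") as fh:
        fh.attrs["config_json"] = json.dumps(config_to_dict(result.config))
        fh.attrs["config_hash"] = result.config_hash
        fh.attrs["seed"] = result.seed
        fh.attrs["bin_ms"] = result.bin_ms
        fh.attrs["dt_ms"] = result.config.dt
        fh.create_dataset("spike_neurons", data=result.spike_neurons)
        fh.create_dataset("spike_times", data=result.spike_times)
        fh.create_dataset("is_exc", data=result.is_exc)
        fh.create_dataset("t_bins", data=result.t_bins)
        fh.create_dataset("lambda", data=result.lam)
        fh.create_dataset("mean_abs_ampa", data=result.mean_abs_ampa)
        fh.create_dataset("mean_abs_gaba", data=result.mean_abs_gaba)
        fh.create_dataset("mean_ext_current", data=result.mean_ext_current)
        fh.create_dataset("rec_indices", data=result.rec_indices)
        fh.create_dataset("i_input", data=result.i_input, compression="gzip")
        fh.create_dataset("i_gaba", data=result.i_gaba, compression="gzip")
        fh.create_dataset("v_indices", data=result.v_indices)
        fh.create_dataset("v_traces", data=result.v_traces)


def load_result(path) -> SimulationResult:
    with h5py.File(path, "r") as fh:
        cfg = config_from_dict(json.loads(fh.attrs["config_json"]))
        return SimulationResult(
            config=cfg,
            seed=int(fh.attrs["seed"]),
            spike_neurons=fh["spike_neurons"][()],
            spike_times=fh["spike_times"][()],
            is_exc=fh["is_exc"][()].astype(bool),
            bin_ms=float(fh.attrs["bin_ms"]),
            t_bins=fh["t_bins"][()],
            lam=fh["lambda"][()],
            mean_abs_ampa=fh["mean_abs_ampa"][()],
            mean_abs_gaba=fh["mean_abs_gaba"][()],
            mean_ext_current=fh["mean_ext_current"][()],
            rec_indices=fh["rec_indices"][()],
            i_input=fh["i_input"][()],
            i_gaba=fh["i_gaba"][()],
            v_indices=fh["v_indices"][()],
            v_traces=fh["v_traces"][()],
        )


def raster_to_csv(result: SimulationResult, path) -> None:
    """Spike raster as ``neuron_id,time_ms,population``."""
    df = pd.DataFrame(
        {
            "neuron_id": result.spike_neurons,
            "time_ms": result.spike_times,
            "population": np.where(
                result.is_exc[result.spike_neurons], "exc", "inh"
            ),
        }
    )
    df.to_csv(path, index=False)


def raster_from_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def curve_to_csv(path, columns: dict, header_comment: str = "") -> None:
    """Two-(or more-)column CSV with ``#`` comment lines recording context."""
    names = list(columns)
    arrays = [np.asarray(columns[k]) for k in names]
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write(",".join(names) + "\n")
        for row in zip(*arrays):
            fh.write(",".join(f"{v:.8g}" for v in row) + "\n")


def spectrum_to_csv(spectrum, path, header_comment: str = "") -> None:
    """Power spectrum as ``freq_hz,power`` with an optional comment header."""
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("freq_hz,power\n")
        for f, p in zip(spectrum.freqs, spectrum.psd):
            fh.write(f"{f:.6g},{p:.8g}\n")
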