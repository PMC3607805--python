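"""Structured configuration loading and saving (YAML).

The config file mirrors the parameter tables of the model: sections
``neurons`` (per population), ``synapses`` (AMPA recurrent/external, GABA),
``network`` (size, composition, connectivity, delays), ``drive`` (external
OU-Poisson input), ``integration`` and ``recording``.
"""

from __future__ import annotations

import yaml

from .network_sim import (
    DelayParams,
    ExternalDriveParams,
    NetworkConfig,
    RecordingConfig,
    SynapseParams,
)
from .neuron_model import NeuronParams

__all__ = ["config_to_dict", "config_from_dict", "load_config", "save_config"]


def config_to_dict(cfg: NetworkConfig) -> dict:
    return {
        "neurons": {
            "excitatory": _neuron_dict(cfg.exc),
            "inhibitory": _neuron_dict(cfg.inh),
        },
        "synapses": {
            "ampa_recurrent": _syn_dict(cfg.ampa_recurrent),
            "ampa_external": _syn_dict(cfg.ampa_external),
            "gaba": _syn_dict(cfg.gaba),
        },
        "network": {
            "n_neurons": cfg.n_neurons,
            "frac_exc": cfg.frac_exc,
            "p_connect": cfg.p_connect,
            "delay_mean_ms": cfg.delay.mean,
            "delay_variance_ms2": cfg.delay.variance,
        },
        "drive": {
            "mean_rate": cfg.drive.mean_rate,
            "sigma": cfg.drive.sigma,
            "tau_ou": cfg.drive.tau_ou,
            "sigma_scale": cfg.drive.sigma_scale,
        },
        "integration": {
            "duration_ms": cfg.duration,
            "dt_ms": cfg.dt,
            "i_bias_na": cfg.i_bias,
        },
        "lfp": {"electrode_resistance_mohm": cfg.electrode_resistance},
        "recording": {
            "bin_ms": cfg.recording.bin_ms,
            "record_subset": list(cfg.recording.record_subset)
            if cfg.recording.record_subset is not None
            else None,
            "v_subset": list(cfg.recording.v_subset),
        },
    }


def _neuron_dict(p: NeuronParams) -> dict:
    return {
        "g_K_us": p.g_k,
        "g_Na_us": p.g_na,
        "g_L_us": p.g_l,
        "V_K_mv": p.v_k,
        "V_Na_mv": p.v_na,
        "V_L_mv": p.v_l,
        "C_m_nf": p.c_m,
        "temperature_c": p.temperature,
    }


def _syn_dict(s: SynapseParams) -> dict:
    return {
        "tau_r_ms": s.tau_r,
        "tau_d_ms": s.tau_d,
        "E_syn_mv": s.e_syn,
        "g_prime_ns": s.g_prime,
    }


def _neuron_from(d: dict, label: str) -> NeuronParams:
    return NeuronParams(
        g_k=d["g_K_us"],
        g_na=d["g_Na_us"],
        g_l=d["g_L_us"],
        v_k=d["V_K_mv"],
        v_na=d["V_Na_mv"],
        v_l=d["V_L_mv"],
        c_m=d["C_m_nf"],
        temperature=d["temperature_c"],
        label=label,
    )


def _syn_from(d: dict, kind: str) -> SynapseParams:
    return SynapseParams(
        tau_r=d["tau_r_ms"],
        tau_d=d["tau_d_ms"],
        e_syn=d["E_syn_mv"],
        g_prime=d["g_prime_ns"],
        kind=kind,
    )


def config_from_dict(d: dict) -> NetworkConfig:
    rec = d.get("recording", {})
    subset = rec.get("record_subset")
    return NetworkConfig(
        n_neurons=d["network"]["n_neurons"],
        frac_exc=d["network"]["frac_exc"],
        p_connect=d["network"]["p_connect"],
        exc=_neuron_from(d["neurons"]["excitatory"], "excitatory"),
        inh=_neuron_from(d["neurons"]["inhibitory"], "inhibitory"),
        ampa_recurrent=_syn_from(d["synapses"]["ampa_recurrent"], "AMPA_recurrent"),
        ampa_external=_syn_from(d["synapses"]["ampa_external"], "AMPA_external"),
        gaba=_syn_from(d["synapses"]["gaba"], "GABA"),
        delay=DelayParams(
            mean=d["network"]["delay_mean_ms"],
            variance=d["network"]["delay_variance_ms2"],
        ),
        drive=ExternalDriveParams(
            mean_rate=d["drive"]["mean_rate"],
            sigma=d["drive"]["sigma"],
            tau_ou=d["drive"]["tau_ou"],
            sigma_scale=d["drive"].get("sigma_scale", 1.0),
        ),
        duration=d["integration"]["duration_ms"],
        dt=d["integration"]["dt_ms"],
        i_bias=d["integration"].get("i_bias_na", 0.0),
        electrode_resistance=d.get("lfp", {}).get("electrode_resistance_mohm", 1.0),
        recording=RecordingConfig(
            bin_ms=rec.get("bin_ms", 1.0),
            record_subset=tuple(subset) if subset is not None else None,
            v_subset=tuple(rec.get("v_subset", ())),
        ),
    )


def apply_overrides(cfg: NetworkConfig, overrides: dict) -> NetworkConfig:
    """Apply dotted-path overrides (e.g. ``drive.mean_rate``) to a config."""
    d = config_to_dict(cfg)
    for path, value in overrides.items():
        node = d
        parts = path.split(".")
        for p in parts[:-1]:
            node = node[p]
        if parts[-1] not in node:
            raise KeyError(f"unknown config key: {path}")
        node[parts[-1]] = value
    return config_from_dict(d)


def load_config(path) -> NetworkConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def save_config(cfg: NetworkConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)
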