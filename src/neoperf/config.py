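"""Run configuration: one YAML profile covering every pipeline stage.

The packaged defaults reproduce the published operating point (5 s press /
10 s release / 3 cycles, 6 trials per subject, 64 hidden neurons, decision
threshold 0.5). A user YAML is deep-merged over the defaults; unknown keys
are rejected by name so typos fail loudly.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import json
from pathlib import Path

import yaml

from .indexes import IndexWindows
from .optics import ProbeGeometry, default_geometry
from .synthetic import SimConfig

__all__ = [
    "default_config",
    "load_config",
    "config_hash",
    "sim_config_from",
    "index_windows_from",
    "geometry_from",
    "protocol_kwargs_from",
]


def default_config() -> dict:
    ref = importlib.resources.files("neoperf.data") / "default_config.yaml"
    with importlib.resources.as_file(ref) as p:
        return yaml.safe_load(p.read_text())


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = dict(base)
    for key, value in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise KeyError(f"unknown configuration key: {here}")
        if isinstance(base[key], dict) and isinstance(value, dict):
            out[key] = _merge(base[key], value, here)
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Packaged defaults, optionally merged with a user YAML and overrides."""
    cfg = default_config()
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable digest of a configuration for run logs."""
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def sim_config_from(cfg: dict) -> SimConfig:
    p, s = cfg["protocol"], cfg["simulation"]
    return SimConfig(
        sampling_rate=p["sampling_rate_hz"],
        press_duration_s=p["press_duration_s"],
        release_duration_s=p["release_duration_s"],
        n_cycles=p["n_cycles"],
        trials_per_subject=p["trials_per_subject"],
        lead_in_s=s["lead_in_s"],
        tail_s=s["tail_s"],
        ramp_s=s["ramp_s"],
        timing_jitter_fraction=s["timing_jitter_fraction"],
        amplitude_jitter_fraction=s["amplitude_jitter_fraction"],
        pressure_noise_fraction=s["pressure_noise_fraction"],
        press_tau_s=s["press_tau_s"],
        recovery_ramp_s=s["recovery_ramp_s"],
        settle_tau_s=s["settle_tau_s"],
        between_subject_fraction=s["between_subject_fraction"],
        hbt_noise_sd=s["hbt_noise_sd"],
        sto2_noise_sd=s["sto2_noise_sd"],
    )


def index_windows_from(cfg: dict) -> IndexWindows:
    i = cfg["indexes"]
    return IndexWindows(
        baseline_s=i["baseline_window_s"],
        press_plateau_s=i["press_plateau_s"],
        recovery_plateau_s=i["recovery_plateau_s"],
        fit_window_s=i["fit_window_s"],
    )


def geometry_from(cfg: dict) -> ProbeGeometry:
    m = cfg["mbll"]
    return default_geometry(
        wavelengths_nm=tuple(m["wavelengths_nm"]),
        source_detector_distance_cm=m["source_detector_distance_cm"],
    )


def protocol_kwargs_from(cfg: dict) -> dict:
    p = cfg["protocol"]
    return {
        "n_cycles": p["n_cycles"],
        "threshold_fraction": p["threshold_fraction"],
        "debounce_s": p["debounce_s"],
        "press_duration_s": p["press_duration_s"],
        "release_duration_s": p["release_duration_s"],
        "timing_tolerance": p["timing_tolerance"],
        "baseline_window_s": p["baseline_window_s"],
        "min_baseline_s": p["min_baseline_s"],
    }
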