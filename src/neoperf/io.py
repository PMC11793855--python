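"""Readers and writers for trial CSVs, manifests, and tables.

A trial file is a delimited text table with header
``time_s, pressure, i700, i910`` — one row per sample, empty fields for
missing values. The incident optical reference is either a configured
constant (simulated cohorts, where it is known exactly) or estimated from
the earliest pre-press samples of the detected intensities themselves,
which turns every derived quantity into a change from baseline.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .optics import OpticalTrace
from .protocol import PressureTrace

TRIAL_COLUMNS = ("time_s", "pressure", "i700", "i910")


def write_trial_csv(path: str | Path, pressure: PressureTrace, optical: OpticalTrace) -> None:
    """Write one trial in the standard schema (fixed formatting, reproducible)."""
    df = pd.DataFrame(
        {
            "time_s": pressure.time,
            "pressure": pressure.pressure,
            "i700": optical.intensity_out[:, 0],
            "i910": optical.intensity_out[:, 1],
        }
    )
    df.to_csv(path, index=False, float_format="%.8f")


def read_trial_csv(
    path: str | Path,
    incident_mode: str = "baseline",
    incident_window_s: float = 1.0,
    incident_values: tuple[float, float] | None = None,
) -> tuple[PressureTrace, OpticalTrace]:
    """Read one trial CSV into pressure and optical traces.

    ``incident_mode="constant"`` divides by ``incident_values``;
    ``"baseline"`` uses the mean detected intensity over the first
    ``incident_window_s`` seconds as the per-channel incident reference, so
    optical densities are changes from the trial's own start.
    """
    df = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    time = df["time_s"].to_numpy(dtype=float)
    fs = 1.0 / float(np.median(np.diff(time)))
    pressure = df["pressure"].interpolate(limit_direction="both").to_numpy(dtype=float)
    i_out = df[["i700", "i910"]].to_numpy(dtype=float)
    if incident_mode == "constant":
        if incident_values is None:
            raise ValueError("incident_mode='constant' requires incident_values")
        i_in = np.asarray(incident_values, dtype=float)
    elif incident_mode == "baseline":
        n0 = max(1, int(round(incident_window_s * fs)))
        i_in = np.nanmean(i_out[:n0], axis=0)
    else:
        raise ValueError(f"unknown incident_mode {incident_mode!r}")
    return (
        PressureTrace(time=time, pressure=pressure, sampling_rate=fs),
        OpticalTrace(time=time, intensity_out=i_out, intensity_in=i_in, sampling_rate=fs),
    )


def write_manifest(path: str | Path, manifest: dict) -> None:
    Path(path).write_text(json.dumps(manifest, indent=1, sort_keys=True))


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
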