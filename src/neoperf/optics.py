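"""Modified Beer-Lambert law (MBLL) conversion of dual-wavelength NIRS intensities.

Reflected intensities at two wavelengths (700 and 910 nm by default, one on
each side of the ~800 nm oxy/deoxy-hemoglobin isosbestic point) are converted
to optical-density changes, inverted through the two-chromophore extinction
system to concentration changes ``dHbO2`` / ``dHb``, and combined into total
hemoglobin ``dHbT`` and tissue oxygen saturation ``dStO2``.

The inversion uses the normal-equations form

    [dHbO2, dHb]^T = (1/L) (E^T E)^{-1} E^T A,    A_k = dOD(lambda_k) / B(lambda_k)

with ``E`` the 2x2 matrix of molar extinction coefficients, ``L`` the
source-detector distance and ``B`` the differential pathlength factor.
Optical density is decadic: ``dOD = -log10(I_out / I_in)``.

Non-physical samples (zero or negative detected intensity, vanishing StO2
denominator) are marked missing with NaN and propagate through downstream
window statistics rather than raising.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "WavelengthChannel",
    "ProbeGeometry",
    "OpticalTrace",
    "HemoTrace",
    "load_extinction_table",
    "default_geometry",
    "compute_delta_od",
    "invert_mbll",
    "compute_hbt",
    "compute_sto2",
    "process_trace",
]

#: guard against near-singular extinction systems
DEFAULT_CONDITION_MAX = 1e8
#: |dHbO2 + dHb| below this marks the StO2 sample missing
DEFAULT_STO2_FLOOR = 1e-9


@dataclass(frozen=True)
class WavelengthChannel:
    """One optical channel: wavelength, extinction coefficients, pathlength factor.

    Extinction coefficients are in 1/(mM*cm); the pathlength factor B is the
    dimensionless differential-pathlength correction for that wavelength.
    """

    wavelength_nm: float
    eps_hbo2: float
    eps_hb: float
    pathlength_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength must be positive")
        if self.eps_hbo2 <= 0 or self.eps_hb <= 0:
            raise ValueError("extinction coefficients must be positive")
        if self.pathlength_factor <= 0:
            raise ValueError("pathlength factor must be positive")


@dataclass(frozen=True)
class ProbeGeometry:
    """Source-detector separation plus the two wavelength channels."""

    channels: tuple[WavelengthChannel, WavelengthChannel]
    source_detector_distance_cm: float = 1.0

    def __post_init__(self) -> None:
        if self.source_detector_distance_cm <= 0:
            raise ValueError("source-detector distance must be positive")
        if len(self.channels) != 2:
            raise ValueError("exactly two wavelength channels are required")
        if self.channels[0].wavelength_nm == self.channels[1].wavelength_nm:
            raise ValueError("the two channels must have distinct wavelengths")

    @property
    def extinction_matrix(self) -> np.ndarray:
        """2x2 matrix E with rows [eps_hbo2(lambda_k), eps_hb(lambda_k)]."""
        return np.array([[c.eps_hbo2, c.eps_hb] for c in self.channels])

    @property
    def pathlength_factors(self) -> np.ndarray:
        return np.array([c.pathlength_factor for c in self.channels])


def load_extinction_table(path: str | None = None) -> pd.DataFrame:
    """Load the extinction-coefficient table (packaged default or user CSV).

    Columns: ``wavelength_nm, eps_hbo2, eps_hb, b_factor``. The packaged values
    at 700 and 910 nm are standard literature compilation values in 1/(mM*cm).
    """
    if path is None:
        ref = importlib.resources.files("neoperf.data") / "extinction_coefficients.csv"
        with importlib.resources.as_file(ref) as p:
            return pd.read_csv(p)
    return pd.read_csv(path)


def default_geometry(
    wavelengths_nm: tuple[float, float] = (700.0, 910.0),
    source_detector_distance_cm: float = 1.0,
    table: pd.DataFrame | None = None,
) -> ProbeGeometry:
    """Build a :class:`ProbeGeometry` from the extinction table."""
    if table is None:
        table = load_extinction_table()
    channels = []
    for wl in wavelengths_nm:
        row = table[np.isclose(table["wavelength_nm"], wl)]
        if row.empty:
            raise ValueError(
                f"wavelength {wl} nm not found in extinction table "
                f"(available: {sorted(table['wavelength_nm'])})"
            )
        r = row.iloc[0]
        channels.append(
            WavelengthChannel(
                wavelength_nm=float(r["wavelength_nm"]),
                eps_hbo2=float(r["eps_hbo2"]),
                eps_hb=float(r["eps_hb"]),
                pathlength_factor=float(r.get("b_factor", 1.0)),
            )
        )
    return ProbeGeometry(channels=(channels[0], channels[1]),
                         source_detector_distance_cm=source_detector_distance_cm)


@dataclass
class OpticalTrace:
    """Time-aligned raw reflected intensities at the two wavelengths.

    ``intensity_out`` has shape (n_samples, 2); ``intensity_in`` is the
    per-channel incident reference, constant over the trial.
    """

    time: np.ndarray
    intensity_out: np.ndarray
    intensity_in: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.intensity_out = np.asarray(self.intensity_out, dtype=float)
        self.intensity_in = np.asarray(self.intensity_in, dtype=float)
        if self.time.ndim != 1 or self.time.size < 2:
            raise ValueError("time must be a 1-d sequence of length >= 2")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.intensity_out.shape != (self.time.size, 2):
            raise ValueError("intensity_out must have shape (n_samples, 2)")
        if self.intensity_in.shape != (2,) or np.any(self.intensity_in <= 0):
            raise ValueError("intensity_in must be two positive reals")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        dt = np.diff(self.time)
        if np.any(np.abs(dt * self.sampling_rate - 1.0) > 0.01):
            raise ValueError("time spacing inconsistent with sampling_rate (>1%)")

    def __len__(self) -> int:
        return self.time.size


@dataclass
class HemoTrace:
    """Derived hemoglobin time series; missing samples are NaN."""

    time: np.ndarray
    d_hbo2: np.ndarray
    d_hb: np.ndarray
    d_hbt: np.ndarray
    d_sto2: np.ndarray
    sampling_rate: float = field(default=0.0)

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in ("d_hbo2", "d_hb", "d_hbt", "d_sto2"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must match the length of time")
            setattr(self, name, arr)
        if self.sampling_rate <= 0:
            dt = np.median(np.diff(self.time))
            self.sampling_rate = 1.0 / dt

    def signal(self, name: str) -> np.ndarray:
        """Return the HbT or StO2 series by name."""
        key = name.lower()
        if key == "hbt":
            return self.d_hbt
        if key == "sto2":
            return self.d_sto2
        raise KeyError(f"unknown signal {name!r}; expected 'HbT' or 'StO2'")

    def __len__(self) -> int:
        return self.time.size


def compute_delta_od(trace: OpticalTrace, channel_index: int) -> np.ndarray:
    """Optical-density change ``-log10(I_out / I_in)`` for one channel.

    Zero or negative detected intensities are flagged as missing (NaN).
    """
    if channel_index not in (0, 1):
        raise IndexError("channel_index must be 0 or 1")
    i_out = trace.intensity_out[:, channel_index]
    i_in = trace.intensity_in[channel_index]
    od = np.full(i_out.shape, np.nan)
    valid = i_out > 0
    od[valid] = -np.log10(i_out[valid] / i_in)
    return od


def invert_mbll(
    delta_od_pair: tuple[np.ndarray, np.ndarray] | np.ndarray,
    geometry: ProbeGeometry,
    condition_max: float = DEFAULT_CONDITION_MAX,
) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares inversion of the two-wavelength attenuation system.

    Solves, per sample, ``[dHbO2, dHb]^T = (1/L) (E^T E)^{-1} E^T A`` with
    ``A_k = dOD(lambda_k) / B(lambda_k)``. Samples with a missing dOD in
    either channel come out missing in both concentrations.
    """
    a = np.vstack([np.asarray(delta_od_pair[0], dtype=float),
                   np.asarray(delta_od_pair[1], dtype=float)])
    if a.shape[0] != 2 or a.shape[1] < 1:
        raise ValueError("expected two equal-length delta-OD sequences")
    e = geometry.extinction_matrix
    cond = np.linalg.cond(e)
    if not np.isfinite(cond) or cond > condition_max:
        wls = [c.wavelength_nm for c in geometry.channels]
        raise np.linalg.LinAlgError(
            f"extinction matrix for wavelengths {wls} nm is ill-conditioned "
            f"(condition number {cond:.3g} > {condition_max:.3g}); "
            "check the extinction-coefficient table"
        )
    a = a / geometry.pathlength_factors[:, None]
    # normal-equations form, kept as written rather than a QR solve
    sol = np.linalg.solve(e.T @ e, e.T @ a) / geometry.source_detector_distance_cm
    return sol[0], sol[1]


def compute_hbt(d_hbo2: np.ndarray, d_hb: np.ndarray) -> np.ndarray:
    """Total-hemoglobin change: element-wise ``dHbO2 + dHb``."""
    d_hbo2 = np.asarray(d_hbo2, dtype=float)
    d_hb = np.asarray(d_hb, dtype=float)
    if d_hbo2.shape != d_hb.shape:
        raise ValueError("dHbO2 and dHb must have the same length")
    return d_hbo2 + d_hb


def compute_sto2(
    d_hbo2: np.ndarray,
    d_hb: np.ndarray,
    denominator_floor: float = DEFAULT_STO2_FLOOR,
) -> np.ndarray:
    """Tissue oxygen saturation, percent: ``100 * dHbO2 / (dHbO2 + dHb)``.

    Samples whose denominator magnitude falls below ``denominator_floor`` are
    marked missing instead of emitting huge or infinite ratios.
    """
    d_hbo2 = np.asarray(d_hbo2, dtype=float)
    d_hb = np.asarray(d_hb, dtype=float)
    if d_hbo2.shape != d_hb.shape:
        raise ValueError("dHbO2 and dHb must have the same length")
    denom = d_hbo2 + d_hb
    out = np.full(denom.shape, np.nan)
    ok = np.abs(denom) > denominator_floor
    out[ok] = 100.0 * d_hbo2[ok] / denom[ok]
    return out


def process_trace(
    trace: OpticalTrace,
    geometry: ProbeGeometry,
    denominator_floor: float = DEFAULT_STO2_FLOOR,
    condition_max: float = DEFAULT_CONDITION_MAX,
) -> HemoTrace:
    """Full MBLL conversion of an optical trace into a :class:`HemoTrace`."""
    od = (compute_delta_od(trace, 0), compute_delta_od(trace, 1))
    d_hbo2, d_hb = invert_mbll(od, geometry, condition_max=condition_max)
    d_hbt = compute_hbt(d_hbo2, d_hb)
    d_sto2 = compute_sto2(d_hbo2, d_hb, denominator_floor=denominator_floor)
    return HemoTrace(
        time=trace.time,
        d_hbo2=d_hbo2,
        d_hb=d_hb,
        d_hbt=d_hbt,
        d_sto2=d_sto2,
        sampling_rate=trace.sampling_rate,
    )
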