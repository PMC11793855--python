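"""Perfusion indexes I-VII extracted from a pressure-modulated hemoglobin trace.

Given a segmented trial, seven scalar indexes summarize one signal (HbT or
StO2):

* I   - baseline window mean (initial circulation state),
* II  - mean press-plateau level across cycles (perfusion under occlusion),
* III - mean recovery-plateau level across cycles (recovered perfusion),
* IV  - III minus I (recovery deficit),
* V   - first-cycle press plateau minus the mean of the repeat-cycle plateaus,
* VI  - mean early-recovery slope across cycles (reperfusion rate, units/s),
* VII - first-cycle recovery slope minus the mean of the repeat-cycle slopes.

Plateau levels are means over windows placed at the end of each press /
release epoch (avoiding the transition transients); the recovery slope is an
ordinary-least-squares line fit over the first seconds after each release.
All window lengths are configurable through :class:`IndexWindows`.

The classifier feature vector is the fixed-order quintuple
[HbT-I, HbT-II, HbT-III, HbT-VI, StO2-VII].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .optics import HemoTrace
from .protocol import PressCycle, ProtocolSegmentation

__all__ = [
    "IndexWindows",
    "PerfusionIndexSet",
    "FEATURE_NAMES",
    "window_mean",
    "recovery_rate",
    "compute_indexes",
    "build_features",
]

FEATURE_NAMES = (
    "hbt_index_i",
    "hbt_index_ii",
    "hbt_index_iii",
    "hbt_index_vi",
    "sto2_index_vii",
)


@dataclass(frozen=True)
class IndexWindows:
    """Window lengths (seconds) used by the index estimators."""

    baseline_s: float = 3.0
    press_plateau_s: float = 2.0
    recovery_plateau_s: float = 3.0
    fit_window_s: float = 2.0


@dataclass(frozen=True)
class PerfusionIndexSet:
    """Indexes I-VII for one signal of one trial.

    Index V and VII require at least two cycles and are NaN otherwise.
    """

    signal_name: str
    index_i: float
    index_ii: float
    index_iii: float
    index_iv: float
    index_v: float
    index_vi: float
    index_vii: float

    def as_dict(self) -> dict[str, float]:
        return {
            "index_i": self.index_i,
            "index_ii": self.index_ii,
            "index_iii": self.index_iii,
            "index_iv": self.index_iv,
            "index_v": self.index_v,
            "index_vi": self.index_vi,
            "index_vii": self.index_vii,
        }


def window_mean(signal: np.ndarray, start: int, stop: int) -> float:
    """Mean of ``signal[start:stop]`` over non-missing samples.

    Raises if the window is empty or entirely missing.
    """
    window = np.asarray(signal, dtype=float)[start:stop]
    valid = window[~np.isnan(window)]
    if valid.size == 0:
        raise ValueError(f"window [{start}, {stop}) contains no valid samples")
    return float(valid.mean())


def recovery_rate(
    signal: np.ndarray,
    time: np.ndarray,
    cycle: PressCycle,
    sampling_rate: float,
    fit_window_s: float = 2.0,
) -> float:
    """Early-recovery slope (units/s): OLS line fit just after the release.

    Fits ``signal`` against ``time`` over the first ``fit_window_s`` seconds
    following the press offset; at least three non-missing samples required.
    """
    signal = np.asarray(signal, dtype=float)
    start = cycle.press_offset
    stop = min(start + int(round(fit_window_s * sampling_rate)), cycle.release_offset)
    y = signal[start:stop]
    t = np.asarray(time, dtype=float)[start:stop]
    ok = ~np.isnan(y)
    if ok.sum() < 3:
        raise ValueError(
            f"recovery fit window [{start}, {stop}) has {int(ok.sum())} valid "
            "samples (need >= 3)"
        )
    slope = np.polyfit(t[ok], y[ok], 1)[0]
    return float(slope)


def compute_indexes(
    hemo: HemoTrace,
    seg: ProtocolSegmentation,
    signal_name: str = "HbT",
    windows: IndexWindows = IndexWindows(),
) -> PerfusionIndexSet:
    """Indexes I-VII of one signal from a segmented trial."""
    sig = hemo.signal(signal_name)
    fs = hemo.sampling_rate
    plateau = int(round(windows.press_plateau_s * fs))
    rec_plateau = int(round(windows.recovery_plateau_s * fs))
    base_start = max(seg.baseline_start,
                     seg.baseline_end - int(round(windows.baseline_s * fs)))

    index_i = window_mean(sig, base_start, seg.baseline_end)
    press_means = [
        window_mean(sig, max(c.press_onset, c.press_offset - plateau), c.press_offset)
        for c in seg.cycles
    ]
    rec_means = [
        window_mean(sig, max(c.press_offset, c.release_offset - rec_plateau),
                    c.release_offset)
        for c in seg.cycles
    ]
    rates = [
        recovery_rate(sig, hemo.time, c, fs, windows.fit_window_s)
        for c in seg.cycles
    ]

    index_ii = float(np.mean(press_means))
    index_iii = float(np.mean(rec_means))
    index_iv = index_iii - index_i
    index_vi = float(np.mean(rates))
    if len(seg.cycles) >= 2:
        index_v = press_means[0] - float(np.mean(press_means[1:]))
        index_vii = rates[0] - float(np.mean(rates[1:]))
    else:
        index_v = float("nan")
        index_vii = float("nan")
    return PerfusionIndexSet(
        signal_name=signal_name,
        index_i=index_i,
        index_ii=index_ii,
        index_iii=index_iii,
        index_iv=index_iv,
        index_v=index_v,
        index_vi=index_vi,
        index_vii=index_vii,
    )


def build_features(
    hbt: PerfusionIndexSet,
    sto2: PerfusionIndexSet,
) -> np.ndarray:
    """Classifier feature vector [HbT-I, HbT-II, HbT-III, HbT-VI, StO2-VII].

    Raises if any constituent index is undefined.
    """
    vec = np.array([
        hbt.index_i,
        hbt.index_ii,
        hbt.index_iii,
        hbt.index_vi,
        sto2.index_vii,
    ])
    if np.any(np.isnan(vec)):
        missing = [FEATURE_NAMES[i] for i in np.flatnonzero(np.isnan(vec))]
        raise ValueError(f"undefined feature component(s): {missing}")
    return vec
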