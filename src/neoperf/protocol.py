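"""Segmentation of the press/release pressure protocol.

The clinical procedure applies pressure to the probe for 5 s, releases for
10 s, and repeats three times per trial. Segmentation finds the press epochs
as maximal runs of the pressure signal above a relative threshold, debounces
sensor chatter, and checks the detected timing against the nominal protocol.

The threshold is relative to the robust dynamic range (5th to 95th pressure
percentile), so segmentation is invariant to affine rescaling of the sensor
signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ProtocolError",
    "PressureTrace",
    "PressCycle",
    "ProtocolSegmentation",
    "ProtocolReport",
    "segment_protocol",
    "validate_protocol",
]


class ProtocolError(ValueError):
    """Raised when a pressure trace cannot be segmented into the protocol."""


@dataclass
class PressureTrace:
    time: np.ndarray
    pressure: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        if self.time.shape != self.pressure.shape:
            raise ValueError("time and pressure must have equal length")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    def __len__(self) -> int:
        return self.time.size


@dataclass(frozen=True)
class PressCycle:
    """Sample indices of one press/release cycle; windows are half-open."""

    press_onset: int
    press_offset: int
    release_offset: int

    def __post_init__(self) -> None:
        if not self.press_onset < self.press_offset < self.release_offset:
            raise ValueError("cycle indices must satisfy onset < offset < release end")

    def press_duration_s(self, sampling_rate: float) -> float:
        return (self.press_offset - self.press_onset) / sampling_rate

    def release_duration_s(self, sampling_rate: float) -> float:
        return (self.release_offset - self.press_offset) / sampling_rate


@dataclass
class ProtocolSegmentation:
    cycles: list[PressCycle]
    baseline_start: int
    baseline_end: int
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.baseline_end > min(c.press_onset for c in self.cycles):
            raise ValueError("baseline must end before the first press onset")
        for a, b in zip(self.cycles, self.cycles[1:]):
            if a.release_offset > b.press_onset:
                raise ValueError("cycles must be time-ordered and non-overlapping")

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)


@dataclass
class ProtocolReport:
    """Per-cycle timing versus the nominal protocol."""

    press_durations_s: list[float]
    release_durations_s: list[float]
    inter_cycle_gaps_s: list[float]
    press_ok: list[bool]
    release_ok: list[bool]

    @property
    def ok(self) -> bool:
        return all(self.press_ok) and all(self.release_ok)


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) runs of True in a boolean mask."""
    idx = np.flatnonzero(np.diff(np.concatenate(([False], mask, [False])).astype(int)))
    return list(zip(idx[0::2], idx[1::2]))


def segment_protocol(
    trace: PressureTrace,
    n_cycles: int = 3,
    threshold_fraction: float = 0.5,
    debounce_s: float = 0.25,
    press_duration_s: float = 5.0,
    release_duration_s: float = 10.0,
    timing_tolerance: float = 0.2,
    baseline_window_s: float = 3.0,
    min_baseline_s: float = 1.0,
) -> ProtocolSegmentation:
    """Detect the press/release cycles of the pressure protocol.

    Press epochs are maximal runs where the pressure exceeds
    ``lo + threshold_fraction * (hi - lo)`` with ``hi``/``lo`` the 95th/5th
    percentiles. Runs separated by gaps shorter than ``debounce_s`` are
    merged; runs shorter than ``debounce_s`` are dropped. Exactly ``n_cycles``
    cycles are returned (the longest ones if the detector finds more);
    fewer raises :class:`ProtocolError`.
    """
    p = trace.pressure
    fs = trace.sampling_rate
    lo, hi = np.percentile(p, [5, 95])
    if hi - lo <= 0:
        raise ProtocolError("pressure signal has no dynamic range (flat trace)")
    thr = lo + threshold_fraction * (hi - lo)

    runs = _runs_above(p > thr)
    debounce = max(1, int(round(debounce_s * fs)))
    # merge runs separated by short gaps
    merged: list[tuple[int, int]] = []
    for start, stop in runs:
        if merged and start - merged[-1][1] < debounce:
            merged[-1] = (merged[-1][0], stop)
        else:
            merged.append((start, stop))
    merged = [(a, b) for a, b in merged if b - a >= debounce]

    if len(merged) < n_cycles:
        epochs = [(a / fs, b / fs) for a, b in merged]
        raise ProtocolError(
            f"detected {len(merged)} press epoch(s), expected {n_cycles}; "
            f"epochs (s): {epochs}"
        )
    warnings: list[str] = []
    if len(merged) > n_cycles:
        warnings.append(
            f"detected {len(merged)} press epochs; keeping the {n_cycles} longest"
        )
        merged = sorted(sorted(merged, key=lambda r: r[1] - r[0])[-n_cycles:])

    release_samples = int(round(release_duration_s * fs))
    cycles = []
    for i, (start, stop) in enumerate(merged):
        if i + 1 < len(merged):
            rel_end = merged[i + 1][0]
        else:
            rel_end = min(stop + release_samples, len(trace))
        cycles.append(PressCycle(start, stop, rel_end))

    first = cycles[0].press_onset
    base_start = max(0, first - int(round(baseline_window_s * fs)))
    if (first - base_start) / fs < min_baseline_s:
        raise ProtocolError(
            f"only {(first - base_start) / fs:.2f} s of pre-press baseline "
            f"available (need >= {min_baseline_s} s)"
        )

    for i, c in enumerate(cycles):
        pd_s = c.press_duration_s(fs)
        rd_s = c.release_duration_s(fs)
        if abs(pd_s - press_duration_s) > timing_tolerance * press_duration_s:
            warnings.append(
                f"cycle {i + 1}: press duration {pd_s:.2f} s outside "
                f"{press_duration_s} s +/- {timing_tolerance:.0%}"
            )
        # the last release may be truncated by the end of the trace
        if i + 1 < len(cycles) and abs(rd_s - release_duration_s) > (
            timing_tolerance * release_duration_s
        ):
            warnings.append(
                f"cycle {i + 1}: release duration {rd_s:.2f} s outside "
                f"{release_duration_s} s +/- {timing_tolerance:.0%}"
            )
    return ProtocolSegmentation(cycles, base_start, first, warnings)


def validate_protocol(
    seg: ProtocolSegmentation,
    trace: PressureTrace,
    press_duration_s: float = 5.0,
    release_duration_s: float = 10.0,
    timing_tolerance: float = 0.2,
) -> ProtocolReport:
    """Timing conformance of a segmentation against the nominal protocol."""
    fs = trace.sampling_rate
    press = [c.press_duration_s(fs) for c in seg.cycles]
    release = [c.release_duration_s(fs) for c in seg.cycles]
    gaps = [
        (b.press_onset - a.press_offset) / fs
        for a, b in zip(seg.cycles, seg.cycles[1:])
    ]
    press_ok = [abs(d - press_duration_s) <= timing_tolerance * press_duration_s
                for d in press]
    release_ok = [
        abs(d - release_duration_s) <= timing_tolerance * release_duration_s
        for d in release
    ]
    return ProtocolReport(press, release, gaps, press_ok, release_ok)


def segmentation_to_dict(seg: ProtocolSegmentation, sampling_rate: float) -> dict:
    """JSON-friendly representation (sample indices and seconds)."""
    return {
        "baseline": {
            "start": int(seg.baseline_start),
            "end": int(seg.baseline_end),
            "start_s": seg.baseline_start / sampling_rate,
            "end_s": seg.baseline_end / sampling_rate,
        },
        "cycles": [
            {
                "press_onset": int(c.press_onset),
                "press_offset": int(c.press_offset),
                "release_offset": int(c.release_offset),
                "press_onset_s": c.press_onset / sampling_rate,
                "press_offset_s": c.press_offset / sampling_rate,
                "release_offset_s": c.release_offset / sampling_rate,
            }
            for c in seg.cycles
        ],
        "warnings": list(seg.warnings),
    }
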