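"""Event detection in electrophysiology traces, sweep QC and shift computation.

The whole method stands or falls with the per-sweep measurement of the
triggering event's latency: the patch-pipette recording (typically 40 kHz)
gives each action potential's time far more precisely than any camera frame.
Two detection conventions are supported — the AP *peak* (sample of the local
voltage maximum) and the AP *threshold* (first sample where dV/dt crosses a
slope criterion on the rising phase).  Sweeps with no event or more than one
event are rejected; the per-sweep alignment shift is the reference time minus
that sweep's event time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple, Union

import numpy as np
from scipy.signal import find_peaks

from .signal_model import EphysTrace

__all__ = [
    "EventDetectionConfig",
    "detect_events",
    "qc_sweeps",
    "compute_shifts",
    "frame_times_from_ttl",
    "flag_jitter_outliers",
]


@dataclass(frozen=True)
class EventDetectionConfig:
    """How to locate the triggering action potential in a voltage trace.

    mode
        ``"peak"``: event time is the sample of the local voltage maximum.
        ``"threshold"``: event time is the first upward crossing of the
        dV/dt criterion within ``refractory_s`` before a qualifying peak.
    peak_min_mv
        Minimum voltage for a local maximum to count as an AP (APs overshoot
        0 mV, so the default rejects subthreshold bumps).
    dvdt_threshold_v_per_s
        Slope criterion for threshold mode, in volts per second.
    refractory_s
        Minimum separation between detected events, and the backward search
        window for the threshold crossing.
    """

    mode: str = "peak"
    peak_min_mv: float = 0.0
    dvdt_threshold_v_per_s: float = 20.0
    refractory_s: float = 0.005

    def __post_init__(self) -> None:
        if self.mode not in ("peak", "threshold"):
            raise ValueError(f"unknown detection mode {self.mode!r}")
        if self.dvdt_threshold_v_per_s <= 0:
            raise ValueError("dvdt_threshold_v_per_s must be positive")
        if self.refractory_s <= 0:
            raise ValueError("refractory_s must be positive")


def detect_events(trace: EphysTrace, cfg: EventDetectionConfig) -> List[float]:
    """Detect AP times (seconds, ascending) in ``trace`` per ``cfg``.

    Returns an empty list when nothing qualifies (that is not an error: QC
    discards such sweeps downstream).
    """
    v = trace.voltage
    if v.size == 0:
        raise ValueError("empty electrophysiology trace")
    distance = max(1, int(round(cfg.refractory_s * trace.rate_hz)))
    height = None if np.isneginf(cfg.peak_min_mv) else cfg.peak_min_mv
    peaks, _ = find_peaks(v, height=height, distance=distance)
    if cfg.mode == "peak":
        return [trace.t0_s + int(p) / trace.rate_hz for p in peaks]
    # threshold mode: forward two-point derivative, mV * Hz -> V/s
    dvdt = np.diff(v) * trace.rate_hz / 1000.0
    thr = cfg.dvdt_threshold_v_per_s
    events: List[float] = []
    for p in peaks:
        lo = max(0, int(p) - distance)
        seg = dvdt[lo:p]
        above = seg >= thr
        crossing = None
        for i in np.flatnonzero(above):
            if i == 0 and lo == 0:
                crossing = lo + i
                break
            prev = dvdt[lo + i - 1] if lo + i - 1 >= 0 else -np.inf
            if prev < thr:
                crossing = lo + int(i)
                break
        if crossing is not None:
            events.append(trace.t0_s + crossing / trace.rate_hz)
    return sorted(events)


def qc_sweeps(
    events_per_sweep: Sequence[Sequence[float]],
) -> Tuple[List[bool], Dict[str, int]]:
    """Pass exactly-one-event sweeps; report discard counts by reason.

    Returns ``(flags, report)`` where ``report`` counts ``accepted``,
    ``no_event`` and ``multiple_events`` sweeps.
    """
    flags = [len(ev) == 1 for ev in events_per_sweep]
    report = {
        "accepted": sum(flags),
        "no_event": sum(1 for ev in events_per_sweep if len(ev) == 0),
        "multiple_events": sum(1 for ev in events_per_sweep if len(ev) > 1),
    }
    return flags, report


def compute_shifts(
    event_times_s: Sequence[float],
    reference: Union[str, float] = "mean",
) -> np.ndarray:
    """Per-sweep alignment shifts ``reference_time - event_time`` (seconds).

    ``reference`` is ``"mean"`` (default; keeps the reconstructed event
    centred), ``"first_sweep"``, or an explicit time in seconds.  Adding
    ``shifts[i]`` to sweep *i*'s frame times brings all events to the
    reference time.
    """
    times = np.asarray(event_times_s, dtype=float)
    if times.size == 0:
        raise ValueError("no event times given")
    if isinstance(reference, str):
        if reference == "mean":
            ref = float(times.mean())
        elif reference == "first_sweep":
            ref = float(times[0])
        else:
            raise ValueError(f"unknown reference mode {reference!r}")
    elif reference is None:
        raise ValueError("explicit reference mode requires a time")
    else:
        ref = float(reference)
    return ref - times


def frame_times_from_ttl(ttl: np.ndarray, rate_hz: float, t0_s: float = 0.0) -> np.ndarray:
    """Frame-readout times from a TTL trace: rising crossings of half-max.

    The threshold is the midpoint of the trace's min and max; a frame time is
    the time of the first sample at or above threshold in each rising edge.
    """
    ttl = np.asarray(ttl, dtype=float)
    if ttl.size < 2:
        raise ValueError("TTL trace too short")
    half = (ttl.min() + ttl.max()) / 2.0
    above = ttl >= half
    rising = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if above[0]:
        rising = np.insert(rising, 0, 0)
    return t0_s + rising / rate_hz


def flag_jitter_outliers(shifts_s: Sequence[float], bound_s: float = 0.005) -> np.ndarray:
    """Flag sweeps whose |shift| exceeds ``bound_s`` (default 5 ms).

    Triggered APs jitter by a few milliseconds at most; a much larger shift
    usually means a misdetected event.  Flagged sweeps are reported, not
    silently used.
    """
    shifts = np.asarray(shifts_s, dtype=float)
    flagged = np.abs(shifts) > bound_s
    if np.any(flagged):
        warnings.warn(
            f"{int(flagged.sum())} sweep shift(s) exceed {bound_s * 1e3:.1f} ms",
            stacklevel=2,
        )
    return flagged
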