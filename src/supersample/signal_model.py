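"""Shared domain types and the master high-resolution time base.

Every alignment and accumulation step in the shift-and-mean pipeline happens
on a single discrete high-resolution (HR) grid, normally the clock of the
electrophysiology acquisition (e.g. 40 kHz).  Times are seconds (float)
at the API surface and integer ticks internally; all bin conventions are
half-open ``[k/R, (k+1)/R)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

__all__ = [
    "TimeBase",
    "Sweep",
    "SuperSampledSignal",
    "ResampledSignal",
    "EphysTrace",
    "FitResult",
    "time_to_tick",
    "tick_to_time",
]


@dataclass(frozen=True)
class TimeBase:
    """Uniform high-resolution clock: tick ``k`` is at ``origin_s + k / rate_hz``.

    Parameters
    ----------
    rate_hz
        Sampling rate of the grid in Hz; must be positive.
    origin_s
        Time of tick 0, in seconds.
    n_ticks
        Number of ticks on the grid (non-negative).
    """

    rate_hz: float
    origin_s: float = 0.0
    n_ticks: int = 0

    def __post_init__(self) -> None:
        if not self.rate_hz > 0:
            raise ValueError(f"rate_hz must be positive, got {self.rate_hz}")
        if self.n_ticks < 0:
            raise ValueError(f"n_ticks must be non-negative, got {self.n_ticks}")

    @property
    def duration_s(self) -> float:
        return self.n_ticks / self.rate_hz

    def tick_times(self) -> np.ndarray:
        """Times of all ticks, in seconds."""
        return self.origin_s + np.arange(self.n_ticks) / self.rate_hz


def time_to_tick(t, tb: TimeBase, *, bounds_check: bool = False):
    """Quantize time(s) ``t`` (seconds) to the nearest tick of ``tb``.

    Ties (exact half-tick offsets) round half away from zero.  Scalar in,
    scalar out; array in, int array out.

    Raises
    ------
    ValueError
        If ``bounds_check`` is true and any result falls outside
        ``[0, tb.n_ticks)``.
    """
    x = (np.asarray(t, dtype=float) - tb.origin_s) * tb.rate_hz
    ticks = np.sign(x) * np.floor(np.abs(x) + 0.5)
    ticks = ticks.astype(np.int64)
    if bounds_check:
        bad = (ticks < 0) | (ticks >= tb.n_ticks)
        if np.any(bad):
            raise ValueError(
                f"{int(np.sum(bad))} time(s) map outside [0, {tb.n_ticks}) ticks"
            )
    if np.isscalar(t) or np.ndim(t) == 0:
        return int(ticks)
    return ticks


def tick_to_time(k, tb: TimeBase):
    """Nominal time (seconds) of tick(s) ``k``."""
    return tb.origin_s + np.asarray(k) / tb.rate_hz


@dataclass
class Sweep:
    """One trial's ROI fluorescence trace with its frame timing.

    ``frame_times_s`` must be strictly increasing and the same length as
    ``values``.  ``event_time_s`` is the detected triggering-event time for
    this sweep (None if not yet detected / not detectable).
    """

    sweep_id: str
    frame_times_s: np.ndarray
    values: np.ndarray
    event_time_s: Optional[float] = None
    qc_pass: bool = True

    def __post_init__(self) -> None:
        self.frame_times_s = np.asarray(self.frame_times_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.frame_times_s.shape != self.values.shape:
            raise ValueError(
                f"sweep {self.sweep_id!r}: {len(self.values)} values for "
                f"{len(self.frame_times_s)} frame times"
            )
        if self.frame_times_s.size > 1 and not np.all(np.diff(self.frame_times_s) > 0):
            raise ValueError(f"sweep {self.sweep_id!r}: frame times not strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.values)


@dataclass
class SuperSampledSignal:
    """Non-uniform accumulation of aligned sweeps on the HR grid.

    ``value_sum[k]`` is the sum of all fluorescence values contributed to
    tick ``k``; ``weight[k]`` counts the contributing sweeps ("the precision
    of each point").  The per-tick mean is ``value_sum / weight`` wherever
    ``weight > 0``.
    """

    timebase: TimeBase
    value_sum: np.ndarray
    weight: np.ndarray
    n_dropped_frames: int = 0

    def __post_init__(self) -> None:
        self.value_sum = np.asarray(self.value_sum, dtype=float)
        self.weight = np.asarray(self.weight, dtype=np.int64)
        n = self.timebase.n_ticks
        if len(self.value_sum) != n or len(self.weight) != n:
            raise ValueError("value_sum and weight must have length timebase.n_ticks")
        if np.any(self.weight < 0):
            raise ValueError("weights must be non-negative")
        if np.any(self.value_sum[self.weight == 0] != 0):
            raise ValueError("value_sum must be 0 where weight is 0")

    @property
    def total_weight(self) -> int:
        return int(self.weight.sum())


@dataclass
class ResampledSignal:
    """Uniform-rate weighted-mean signal with explicit missing-bin bookkeeping.

    Bin ``b`` covers times ``origin_s + [b/rate_hz, (b+1)/rate_hz)``; its
    nominal time is the bin start.  ``values`` is NaN where ``missing_mask``
    is true unless the signal has been gap-filled (``filled`` set), in which
    case ``missing_mask`` still records the originally empty bins.
    """

    rate_hz: float
    values: np.ndarray
    bin_weight: np.ndarray
    missing_mask: np.ndarray
    origin_s: float = 0.0
    filled: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.bin_weight = np.asarray(self.bin_weight, dtype=np.int64)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n = len(self.values)
        if len(self.bin_weight) != n or len(self.missing_mask) != n:
            raise ValueError("values, bin_weight and missing_mask must share a length")
        if np.any(self.bin_weight < 0):
            raise ValueError("bin weights must be non-negative")
        present = ~self.missing_mask
        if not np.all(np.isfinite(self.values[present])):
            raise ValueError("values must be finite where not missing")

    @property
    def n_bins(self) -> int:
        return len(self.values)

    @property
    def coverage(self) -> float:
        """Fraction of bins that received at least one sample."""
        return float(np.mean(self.bin_weight > 0)) if self.n_bins else 0.0

    def bin_times_s(self) -> np.ndarray:
        return self.origin_s + np.arange(self.n_bins) / self.rate_hz


@dataclass
class EphysTrace:
    """Uniformly sampled membrane-potential recording (mV) for event detection."""

    rate_hz: float
    t0_s: float
    voltage: np.ndarray

    def __post_init__(self) -> None:
        self.voltage = np.asarray(self.voltage, dtype=float)
        if not self.rate_hz > 0:
            raise ValueError("rate_hz must be positive")
        if not np.all(np.isfinite(self.voltage)):
            raise ValueError("voltage samples must be finite")

    @property
    def n_samples(self) -> int:
        return len(self.voltage)

    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n_samples) / self.rate_hz


@dataclass
class FitResult:
    """Outcome of a nonlinear least-squares fit."""

    params: Mapping[str, float]
    residual_rms: float
    converged: bool
    n_points: int
    message: str = ""

    def __post_init__(self) -> None:
        if self.residual_rms < 0:
            raise ValueError("residual_rms must be non-negative")
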