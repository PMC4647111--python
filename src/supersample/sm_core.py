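"""The shift-and-mean engine: accumulate aligned sweeps, resample by weighted mean.

Accumulation places every frame of every accepted sweep on the discrete HR
grid (after applying its per-sweep alignment shift) and stores, per tick, the
*sum* of contributed values and the count of contributing sweeps (the
"weight").  Resampling to any coarser uniform rate is then a single weighted
division per bin: sum of value sums over the bin's ticks divided by the sum
of weights.  Storing sums rather than means makes the conservation identity
``sum(values * bin_weight) == sum(value_sum)`` exact at every target rate.

Bins are half-open on time: bin ``b`` of rate ``R`` covers ticks whose
nominal time falls in ``[b/R, (b+1)/R)`` relative to the grid origin.
Empty bins are reported as missing and may be filled by linear
interpolation (with nearest-value hold at the ends).
"""

from __future__ import annotations

from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .signal_model import (
    ResampledSignal,
    SuperSampledSignal,
    Sweep,
    TimeBase,
    time_to_tick,
)

__all__ = [
    "accumulate",
    "resample",
    "fill_gaps",
    "reconstruct",
    "max_reconstruction_rate_hz",
]


def accumulate(
    sweeps: Sequence[Sweep],
    shifts_s: Sequence[float],
    tb: TimeBase,
) -> SuperSampledSignal:
    """Accumulate aligned sweeps onto the HR grid of ``tb``.

    For every frame of every sweep, the frame time plus the sweep's alignment
    shift is quantized to the nearest HR tick; the frame value is added to
    that tick's ``value_sum`` and its ``weight`` is incremented.  Frames that
    map outside ``[0, n_ticks)`` are dropped and counted in
    ``n_dropped_frames``.

    Raises
    ------
    ValueError
        If two frames of the *same* sweep land on the same tick (the grid is
        too coarse for the camera rate), or if the shift count mismatches.
    """
    if len(sweeps) != len(shifts_s):
        raise ValueError(f"{len(sweeps)} sweeps but {len(shifts_s)} shifts")
    value_sum = np.zeros(tb.n_ticks)
    weight = np.zeros(tb.n_ticks, dtype=np.int64)
    dropped = 0
    # deterministic sweep order so floating-point sums are reproducible
    for sweep, shift in zip(sweeps, shifts_s):
        ticks = time_to_tick(sweep.frame_times_s + shift, tb)
        ticks = np.atleast_1d(ticks)
        in_range = (ticks >= 0) & (ticks < tb.n_ticks)
        dropped += int(np.sum(~in_range))
        kept = ticks[in_range]
        if len(np.unique(kept)) != len(kept):
            raise ValueError(
                f"sweep {sweep.sweep_id!r}: multiple frames map to one tick; "
                f"the time base ({tb.rate_hz} Hz) is too coarse for the frame rate"
            )
        np.add.at(value_sum, kept, sweep.values[in_range])
        np.add.at(weight, kept, 1)
    return SuperSampledSignal(
        timebase=tb, value_sum=value_sum, weight=weight, n_dropped_frames=dropped
    )


def _bin_of_ticks(n_ticks: int, hr_rate: float, target_rate: float) -> np.ndarray:
    """Half-open bin index for each HR tick at the target rate.

    Integer rates use exact integer arithmetic so ticks sitting exactly on a
    bin boundary are never mis-assigned by floating-point round-off.
    """
    k = np.arange(n_ticks, dtype=np.int64)
    if float(hr_rate).is_integer() and float(target_rate).is_integer():
        return (k * int(target_rate)) // int(hr_rate)
    return np.floor(k * (target_rate / hr_rate) * (1 + 1e-12)).astype(np.int64)


def _n_bins(n_ticks: int, hr_rate: float, target_rate: float) -> int:
    if float(hr_rate).is_integer() and float(target_rate).is_integer():
        return int(-((-n_ticks * int(target_rate)) // int(hr_rate)))
    return int(np.ceil(n_ticks * target_rate / hr_rate - 1e-12))


def resample(ss: SuperSampledSignal, target_rate_hz: float) -> ResampledSignal:
    """Resample the accumulated signal to a uniform ``target_rate_hz``.

    Bin ``b`` covers HR ticks with time in ``[b/R, (b+1)/R)``; its value is
    the weighted mean ``sum(value_sum) / sum(weight)`` over those ticks.
    Bins receiving no sample are flagged missing (value NaN).
    """
    tb = ss.timebase
    if target_rate_hz > tb.rate_hz:
        raise ValueError(
            f"target rate {target_rate_hz} Hz exceeds the HR grid rate {tb.rate_hz} Hz"
        )
    n_bins = _n_bins(tb.n_ticks, tb.rate_hz, target_rate_hz)
    bins = _bin_of_ticks(tb.n_ticks, tb.rate_hz, target_rate_hz)
    vsum = np.bincount(bins, weights=ss.value_sum, minlength=n_bins)
    wsum = np.bincount(bins, weights=ss.weight, minlength=n_bins).astype(np.int64)
    missing = wsum == 0
    values = np.full(n_bins, np.nan)
    np.divide(vsum, wsum, out=values, where=~missing)
    return ResampledSignal(
        rate_hz=target_rate_hz,
        values=values,
        bin_weight=wsum,
        missing_mask=missing,
        origin_s=tb.origin_s,
    )


def fill_gaps(rs: ResampledSignal, method: str = "linear") -> ResampledSignal:
    """Fill missing bins; ``method`` is ``"none"`` (identity copy) or ``"linear"``.

    Linear filling interpolates each gap between its nearest non-missing
    neighbours; leading and trailing gaps are held at the nearest value.  The
    original ``missing_mask`` is preserved and ``filled`` is set.
    """
    if method not in ("none", "linear"):
        raise ValueError(f"unknown fill method {method!r}")
    if method == "none":
        return ResampledSignal(
            rate_hz=rs.rate_hz,
            values=rs.values.copy(),
            bin_weight=rs.bin_weight.copy(),
            missing_mask=rs.missing_mask.copy(),
            origin_s=rs.origin_s,
            filled=rs.filled,
        )
    present = ~rs.missing_mask
    n_present = int(np.sum(present))
    if n_present == 0:
        raise ValueError("cannot fill: all bins are missing")
    if n_present < 2 and n_present < rs.n_bins:
        raise ValueError("linear fill needs at least two non-missing bins")
    idx = np.arange(rs.n_bins)
    # np.interp holds the edge values on leading/trailing gaps
    values = np.interp(idx, idx[present], rs.values[present])
    return ResampledSignal(
        rate_hz=rs.rate_hz,
        values=values,
        bin_weight=rs.bin_weight.copy(),
        missing_mask=rs.missing_mask.copy(),
        origin_s=rs.origin_s,
        filled=True,
    )


def reconstruct(
    sweeps: Sequence[Sweep],
    shifts_s: Sequence[float],
    tb: TimeBase,
    target_rate_hz: float,
    fill: str = "linear",
) -> ResampledSignal:
    """Convenience chain: accumulate → resample → fill_gaps."""
    ss = accumulate(sweeps, shifts_s, tb)
    rs = resample(ss, target_rate_hz)
    return fill_gaps(rs, method=fill)


def max_reconstruction_rate_hz(lr_rate_hz: float, n_sweeps: int) -> float:
    """Theoretical ceiling of the reconstruction rate: LR rate × sweep count.

    With ``n`` sweeps of a sensor at rate ``R0`` over a window ``T`` there
    are at most ``n * R0 * T`` samples; any target rate above ``n * R0``
    defines more bins than samples over the same window, so missing bins are
    guaranteed by pigeonhole regardless of the jitter realization.
    """
    if n_sweeps < 1:
        raise ValueError("n_sweeps must be at least 1")
    return lr_rate_hz * n_sweeps
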