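"""Per-sweep image preprocessing: drift correction, ROI traces, ΔF/F.

Stacks are ``(n_frames, height, width)`` float arrays; pixels vacated by a
drift translation are set to NaN and excluded from ROI means.  Pixel
coordinates are 0-based with ``x`` the column and ``y`` the row; rectangles
are half-open.  A pixel belongs to a polygon ROI iff its centre
``(x + 0.5, y + 0.5)`` lies inside the polygon (even-odd rule for simple
polygons).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "RoiSpec",
    "DriftTable",
    "apply_drift",
    "estimate_drift",
    "extract_roi_trace",
    "dff",
    "baseline_window_before_event",
]


@dataclass(frozen=True)
class RoiSpec:
    """A region of interest: a half-open rectangle or a polygon.

    Use :meth:`rectangle` / :meth:`polygon` to construct.
    """

    roi_id: str
    kind: str
    rect: Optional[Tuple[int, int, int, int]] = None  # x0, y0, width, height
    vertices: Optional[Tuple[Tuple[float, float], ...]] = None

    @classmethod
    def rectangle(cls, roi_id: str, x0: int, y0: int, width: int, height: int) -> "RoiSpec":
        if width <= 0 or height <= 0:
            raise ValueError("rectangle must have positive width and height")
        return cls(roi_id=roi_id, kind="rect", rect=(x0, y0, width, height))

    @classmethod
    def polygon(cls, roi_id: str, vertices: Sequence[Tuple[float, float]]) -> "RoiSpec":
        if len(vertices) < 3:
            raise ValueError("polygon needs at least 3 vertices")
        return cls(roi_id=roi_id, kind="polygon", vertices=tuple(tuple(v) for v in vertices))

    def mask(self, height: int, width: int) -> np.ndarray:
        """Boolean pixel mask of shape ``(height, width)``."""
        if self.kind == "rect":
            x0, y0, w, h = self.rect
            if x0 < 0 or y0 < 0 or x0 + w > width or y0 + h > height:
                raise ValueError(f"ROI {self.roi_id!r} outside image bounds")
            m = np.zeros((height, width), dtype=bool)
            m[y0 : y0 + h, x0 : x0 + w] = True
            return m
        from matplotlib.path import Path

        yy, xx = np.mgrid[0:height, 0:width]
        centers = np.column_stack([xx.ravel() + 0.5, yy.ravel() + 0.5])
        m = Path(self.vertices).contains_points(centers).reshape(height, width)
        if not m.any():
            raise ValueError(f"polygon ROI {self.roi_id!r} covers no pixel centre")
        return m


@dataclass
class DriftTable:
    """Per-sweep integer pixel offsets ``(dx, dy)`` keyed by sweep id."""

    offsets: dict  # sweep_id -> (dx, dy)

    def get(self, sweep_id: str) -> Tuple[int, int]:
        return tuple(self.offsets.get(sweep_id, (0, 0)))


def apply_drift(stack: np.ndarray, offset: Tuple[int, int]) -> np.ndarray:
    """Translate every frame by integer pixels ``(dx, dy)``.

    ``dx`` moves content along columns (x), ``dy`` along rows (y).  Vacated
    pixels become NaN so ROI means ignore them.  Returns a float copy.
    """
    dx, dy = int(offset[0]), int(offset[1])
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("stack must be (n_frames, height, width)")
    _, h, w = stack.shape
    if abs(dx) >= w or abs(dy) >= h:
        raise ValueError(f"offset {(dx, dy)} is as large as the image")
    out = np.full_like(stack, np.nan)
    ys = slice(max(dy, 0), h + min(dy, 0))
    xs = slice(max(dx, 0), w + min(dx, 0))
    ys_src = slice(max(-dy, 0), h + min(-dy, 0))
    xs_src = slice(max(-dx, 0), w + min(-dx, 0))
    out[:, ys, xs] = stack[:, ys_src, xs_src]
    return out


def estimate_drift(reference_frame: np.ndarray, frame: np.ndarray) -> Tuple[int, int]:
    """Integer-pixel offset ``(dx, dy)`` maximizing the cross-correlation.

    The returned offset satisfies ``frame ≈ reference translated by (dx, dy)``
    (so ``apply_drift(frame, (-dx, -dy))`` re-registers it).  Warns when the
    correlation peak is not unique (e.g. pure noise or periodic content).
    """
    from scipy.signal import correlate

    ref = np.asarray(reference_frame, dtype=float)
    frm = np.asarray(frame, dtype=float)
    if ref.shape != frm.shape or ref.ndim != 2:
        raise ValueError("frames must be 2-D and the same shape")
    cc = correlate(frm - frm.mean(), ref - ref.mean(), mode="full", method="fft")
    peak = cc.max()
    near = np.abs(cc - peak) <= 1e-9 * max(abs(peak), 1.0)
    if np.sum(near) > 1:
        warnings.warn("drift correlation peak is not unique", stacklevel=2)
    iy, ix = np.unravel_index(int(np.argmax(cc)), cc.shape)
    dy = iy - (ref.shape[0] - 1)
    dx = ix - (ref.shape[1] - 1)
    return int(dx), int(dy)


def extract_roi_trace(stack: np.ndarray, roi: RoiSpec) -> np.ndarray:
    """Per-frame mean fluorescence over the ROI's valid (non-NaN) pixels.

    Raises if any frame has zero valid ROI pixels.
    """
    stack = np.asarray(stack, dtype=float)
    _, h, w = stack.shape
    m = roi.mask(h, w)
    pixels = stack[:, m]
    valid = np.isfinite(pixels)
    n_valid = valid.sum(axis=1)
    if np.any(n_valid == 0):
        bad = int(np.argmax(n_valid == 0))
        raise ValueError(f"frame {bad}: ROI {roi.roi_id!r} has no valid pixel")
    return np.nansum(np.where(valid, pixels, 0.0), axis=1) / n_valid


def dff(trace: np.ndarray, baseline_window: Tuple[int, int]) -> np.ndarray:
    """ΔF/F: ``(F - F0) / F0`` with ``F0`` the mean over the baseline frames.

    ``baseline_window`` is a half-open frame-index range ``(start, stop)``,
    which should lie strictly before the event.  Raises for an empty window
    or a non-positive baseline (dark ROI).
    """
    trace = np.asarray(trace, dtype=float)
    start, stop = baseline_window
    if stop <= start or start < 0 or stop > len(trace):
        raise ValueError(f"invalid baseline window {baseline_window}")
    f0 = trace[start:stop].mean()
    if f0 <= 0:
        raise ValueError(f"baseline F0 = {f0:g} is not positive (dark ROI?)")
    return (trace - f0) / f0


def baseline_window_before_event(
    frame_times_s: np.ndarray,
    event_time_s: float,
    guard_frames: int = 2,
) -> Tuple[int, int]:
    """Baseline frame range: all frames before the event minus a guard gap.

    Raises if no frame survives the guard (the event is too early in the
    acquisition for a pre-event baseline).
    """
    n_before = int(np.searchsorted(np.asarray(frame_times_s), event_time_s))
    stop = n_before - guard_frames
    if stop < 1:
        raise ValueError("no baseline frames before the event after the guard gap")
    return 0, stop
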