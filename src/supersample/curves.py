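"""Curve operations: weighted spline smoothing, bleach correction, kinetics fits.

Three operations quantify or clean the reconstructed trace:

* **Weighted cubic smoothing spline** minimizing
  ``p * sum_i w_i (y_i - f(x_i))^2 + (1 - p) * integral (f''(x))^2 dx``,
  with the per-bin weight ``w_i`` equal to the number of sweeps that defined
  bin *i*.  ``p = 1`` interpolates the data, ``p = 0`` degenerates to the
  weighted least-squares straight line; heavier bins are smoothed less.

* **Bleach correction**: a double exponential (plus optional constant) is
  fitted by least squares to the trace *outside* a window around the event
  and subtracted, removing the slow fluorescence decay of the dye.

* **Logistic (sigmoid) fit** ``f(x) = A / (1 + exp((mu - x) * s))`` of the
  rising phase of a calcium transient: ``A`` is the amplitude, ``mu`` the
  half-maximum time and ``s`` the slope (1/s); ``s > 0`` gives a rising
  sigmoid and ``f(mu) = A / 2``.

Plus the Pearson correlation used throughout the evaluation study.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Tuple

import numpy as np
from scipy.interpolate import make_smoothing_spline
from scipy.optimize import least_squares

from .signal_model import FitResult, ResampledSignal

__all__ = [
    "SplineConfig",
    "BleachConfig",
    "LogisticParams",
    "weighted_spline",
    "smooth_weighted_spline",
    "fit_double_exponential",
    "bleach_correct",
    "fit_logistic",
    "pearson_r",
]


# --------------------------------------------------------------------------
# weighted cubic smoothing spline
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SplineConfig:
    """Smoothing balance ``p`` in [0, 1] and the weight normalization.

    ``mean_one`` (default) rescales the weights to mean 1 so a given ``p``
    means the same thing regardless of trace length; ``raw`` uses the sweep
    counts as-is.
    """

    p: float
    weight_normalization: str = "mean_one"
    penalty_scale: str = "knot_spacing"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p must be in [0, 1], got {self.p}")
        if self.weight_normalization not in ("mean_one", "raw"):
            raise ValueError(f"unknown normalization {self.weight_normalization!r}")
        if self.penalty_scale not in ("knot_spacing", "raw"):
            raise ValueError(f"unknown penalty scale {self.penalty_scale!r}")


def weighted_spline(
    x: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    cfg: SplineConfig,
) -> Callable[[np.ndarray], np.ndarray]:
    """Fit the weighted cubic smoothing spline; returns a callable ``f(x)``.

    Minimizes ``p * sum w_i (y_i - f(x_i))^2 + (1-p) * int (f'')^2``; dividing
    by ``p`` shows this is the classic penalized form with roughness penalty
    ``lam = (1 - p) / p``, so the interior regime delegates to
    :func:`scipy.interpolate.make_smoothing_spline`.  The limits are handled
    exactly: ``p = 1`` interpolates (zero penalty), ``p = 0`` returns the
    weighted least-squares straight line.

    With the default ``penalty_scale="knot_spacing"`` the roughness integral
    is taken over ``x`` measured in units of the mean knot spacing ``h``
    (equivalently ``lam`` is multiplied by ``h**3``), so a given ``p`` means
    the same fidelity/roughness balance per data point regardless of the
    sampling rate or time units.  ``penalty_scale="raw"`` integrates over
    ``x`` as given; with ``x`` in seconds and kHz-scale sampling the penalty
    then dwarfs the residual term for any interior ``p`` and the fit
    collapses towards the straight line.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if not (len(x) == len(y) == len(w)):
        raise ValueError("x, y, w must share a length")
    if len(x) < 4:
        raise ValueError("need at least 4 points for a cubic smoothing spline")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if cfg.weight_normalization == "mean_one":
        mean_w = w.mean()
        if mean_w <= 0:
            raise ValueError("all weights are zero")
        w = w / mean_w
    if cfg.p == 0.0:
        # weighted least-squares line: solve min sum w (y - (a + b x))^2
        design = np.column_stack([np.ones_like(x), x]) * np.sqrt(w)[:, None]
        coef, *_ = np.linalg.lstsq(design, y * np.sqrt(w), rcond=None)
        return lambda xq: coef[0] + coef[1] * np.asarray(xq, dtype=float)
    lam = (1.0 - cfg.p) / cfg.p
    if cfg.penalty_scale == "knot_spacing":
        h = float(np.mean(np.diff(x)))
        if h <= 0:
            raise ValueError("x must be strictly increasing")
        lam *= h**3
    spline = make_smoothing_spline(x, y, w=w, lam=lam)
    return lambda xq: spline(np.asarray(xq, dtype=float))


def smooth_weighted_spline(rs: ResampledSignal, cfg: SplineConfig) -> np.ndarray:
    """Smooth a resampled trace; returns values at *all* bin times.

    The spline is fitted on bins with ``bin_weight > 0`` (gap-filled bins
    carry weight 0 and do not constrain the fit) and evaluated everywhere.
    """
    t = rs.bin_times_s()
    fit_on = rs.bin_weight > 0
    if int(fit_on.sum()) < 4:
        raise ValueError("need at least 4 weighted bins to smooth")
    f = weighted_spline(t[fit_on], rs.values[fit_on], rs.bin_weight[fit_on], cfg)
    return f(t)


# --------------------------------------------------------------------------
# bleach correction (double exponential)
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class BleachConfig:
    """Bleach-fit settings: the event window to exclude, and the offset term.

    ``exclusion_window_s`` is the (start, end) time interval around the
    aligned event whose bins are ignored during the fit (the transient must
    not be mistaken for bleaching); ``include_offset`` adds a constant ``c``
    to the double exponential (real baselines do not decay to zero).
    """

    exclusion_window_s: Tuple[float, float]
    include_offset: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.exclusion_window_s
        if hi < lo:
            raise ValueError("exclusion window end precedes its start")


def _double_exp(t: np.ndarray, a1: float, tau1: float, a2: float, tau2: float, c: float) -> np.ndarray:
    return a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2) + c


def fit_double_exponential(
    t: np.ndarray,
    y: np.ndarray,
    include_offset: bool = True,
    init: Optional[np.ndarray] = None,
) -> Tuple[FitResult, Callable[[np.ndarray], np.ndarray]]:
    """Least-squares fit of ``a1 exp(-t/tau1) + a2 exp(-t/tau2) (+ c)``.

    Deterministic initialisation: ``a1 = a2 = (first - last) / 2``,
    ``tau1 = span/10``, ``tau2 = span``, ``c = last value``.  The returned
    parameters are canonicalized to ``tau1 <= tau2``.  Non-convergence is
    reported through ``FitResult.converged``; the best-effort model is still
    returned.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) != len(y):
        raise ValueError("t and y must share a length")
    if len(t) < (6 if include_offset else 5):
        raise ValueError(f"too few points ({len(t)}) for a double-exponential fit")
    span = t[-1] - t[0]
    if span <= 0:
        raise ValueError("time values must span a positive interval")
    if init is None:
        a0 = (y[0] - y[-1]) / 2.0
        init = np.array([a0, span / 10.0, a0, span, y[-1]])
    init = np.asarray(init, dtype=float)

    t_rel = t - t[0]  # fit in local time for conditioning

    if include_offset:
        def residual(p):
            return _double_exp(t_rel, *p) - y
        p0 = init
    else:
        def residual(p):
            return _double_exp(t_rel, p[0], p[1], p[2], p[3], 0.0) - y
        p0 = init[:4]

    sol = least_squares(residual, p0, method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14)
    p = sol.x
    a1, tau1, a2, tau2 = p[0], p[1], p[2], p[3]
    c = p[4] if include_offset else 0.0
    if tau1 > tau2:
        a1, tau1, a2, tau2 = a2, tau2, a1, tau1
    params = {"a1": a1, "tau1": tau1, "a2": a2, "tau2": tau2}
    if include_offset:
        params["c"] = c
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    result = FitResult(
        params=params,
        residual_rms=rms,
        converged=bool(sol.success),
        n_points=len(t),
        message=sol.message,
    )
    t0 = t[0]

    def model(tq: np.ndarray) -> np.ndarray:
        return _double_exp(np.asarray(tq, dtype=float) - t0, a1, tau1, a2, tau2, c)

    return result, model


def bleach_correct(
    rs: ResampledSignal,
    cfg: BleachConfig,
) -> Tuple[np.ndarray, FitResult]:
    """Fit the bleaching decay outside the event window and subtract it.

    The double exponential is fitted on non-missing bins whose time lies
    outside ``exclusion_window_s`` (at least 6 such bins required) and
    evaluated at every bin time; the returned array is ``values - fit``
    (NaN where the input is NaN).
    """
    t = rs.bin_times_s()
    lo, hi = cfg.exclusion_window_s
    usable = (rs.bin_weight > 0) & ((t < lo) | (t > hi)) & np.isfinite(rs.values)
    if int(usable.sum()) < 6:
        raise ValueError(
            f"only {int(usable.sum())} bins outside the exclusion window; need >= 6"
        )
    fit, model = fit_double_exponential(
        t[usable], rs.values[usable], include_offset=cfg.include_offset
    )
    corrected = rs.values - model(t)
    return corrected, fit


# --------------------------------------------------------------------------
# logistic kinetics fit
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class LogisticParams:
    """Sigmoid parameters: amplitude ``A``, midpoint ``mu`` (s), slope ``s`` (1/s)."""

    A: float
    mu: float
    s: float

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return logistic(np.asarray(x, dtype=float), self.A, self.mu, self.s)


def logistic(x: np.ndarray, A: float, mu: float, s: float) -> np.ndarray:
    """``A / (1 + exp((mu - x) * s))``: rising sigmoid for ``s > 0``, ``f(mu) = A/2``."""
    z = np.clip((mu - x) * s, -700, 700)
    return A / (1.0 + np.exp(z))


def _logistic_init(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    A0 = y.max() - y.min()
    half = y.min() + A0 / 2.0
    above = np.flatnonzero(y >= half)
    mu0 = x[above[0]] if above.size else x[len(x) // 2]
    lo = y.min() + 0.1 * A0
    hi = y.min() + 0.9 * A0
    i10 = np.flatnonzero(y >= lo)
    i90 = np.flatnonzero(y >= hi)
    rise = x[i90[0]] - x[i10[0]] if i10.size and i90.size else 0.0
    s0 = 4.0 / rise if rise > 0 else 4.0 / (x[-1] - x[0])
    return np.array([A0, mu0, s0])


def fit_logistic(
    x: np.ndarray,
    y: np.ndarray,
    init: Optional[LogisticParams] = None,
) -> Tuple[LogisticParams, FitResult]:
    """Least-squares logistic fit of the rising phase.

    Needs at least 5 points spanning the rise; a flat input (zero range) is
    an error.  Initialisation: ``A = max - min``, ``mu`` at the half-max
    crossing, ``s = 4 / (10–90% rise time)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must share a length")
    if len(x) < 5:
        raise ValueError("need at least 5 points to fit a logistic")
    if np.ptp(y) == 0:
        raise ValueError("flat input: logistic amplitude is unidentifiable")
    p0 = np.array([init.A, init.mu, init.s]) if init is not None else _logistic_init(x, y)

    def residual(p):
        return logistic(x, *p) - y

    sol = least_squares(residual, p0, method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14)
    params = LogisticParams(A=float(sol.x[0]), mu=float(sol.x[1]), s=float(sol.x[2]))
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    result = FitResult(
        params={"A": params.A, "mu": params.mu, "s": params.s},
        residual_rms=rms,
        converged=bool(sol.success),
        n_points=len(x),
        message=sol.message,
    )
    return params, result


# --------------------------------------------------------------------------
# correlation
# --------------------------------------------------------------------------


def pearson_r(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson product-moment correlation over the common finite support.

    NaNs (missing bins) in either input are excluded pairwise.  Raises if
    fewer than two finite pairs remain or either signal is constant there.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("signals must have equal length")
    ok = np.isfinite(a) & np.isfinite(b)
    if int(ok.sum()) < 2:
        raise ValueError("need at least two overlapping finite samples")
    aa, bb = a[ok], b[ok]
    if np.ptp(aa) == 0 or np.ptp(bb) == 0:
        raise ValueError("correlation is undefined for a constant signal")
    return float(np.corrcoef(aa, bb)[0, 1])
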