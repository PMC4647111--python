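"""Synthetic model case: a jittered triangular transient seen by a slow sensor.

The generator mirrors the canonical bench test for shift-and-mean temporal
super-resolution: an ideal unit-amplitude triangular transient 3 ms wide on a
10 kHz grid, copied many times with a uniform random delay ("jitter") inside
a 5 ms window, decimated to a 500 Hz camera rate, and optionally corrupted
with additive Gaussian noise.  Because the true per-copy delays are returned,
every downstream stage (alignment, accumulation, resampling, evaluation) can
be tested against exact ground truth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .signal_model import Sweep, TimeBase

__all__ = [
    "ModelCaseConfig",
    "ModelCase",
    "make_triangular_signal",
    "make_lr_sweeps",
    "simulate_model_case",
    "save_model_case",
    "load_model_case",
    "MODEL_CASE_PRESET",
]


@dataclass(frozen=True)
class ModelCaseConfig:
    """Parameters of the synthetic model case.

    Defaults reproduce the standard bench conditions: 3 ms triangle of
    amplitude 1 on a 10 kHz grid, 5 ms uniform jitter window, 500 Hz
    low-resolution sampling, 50 sweeps, 40 ms total trace.  ``noise_sd`` is
    the SD of additive Gaussian noise in units of the signal amplitude, so
    SNR = amplitude / noise_sd.
    """

    hr_rate_hz: float = 10_000.0
    signal_width_s: float = 0.003
    amplitude: float = 1.0
    jitter_window_s: float = 0.005
    lr_rate_hz: float = 500.0
    n_sweeps: int = 50
    noise_sd: float = 0.0
    duration_s: float = 0.040
    signal_onset_s: Optional[float] = None  # None -> jitter_window_s
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        ratio = self.hr_rate_hz / self.lr_rate_hz
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                f"hr_rate_hz ({self.hr_rate_hz}) must be an integer multiple of "
                f"lr_rate_hz ({self.lr_rate_hz})"
            )
        if self.jitter_window_s + self.signal_width_s > self.duration_s + 1e-12:
            raise ValueError("jitter_window_s + signal_width_s must fit in duration_s")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_sweeps < 1:
            raise ValueError("n_sweeps must be at least 1")

    @property
    def decimation(self) -> int:
        return int(round(self.hr_rate_hz / self.lr_rate_hz))

    @property
    def n_ticks(self) -> int:
        return int(round(self.duration_s * self.hr_rate_hz))

    @property
    def onset_s(self) -> float:
        return self.jitter_window_s if self.signal_onset_s is None else self.signal_onset_s

    @property
    def snr(self) -> float:
        """Signal-to-noise ratio as amplitude / noise SD (inf when noiseless)."""
        return np.inf if self.noise_sd == 0 else self.amplitude / self.noise_sd


MODEL_CASE_PRESET = ModelCaseConfig()


def make_triangular_signal(cfg: ModelCaseConfig) -> np.ndarray:
    """Ideal HR trace: zero everywhere except an isoceles triangle.

    The triangle has base ``signal_width_s``, peak ``amplitude`` at the base
    midpoint, and onset at ``cfg.onset_s``.
    """
    n = cfg.n_ticks
    k = np.arange(n)
    onset_tick = int(round(cfg.onset_s * cfg.hr_rate_hz))
    half = cfg.signal_width_s * cfg.hr_rate_hz / 2.0
    tri = cfg.amplitude * (1.0 - np.abs(k - onset_tick - half) / half)
    return np.maximum(tri, 0.0)


def make_lr_sweeps(
    ideal: np.ndarray,
    cfg: ModelCaseConfig,
    rng: Optional[np.random.Generator] = None,
) -> List[Tuple[int, np.ndarray]]:
    """Generate ``cfg.n_sweeps`` jittered low-resolution copies of ``ideal``.

    Each copy delays the ideal trace by a shift drawn uniformly from the
    integer HR ticks ``[0, jitter_window_s * hr_rate_hz)`` (leading samples
    zero, trailing samples dropped), decimates by taking every
    ``decimation``-th sample starting at index 0, then adds i.i.d. Gaussian
    noise with SD ``noise_sd``.

    Returns a list of ``(shift_ticks, lr_values)`` pairs; the true shifts are
    the ground truth the alignment stage must recover.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    ideal = np.asarray(ideal, dtype=float)
    n = len(ideal)
    max_shift = int(round(cfg.jitter_window_s * cfg.hr_rate_hz))
    out: List[Tuple[int, np.ndarray]] = []
    for _ in range(cfg.n_sweeps):
        s = int(rng.integers(0, max_shift))
        shifted = np.zeros(n)
        shifted[s:] = ideal[: n - s]
        lr = shifted[:: cfg.decimation].copy()
        if cfg.noise_sd > 0:
            lr += rng.normal(0.0, cfg.noise_sd, size=lr.shape)
        out.append((s, lr))
    return out


@dataclass
class ModelCase:
    """A realized model case: ideal signal, LR sweeps and true shifts."""

    cfg: ModelCaseConfig
    ideal: np.ndarray
    shifts_ticks: np.ndarray
    lr_sweeps: List[np.ndarray]

    def timebase(self) -> TimeBase:
        return TimeBase(rate_hz=self.cfg.hr_rate_hz, origin_s=0.0, n_ticks=self.cfg.n_ticks)

    def alignment_shifts_s(self, n: Optional[int] = None) -> np.ndarray:
        """Per-sweep time shifts (seconds) that realign the sweeps to the ideal.

        A sweep delayed by ``s`` ticks must be advanced by ``s`` ticks, hence
        the minus sign.
        """
        shifts = self.shifts_ticks if n is None else self.shifts_ticks[:n]
        return -shifts / self.cfg.hr_rate_hz

    def as_sweeps(self, n: Optional[int] = None) -> List[Sweep]:
        """LR sweeps wrapped as :class:`Sweep` objects (frame times at the LR rate)."""
        sel = self.lr_sweeps if n is None else self.lr_sweeps[:n]
        frame_times = np.arange(len(sel[0])) / self.cfg.lr_rate_hz
        return [
            Sweep(sweep_id=f"sim{i:03d}", frame_times_s=frame_times, values=v)
            for i, v in enumerate(sel)
        ]


def simulate_model_case(
    cfg: ModelCaseConfig = MODEL_CASE_PRESET,
    rng: Optional[np.random.Generator] = None,
) -> ModelCase:
    """Generate the full model case (ideal trace + jittered noisy LR sweeps)."""
    ideal = make_triangular_signal(cfg)
    pairs = make_lr_sweeps(ideal, cfg, rng=rng)
    shifts = np.array([s for s, _ in pairs], dtype=np.int64)
    sweeps = [v for _, v in pairs]
    return ModelCase(cfg=cfg, ideal=ideal, shifts_ticks=shifts, lr_sweeps=sweeps)


def save_model_case(case: ModelCase, path) -> None:
    """Persist a model case as a self-describing ``.npz`` archive."""
    np.savez(
        path,
        ideal=case.ideal,
        shifts_ticks=case.shifts_ticks,
        sweeps=np.stack(case.lr_sweeps),
        config_json=np.array(json.dumps(asdict(case.cfg))),
    )


def load_model_case(path) -> ModelCase:
    with np.load(path, allow_pickle=False) as z:
        cfg = ModelCaseConfig(**json.loads(str(z["config_json"])))
        return ModelCase(
            cfg=cfg,
            ideal=z["ideal"],
            shifts_ticks=z["shifts_ticks"],
            lr_sweeps=list(z["sweeps"]),
        )


def with_overrides(cfg: ModelCaseConfig, **kwargs) -> ModelCaseConfig:
    """Return a copy of ``cfg`` with the given fields replaced."""
    return replace(cfg, **kwargs)
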