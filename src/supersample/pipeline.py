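"""Manifest-driven end-to-end runs over real (file-based) acquisitions.

A run manifest lists, per sweep, the image stack (multi-page TIFF), the
electrophysiology trace (two-column ``time_s voltage_mV`` text) and the
frame-time source (one-column timestamp text, or a two-column TTL trace
whose rising half-max edges mark frame read-outs), plus an ROI file (JSON),
an optional drift table (CSV) and the detection / reconstruction / analysis
configuration.  :func:`run_pipeline` executes

    drift → event detection → QC → shifts → ΔF/F → accumulate → resample
    → gap fill → (bleach correction) → (spline smoothing | logistic fit)

and writes per-ROI CSV traces, a QC report and fit results as JSON, and a
run log recording every configuration value and every dropped sweep/frame.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import tifffile
import yaml

from .curves import (
    BleachConfig,
    SplineConfig,
    bleach_correct,
    fit_logistic,
    smooth_weighted_spline,
)
from .ephys import (
    EventDetectionConfig,
    compute_shifts,
    detect_events,
    flag_jitter_outliers,
    frame_times_from_ttl,
    qc_sweeps,
)
from .imaging import (
    RoiSpec,
    apply_drift,
    baseline_window_before_event,
    dff,
    extract_roi_trace,
)
from .signal_model import EphysTrace, ResampledSignal, Sweep, TimeBase
from .sm_core import accumulate, fill_gaps, resample

logger = logging.getLogger("supersample")

__all__ = ["ManifestError", "DataError", "RunManifest", "load_manifest", "run_pipeline"]


class ManifestError(ValueError):
    """The manifest itself is invalid (missing keys, bad paths, bad config)."""


class DataError(ValueError):
    """The referenced data cannot be processed (no accepted sweeps, bad files)."""


@dataclass
class SweepEntry:
    sweep_id: str
    image: Path
    ephys: Path
    frame_times: Optional[Path] = None
    frame_ttl: Optional[Path] = None


@dataclass
class RunManifest:
    """Validated manifest: sweep entries plus the stage configurations."""

    sweeps: List[SweepEntry]
    roi_file: Path
    drift_table: Optional[Path] = None
    detection: EventDetectionConfig = field(default_factory=EventDetectionConfig)
    hr_rate_hz: float = 40_000.0
    target_rates_hz: Sequence[float] = (10_000.0,)
    fill: str = "linear"
    mode: str = "voltage"  # voltage -> smoothing, calcium -> logistic fit
    smoothing_p: Optional[float] = 0.2
    bleach_window_s: Optional[Tuple[float, float]] = None
    rise_window_s: Optional[Tuple[float, float]] = None
    baseline_guard_frames: int = 2
    compute_dff: bool = True
    reference: Union[str, float] = "mean"
    jitter_bound_s: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        ids = [s.sweep_id for s in self.sweeps]
        if len(set(ids)) != len(ids):
            raise ManifestError("sweep_ids must be unique")
        if self.mode not in ("voltage", "calcium"):
            raise ManifestError(f"unknown analysis mode {self.mode!r}")
        if self.fill not in ("none", "linear"):
            raise ManifestError(f"unknown fill method {self.fill!r}")
        for s in self.sweeps:
            if s.frame_times is None and s.frame_ttl is None:
                raise ManifestError(f"sweep {s.sweep_id!r}: no frame-time source")


def load_manifest(path: Union[str, Path]) -> RunManifest:
    """Read a YAML/JSON manifest and resolve its paths relative to the file."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except Exception as exc:  # bad YAML is a config error
        raise ManifestError(f"cannot parse manifest {path}: {exc}") from exc
    if not isinstance(raw, dict) or "sweeps" not in raw:
        raise ManifestError("manifest must be a mapping with a 'sweeps' list")
    base = path.parent

    def respath(p) -> Path:
        p = Path(p)
        return p if p.is_absolute() else base / p

    sweeps = []
    for entry in raw["sweeps"]:
        try:
            sweeps.append(
                SweepEntry(
                    sweep_id=str(entry["sweep_id"]),
                    image=respath(entry["image"]),
                    ephys=respath(entry["ephys"]),
                    frame_times=respath(entry["frame_times"]) if "frame_times" in entry else None,
                    frame_ttl=respath(entry["frame_ttl"]) if "frame_ttl" in entry else None,
                )
            )
        except KeyError as exc:
            raise ManifestError(f"sweep entry missing key {exc}") from exc
    det = EventDetectionConfig(**raw.get("detection", {}))
    rec = raw.get("reconstruction", {})
    ana = raw.get("analysis", {})
    try:
        manifest = RunManifest(
            sweeps=sweeps,
            roi_file=respath(raw["roi_file"]),
            drift_table=respath(raw["drift_table"]) if raw.get("drift_table") else None,
            detection=det,
            hr_rate_hz=float(rec.get("hr_rate_hz", 40_000.0)),
            target_rates_hz=tuple(float(r) for r in rec.get("target_rates_hz", (10_000.0,))),
            fill=rec.get("fill", "linear"),
            mode=ana.get("mode", "voltage"),
            smoothing_p=ana.get("smoothing_p", 0.2),
            bleach_window_s=tuple(ana["bleach_window_s"]) if ana.get("bleach_window_s") else None,
            rise_window_s=tuple(ana["rise_window_s"]) if ana.get("rise_window_s") else None,
            baseline_guard_frames=int(ana.get("baseline_guard_frames", 2)),
            compute_dff=bool(ana.get("dff", True)),
            reference=raw.get("reference", "mean"),
            jitter_bound_s=float(raw.get("jitter_bound_s", 0.005)),
            seed=int(raw.get("seed", 0)),
        )
    except (TypeError, ValueError) as exc:
        raise ManifestError(str(exc)) from exc
    missing = [
        str(p)
        for s in manifest.sweeps
        for p in (s.image, s.ephys, s.frame_times, s.frame_ttl)
        if p is not None and not Path(p).exists()
    ]
    if not manifest.roi_file.exists():
        missing.append(str(manifest.roi_file))
    if missing:
        raise ManifestError(f"missing input files: {missing}")
    return manifest


def _read_ephys(path: Path) -> EphysTrace:
    arr = np.loadtxt(path)
    if arr.ndim != 2 or arr.shape[1] < 2 or arr.shape[0] < 2:
        raise DataError(f"{path}: expected two-column time/voltage text")
    t, v = arr[:, 0], arr[:, 1]
    dt = np.diff(t)
    if np.any(dt <= 0) or np.ptp(dt) > 1e-6 * dt[0]:
        raise DataError(f"{path}: time column is not uniformly increasing")
    return EphysTrace(rate_hz=1.0 / float(np.median(dt)), t0_s=float(t[0]), voltage=v)


def _read_frame_times(entry: SweepEntry) -> np.ndarray:
    if entry.frame_times is not None:
        times = np.atleast_1d(np.loadtxt(entry.frame_times))
        if times.ndim != 1:
            raise DataError(f"{entry.frame_times}: expected one column of times")
        return times
    arr = np.loadtxt(entry.frame_ttl)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise DataError(f"{entry.frame_ttl}: expected two-column time/level text")
    rate = 1.0 / float(np.median(np.diff(arr[:, 0])))
    return frame_times_from_ttl(arr[:, 1], rate_hz=rate, t0_s=float(arr[0, 0]))


def _read_rois(path: Path) -> List[RoiSpec]:
    entries = json.loads(Path(path).read_text())
    rois = []
    for e in entries:
        if e.get("kind", "rect") == "rect":
            rois.append(RoiSpec.rectangle(e["roi_id"], *[int(v) for v in e["rect"]]))
        else:
            rois.append(RoiSpec.polygon(e["roi_id"], e["vertices"]))
    if not rois:
        raise ManifestError(f"{path}: no ROIs defined")
    return rois


def _read_drift(path: Optional[Path]) -> Dict[str, Tuple[int, int]]:
    if path is None:
        return {}
    df = pd.read_csv(path)
    return {
        str(row["sweep_id"]): (int(row["dx"]), int(row["dy"])) for _, row in df.iterrows()
    }


def run_pipeline(
    manifest: Union[RunManifest, str, Path],
    outdir: Union[str, Path],
) -> dict:
    """Execute the full pipeline for a manifest; returns a results summary.

    Outputs written to ``outdir``: ``trace_<roi>_<rate>Hz.csv`` per ROI and
    target rate (columns ``bin_time_s, value, bin_weight, was_missing`` plus
    ``smoothed``/``corrected`` when applicable), ``qc_report.json``,
    ``fits.json`` and ``run_log.json``.
    """
    if not isinstance(manifest, RunManifest):
        manifest = load_manifest(manifest)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # ---- per-sweep event detection ------------------------------------
    events_per_sweep: List[List[float]] = []
    frame_times: Dict[str, np.ndarray] = {}
    for entry in manifest.sweeps:
        trace = _read_ephys(entry.ephys)
        events_per_sweep.append(detect_events(trace, manifest.detection))
        frame_times[entry.sweep_id] = _read_frame_times(entry)

    flags, qc_report = qc_sweeps(events_per_sweep)
    accepted = [
        (entry, events_per_sweep[i][0])
        for i, entry in enumerate(manifest.sweeps)
        if flags[i]
    ]
    qc_report["rejected_ids"] = [
        e.sweep_id for i, e in enumerate(manifest.sweeps) if not flags[i]
    ]
    if not accepted:
        raise DataError("no accepted sweeps after QC")

    shifts = compute_shifts([ev for _, ev in accepted], reference=manifest.reference)
    jitter_flags = flag_jitter_outliers(shifts, manifest.jitter_bound_s)
    qc_report["jitter_flagged_ids"] = [
        accepted[i][0].sweep_id for i in np.flatnonzero(jitter_flags)
    ]

    # ---- imaging: drift, ROI extraction, dF/F -------------------------
    drift = _read_drift(manifest.drift_table)
    rois = _read_rois(manifest.roi_file)
    roi_sweeps: Dict[str, List[Sweep]] = {r.roi_id: [] for r in rois}
    for (entry, event_time), shift in zip(accepted, shifts):
        stack = np.asarray(tifffile.imread(entry.image), dtype=float)
        if stack.ndim == 2:
            stack = stack[None]
        offset = drift.get(entry.sweep_id, (0, 0))
        if offset != (0, 0):
            stack = apply_drift(stack, offset)
        times = frame_times[entry.sweep_id]
        if len(times) != stack.shape[0]:
            raise DataError(
                f"sweep {entry.sweep_id!r}: {len(times)} frame times for "
                f"{stack.shape[0]} frames"
            )
        for roi in rois:
            trace = extract_roi_trace(stack, roi)
            if manifest.compute_dff:
                window = baseline_window_before_event(
                    times, event_time, manifest.baseline_guard_frames
                )
                trace = dff(trace, window)
            roi_sweeps[roi.roi_id].append(
                Sweep(
                    sweep_id=entry.sweep_id,
                    frame_times_s=times,
                    values=trace,
                    event_time_s=event_time,
                )
            )

    # ---- HR time base covering all aligned frames ---------------------
    all_aligned = np.concatenate(
        [
            sw.frame_times_s + sh
            for sw, sh in zip(roi_sweeps[rois[0].roi_id], shifts)
        ]
    )
    rate = manifest.hr_rate_hz
    origin = np.floor(all_aligned.min() * rate) / rate
    n_ticks = int(np.round((all_aligned.max() - origin) * rate)) + 1
    tb = TimeBase(rate_hz=rate, origin_s=origin, n_ticks=n_ticks)

    # ---- accumulate / resample / analyse per ROI ----------------------
    fits: Dict[str, dict] = {}
    results: Dict[str, Dict[float, ResampledSignal]] = {}
    dropped_frames = 0
    for roi in rois:
        ss = accumulate(roi_sweeps[roi.roi_id], shifts, tb)
        dropped_frames = ss.n_dropped_frames
        results[roi.roi_id] = {}
        fits[roi.roi_id] = {}
        for target in manifest.target_rates_hz:
            rs = fill_gaps(resample(ss, target), method=manifest.fill)
            values = rs.values
            out = pd.DataFrame(
                {
                    "bin_time_s": rs.bin_times_s(),
                    "value": rs.values,
                    "bin_weight": rs.bin_weight,
                    "was_missing": rs.missing_mask.astype(int),
                }
            )
            if manifest.bleach_window_s is not None:
                corrected, bleach_fit = bleach_correct(
                    rs, BleachConfig(exclusion_window_s=manifest.bleach_window_s)
                )
                values = corrected
                out["corrected"] = corrected
                rs = ResampledSignal(
                    rate_hz=rs.rate_hz,
                    values=corrected,
                    bin_weight=rs.bin_weight,
                    missing_mask=rs.missing_mask,
                    origin_s=rs.origin_s,
                    filled=rs.filled,
                )
                fits[roi.roi_id][f"bleach_{target:g}Hz"] = {
                    "params": dict(bleach_fit.params),
                    "residual_rms": bleach_fit.residual_rms,
                    "converged": bleach_fit.converged,
                    "n_points": bleach_fit.n_points,
                }
            if manifest.mode == "voltage" and manifest.smoothing_p is not None:
                out["smoothed"] = smooth_weighted_spline(
                    rs, SplineConfig(p=manifest.smoothing_p)
                )
            elif manifest.mode == "calcium":
                # calcium traces are not smoothed; quantify rise kinetics
                t = rs.bin_times_s()
                sel = np.isfinite(values)
                if manifest.rise_window_s is not None:
                    lo, hi = manifest.rise_window_s
                    sel &= (t >= lo) & (t <= hi)
                if int(sel.sum()) >= 5 and np.ptp(values[sel]) > 0:
                    params, fit = fit_logistic(t[sel], values[sel])
                    fits[roi.roi_id][f"logistic_{target:g}Hz"] = {
                        "params": dict(fit.params),
                        "residual_rms": fit.residual_rms,
                        "converged": fit.converged,
                        "n_points": fit.n_points,
                    }
            out.to_csv(
                outdir / f"trace_{roi.roi_id}_{target:g}Hz.csv", index=False
            )
            results[roi.roi_id][target] = rs

    qc_report["dropped_frames"] = int(dropped_frames)
    (outdir / "qc_report.json").write_text(json.dumps(qc_report, indent=2))
    (outdir / "fits.json").write_text(json.dumps(fits, indent=2))
    log = {
        "hr_rate_hz": rate,
        "origin_s": origin,
        "n_ticks": n_ticks,
        "target_rates_hz": list(manifest.target_rates_hz),
        "fill": manifest.fill,
        "mode": manifest.mode,
        "smoothing_p": manifest.smoothing_p,
        "bleach_window_s": list(manifest.bleach_window_s) if manifest.bleach_window_s else None,
        "reference": manifest.reference,
        "seed": manifest.seed,
        "detection": asdict(manifest.detection),
        "n_sweeps_in": len(manifest.sweeps),
        "n_sweeps_accepted": qc_report["accepted"],
        "shifts_s": {e.sweep_id: float(s) for (e, _), s in zip(accepted, shifts)},
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2))
    logger.info(
        "pipeline: %d/%d sweeps accepted, %d frames dropped, %d ROI(s), rates %s",
        qc_report["accepted"], len(manifest.sweeps), dropped_frames,
        len(rois), list(manifest.target_rates_hz),
    )
    return {"qc": qc_report, "shifts_s": shifts, "rois": results, "fits": fits}
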