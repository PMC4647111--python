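"""Detect action potentials in patch-clamp traces, QC sweeps, compute shifts.

Builds three synthetic 40 kHz somatic recordings: two with a single AP at
slightly different latencies (the jitter the method exploits), one flat
(no AP -> rejected by QC).  Event times from peak and threshold (dV/dt)
detection differ by the rise time; the alignment shifts bring every accepted
sweep's event to the common reference.
"""

import numpy as np

from supersample import (
    EphysTrace,
    EventDetectionConfig,
    compute_shifts,
    detect_events,
    qc_sweeps,
)

RATE = 40_000.0


def ap_trace(t_start):
    t = np.arange(int(0.5 * RATE)) / RATE
    v = np.interp(t, [t_start, t_start + 0.001, t_start + 0.005],
                  [-65.0, 30.0, -65.0], left=-65.0, right=-65.0)
    return EphysTrace(rate_hz=RATE, t0_s=0.0, voltage=v)


traces = [ap_trace(0.1000), ap_trace(0.1023),
          EphysTrace(rate_hz=RATE, t0_s=0.0, voltage=np.full(20_000, -65.0))]

peak_cfg = EventDetectionConfig(mode="peak")
thr_cfg = EventDetectionConfig(mode="threshold", dvdt_threshold_v_per_s=20.0)
events = [detect_events(tr, peak_cfg) for tr in traces]
for i, tr in enumerate(traces):
    print(f"sweep {i}: peak events {events[i]}, "
          f"threshold events {detect_events(tr, thr_cfg)}")

flags, report = qc_sweeps(events)
print(f"QC: {report['accepted']} accepted, {report['no_event']} without an AP, "
      f"{report['multiple_events']} with multiple APs")

accepted_times = [ev[0] for ev, ok in zip(events, flags) if ok]
shifts = compute_shifts(accepted_times, reference="mean")
print(f"alignment shifts (s): {np.round(shifts, 5)}  "
      f"(each sweep's frames move by this much onto the common grid)")
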