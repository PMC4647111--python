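# Methods

## Model and procedure

Shift-and-mean reconstruction treats a set of repeated low-rate acquisitions
("sweeps") of one triggered event as a single non-uniform sampling of that
event. The assumptions are those of event-triggered averaging: every sweep
records the same underlying waveform, shifted in time by a per-sweep latency
(jitter) that can be measured exactly from a reference channel, and
trial-to-trial amplitude/shape variability is noise, not signal. Under those
assumptions the per-sweep shift is the reference event time minus that
sweep's event time, and the reconstruction is:

- **Accumulation.** All times are quantized to the nearest tick of a
  discrete high-resolution grid (rate `R_hr`, by default the
  electrophysiology clock). For each frame of each accepted sweep, the
  shifted frame time maps to a tick; the frame value is added to that tick's
  `value_sum` and its integer `weight` is incremented. Storing *sums*
  rather than means makes the downstream weighted average a single division
  and the bookkeeping exactly conservative: at any target rate,
  `Σ_b value[b]·bin_weight[b] = Σ value_sum` to round-off.
- **Resampling.** Bins are half-open in time, `[b/R, (b+1)/R)` from the
  grid origin; a bin's value is the weighted mean over its ticks, its weight
  the summed tick weights, and a weightless bin is *missing* (NaN), not
  zero. Missing bins may be filled by linear interpolation between the
  nearest covered neighbours, holding the edge value on leading/trailing
  gaps; the original missing mask is preserved so filled bins remain
  identifiable (and carry weight 0 into any later weighted fit).
- **Ceiling.** With `n` sweeps at camera rate `R0` the reconstruction rate
  is bounded by `n·R0`: above it there are more bins than samples over the
  same window and gaps are guaranteed by pigeonhole, whatever the jitter.

Shifts are quantized to the nearest HR tick (ties round half away from
zero); sub-tick residuals are discarded, bounding the alignment error by
half a tick period (12.5 µs at 40 kHz). Continuous-time (sub-tick)
reconstruction is out of scope.

## Event detection, QC, alignment

The triggering action potential is located per sweep in the patch-clamp
trace either at its **peak** (local maximum above `peak_min_mv`, default
0 mV, separated by a refractory period, default 5 ms) or at its
**threshold** — the first upward crossing of a dV/dt criterion (default
20 V/s, a common AP-threshold convention; the choice of criterion is a
config option because "threshold" has no unique definition) within the
refractory window before a qualifying peak. Sweeps with zero or multiple
detected events are discarded and counted by reason. The alignment
reference defaults to the mean accepted event time, which keeps the
reconstructed event centred in the acquisition window; first-sweep and
explicit-time references are available. Sweeps whose |shift| exceeds a
bound (default 5 ms — triggered APs jitter by under ~3 ms, plus margin)
are flagged as probable misdetections rather than silently used.

Frame times come either from an explicit per-sweep timestamp list or from a
TTL frame-readout trace, taken at the rising crossings of its half-maximum.

## Imaging preprocessing

Drift correction is integer-pixel translation (per-sweep offsets from a
table, or estimated by the cross-correlation peak between frames); vacated
pixels become NaN and are excluded from ROI means, so a ROI fully inside the
valid area is unaffected. ROIs are half-open rectangles or polygons
rasterized by the pixel-centre rule (pixel (x, y) belongs iff its centre
(x+0.5, y+0.5) is inside; even-odd rule for simple polygons). ΔF/F uses
`F0` = mean over all frames before the aligned event minus a guard gap
(default 2 frames) — the field-standard pre-event baseline — and is
computed per sweep *before* accumulation, since `F0` is a per-sweep
quantity; a non-positive `F0` is an error (dark ROI). ΔF/F is invariant to
multiplicative gain but not to additive offsets; background subtraction is
deliberately out of scope.

## Curve operations

- **Weighted cubic smoothing spline** minimizing
  `p·Σ wᵢ(yᵢ−f(xᵢ))² + (1−p)·∫(f″)²`, with `wᵢ` the bin weights. For
  0 < p < 1 this is the classic penalized form with `λ = (1−p)/p`
  (delegated to `scipy.interpolate.make_smoothing_spline`); `p = 1`
  interpolates, `p = 0` is solved exactly as the weighted least-squares
  line. Two normalizations make `p` meaningful: weights are rescaled to
  mean 1 (raw mode available), and the roughness integral is taken over x
  in units of the mean knot spacing (`λ` is multiplied by `h³`; raw-seconds
  mode available). Without the latter, kHz-scale sampling in seconds makes
  the penalty ~10⁸ times the residual term and every interior `p` collapses
  to the straight line — with it, a given `p` buys the same
  fidelity/roughness balance per data point at any rate, and the observed
  trade-off (smoothing rescues noisy high-rate reconstructions, degrades
  low-rate ones) emerges. Gap-filled bins carry weight 0: they are
  evaluated but never constrain the fit.
- **Bleach correction** fits `a₁·e^(−t/τ₁) + a₂·e^(−t/τ₂) + c` by
  Levenberg–Marquardt least squares to the non-missing bins outside an
  event exclusion window (≥ 6 required) and subtracts the model everywhere.
  The constant `c` is on by default (real baselines do not decay to zero).
  Initialisation is deterministic: `a₁ = a₂ = (first−last)/2`,
  `τ₁ = span/10`, `τ₂ = span`, `c = last`; the fit runs in time relative to
  the first fitted point for conditioning, and the reported pair is
  canonicalized to `τ₁ ≤ τ₂`. Non-convergence is flagged on the result,
  which is still returned best-effort.
- **Logistic kinetics** `f(x) = A/(1+exp((mu−x)·s))` — `s > 0` rises,
  `f(mu) = A/2` exactly. (The typeset source formula is ambiguous about
  the exponent's extent; this reading makes `mu` the half-maximum point and
  `s` a rate, matching the parameter descriptions.) Initialisation:
  `A = max−min`, `mu` at the half-max crossing, `s = 4/(10–90 % rise
  time)`. Flat input is rejected as unidentifiable. Calcium traces are fitted,
  not smoothed; voltage traces are smoothed, matching the standard workflow.

## Synthetic model case

The generator reproduces the canonical bench test: an ideal isoceles
triangle, width 3 ms, amplitude 1, on a 10 kHz grid, onset at the end of the
jitter window, in a 40 ms trace; 50 sweeps, each delayed by a shift drawn
uniformly on the integer ticks of a 5 ms window (uniformity is the minimal
assumption for "random within a window"; the delay is tick-quantized because
the grid is), decimated ×20 to 500 Hz at fixed phase 0 (so jitter, not
sensor phase, provides coverage), then i.i.d. Gaussian noise of SD 0/0.2/
0.5/0.8 in amplitude units is added to the *decimated* samples (noise is a
property of the slow sensor). SNR = amplitude/SD, i.e. 5, 2 and 1.25.
Seeded runs are bit-reproducible, and the true shifts are returned so
alignment can be tested against ground truth.

What the generator does **not** emulate: realistic AP/calcium waveforms in
the fluorescence channel, photon shot noise (Poisson), photobleaching
(bleach correction is tested on its own double-exponential fixtures), drift,
or trial-to-trial waveform variability. Passing tests therefore demonstrate
the correctness of the reconstruction arithmetic and its statistical
behaviour under additive Gaussian noise, not robustness to violations of the
identical-sweep assumption.

Because the jitter is a pure delay, the leading jitter window of each sweep
contributes frames that fall before the grid (dropped and counted) and the
*trailing* jitter window of the trace is reached by progressively fewer
sweeps; its bins may rest on a single sample carrying full single-frame
noise.

## Evaluation study

`run_study` scores reconstructions by Pearson correlation against the ideal
signal expressed at the evaluation rate. Design choices, made where the
convention was genuinely open:

- **Reference signal**: the ideal averaged over each target bin (what the
  weighted mean estimates). Phase-0 decimation is available but compares
  each bin against the ideal at the bin *start*, a systematic half-bin lag
  that at coarse rates dominates the score and even inverts the ordering of
  rates; bin averaging removes that artifact.
- **Scored region**: the trailing jitter window is excluded by default
  (see above — its bins measure edge-of-support noise, not reconstruction
  quality); full-trace scoring is a flag away.
- **Common random numbers**: within a replicate, the cells for different
  sweep counts use prefixes of one simulated sweep set, so the dependence
  of mean r on sweep count is measured with paired differences rather than
  independent noise. 20 replicates per condition by default.
- Failures in a cell (e.g. too few bins to smooth) are recorded with a flag,
  never dropped silently. Everything is driven by a single seed.

At low rates the mean correlation is not strictly monotone in the sweep
count: adding a sweep perturbs the within-bin weighting by a ~10⁻³
fluctuation around the rising trend. The corresponding test asserts
non-decrease up to 3 paired SEMs, which is the resolution the Monte-Carlo
design affords.

## Problem sizes and tolerances

Default study sizes (50 sweeps × 20 frames, 400-tick grid, 20 replicates,
the full 1–50 sweep ladder at five rates) run in a few seconds; they are the
package's standard conditions, and everything is reproducible from explicit
seeds. Nonlinear fits use `scipy.optimize.least_squares` (LM) with
tolerances at 1e-14, giving ≤1e-6 relative parameter recovery on noiseless
fixtures; spline limit cases are exact to ~1e-9. Integer tick/bin indices
are computed in exact integer arithmetic whenever both rates are integral,
so bin-boundary ticks are never misassigned by float round-off.

## Known limitations

- Assumes identical waveforms across sweeps; systematic drift of the signal
  (e.g. rundown) aliases into the reconstruction. Trial-to-trial
  variability is averaged away, not modelled.
- Spontaneous (untriggered) events are out of scope — alignment requires a
  reference channel.
- Drift correction is integer-pixel; no subpixel registration, background
  subtraction, or shot-noise weighting.
- No deconvolution/regularized inverse: the estimator is exactly the
  weighted mean, by design.
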