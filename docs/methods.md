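# Methods

## Problem and model

A phase-gated treatment delivers beam only while the respiratory phase
φ ∈ [0.25, 0.75]. Phase is modeled as *linear in time* within each cycle:
a cycle is anchored peak-to-peak on the anterior–posterior (AP) surrogate
signal (0% = end-inhale peak, the common 4D-CT convention), and the phase
at time t inside cycle k is (t − t_k)/(t_{k+1} − t_k). The planned window
edges are therefore t_k + 0.25 P_k and t_k + 0.75 P_k, and the planned
window duration is exactly half the cycle period. This is the model under
which a perfectly regular phantom produces a window duration with zero
variance, which is what regular-phantom QA sessions show; amplitude-based
gating is out of scope.

The QA quantities are, per cycle: Δ_on = t_on − t25, Δ_off = t_off − t75,
the window duration t75 − t25 and the trigger-on duration t_off − t_on.
Per record the identity Δ_off − Δ_on = trigger − window holds exactly and
is asserted in tests. Aggregates are mean, *population* SD (divisor n) and
median; population SD is the default because per-cycle QA tables for
sessions of 5–6 cycles conventionally treat the session as the whole
population (a `sd_mode="sample"` switch exists). All internal arithmetic
is full precision; rounding (2 decimals, half away from zero) happens only
in rendered reports.

## Signal conditioning and cycle segmentation

1. **Min–max normalization** to [0, 1]; a constant signal yields zeros
   plus a `DegenerateSignalWarning`.
2. **Centered moving mean**, default window 5 samples, with shrinking
   windows at the ends (output length = input length).
3. **Cycle segmentation**: a coarse period estimate is taken from the
   autocorrelation maximum; peaks are detected with prominence ≥ 0.2
   (normalized units) and separation ≥ 0.4 × the period estimate. The
   trace is padded with a below-minimum sentinel so an extremum lying on
   the first or last sample is still a candidate (phantom traces commonly
   start at end-inhale).
4. **Anchor timing.** Interior peaks are refined to sub-sample precision
   by a local least-squares parabola over ±0.12 period (falling back to
   the sample time if the fit is not concave or its vertex leaves the
   window). Edge candidates get a different estimator: a single-harmonic
   least-squares fit a·cos(ωt) + b·sin(ωt) + c over one period around the
   candidate, with ω taken from the median interior anchor spacing. The
   fitted crest time both *times* the anchor and *validates* it — a trace
   that ends mid-rise places the crest beyond the trace edge and the
   candidate is dropped as a partial cycle (half-sample slack at the
   boundary). A local parabola is not usable there: with one-sided support
   on a flat sinusoid crest its vertex is unstable by design, while the
   harmonic fit averages ~one period of samples.
5. Cycles are the intervals between successive anchors; leading/trailing
   partial cycles are implicitly discarded.

## Trigger edges and pairing

A rising edge is timestamped at the first sample of the new state (same
for falling edges): reproducible, with a bias bounded by one sample
period. A trace starting with the flag high is an interval whose rising
edge was not observed (warned; `strict_edges` demotes it to incomplete);
a trace ending while on yields an incomplete final interval. Complete
intervals are assigned one-to-one to cycles greedily by overlap with the
planned [t25, t75] window, ties toward the earlier cycle; unmatched
cycles/intervals are reported, never dropped silently.

## EPID cine verification

Per frame, the mean pixel intensity over the ROI — 5 × 5 cm² at the
isocenter plane, projected to the imager by SID/SAD (metadata when
present, config otherwise) — is normalized to the series maximum. Frames
*strictly above* 50% are beam-on (a frame exactly at threshold is off:
ties are resolution artifacts); each contiguous run's duration is frame
count × frame period (0.04 s at 25 fps), hence always an exact multiple
of the frame period and within one frame of the true on-time. When EPID
segment and log interval counts match, durations are compared pairwise in
order; otherwise the difference of means is reported. An optional 3×3
per-frame median filter (off by default) is available for noisy imagers.

## The virtual phantom

`synthetic_phantom` emulates a motion phantom with a reflector block:
z(t) = A·w(2πt/T) with w = cosine (default; analytically tractable, peak
at t = 0) or cos⁴ (dwells at end-exhale like real breathing), x = y = 0,
plus Gaussian surrogate noise. The gate is derived from the *analytic*
phase: rising edges at t25 + L_on and falling edges at t75 + L_off in
continuous time, then sampled onto the log clock by index so a sample
coinciding exactly with an event is consistently the first sample of the
new state. EPID frames carry the beam-exposed fraction of each frame
interval (partial edge frames get intermediate intensity), an optional
one-frame exponential persistence tail, and seeded pixel noise. Dose
readings are nominal 99.95 cGy (a 100 MU delivery at ~1 cGy/MU daily
output) with 0.10 cGy measurement noise.

Defaults define the reference study conditions: period 5.32 s (so the
planned window is 2.66 s), amplitude 1.0 cm, 25 Hz sampling, 6 cycles,
surrogate noise SD 0.01 normalized units (optical-marker jitter relative
to ~1 cm motion), latencies +0.03 s on / −0.04 s off (typical measured
magnitudes for a well-behaved gating chain), EPID frame period 0.04 s.
Seeds are mandatory whenever any noise SD is positive; independent RNG
substreams keep motion, EPID and dose noise decoupled.

What the phantom does *not* emulate — and hence what passing tests do not
demonstrate about patient data: irregular or drifting breathing, baseline
shifts, predictive-filter behaviour, beam hold-offs, and the failure mode
where a trigger is logged but the beam does not actually deliver (only
the EPID cross-check can catch that).

## Tolerances and reporting

Default action levels: 0.10 s on |mean Δ_on|, |mean Δ_off| and the
window-minus-trigger duration gap (the customary gating temporal-accuracy
tolerance for linac QA), and 0.5% of the reference mean for the gated vs
non-gated dose difference. Boundary equality passes; disabled metrics are
"not evaluated". Reports carry a provenance block (input SHA-256 hashes,
full config, package version, seed) and are byte-deterministic given
identical inputs apart from the timestamp.

## Numerical choices and degenerate inputs

- Sampling-uniformity tolerance at read time: any interval within 10% of
  the nominal period; grosser gaps are rejected because phase times rely
  on linear interpolation of the time axis.
- Fewer than two usable anchors → empty cycle list with a diagnostic,
  not an exception; constant signals short-circuit the same way.
- Latency magnitudes above half a period are rejected in the simulator
  (the gate would wrap into the neighbouring cycle).
- Median of an even count is the midpoint of the two central order
  statistics; non-finite inputs to any aggregate are an error, and
  missing table cells must be excluded by the caller (recorded via `n`).

## Problem sizes

The test suite and the acceptance script run entirely on synthetic
sessions of 6 cycles at 25 Hz (~800 log samples, ~800 EPID frames of
64 × 64 px): large enough that every cycle statistic has 4–6 interior
cycles and the latency grid (on/off ∈ {0, 0.03, 0.05, 0.10} s, ten seeds)
exercises sub-sample recovery, small enough to re-run in seconds.

## Known limitations

- Peak anchoring assumes a dominant AP oscillation; bimodal surrogates
  or strong baseline drift would need detrending first (out of scope).
- The harmonic edge-anchor estimator assumes local sinusoidality over one
  period; for very asymmetric waveforms edge cycles are timed slightly
  worse than interior ones (they can be excluded by disabling padding in
  a fork of `segment_cycles`; interior behaviour is unaffected).
- Vendor binary log formats are not parsed; sessions must be exported or
  converted to the documented CSV dialect.
- The beam flag is a single boolean: beam-hold vs beam-off states are not
  distinguished.
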