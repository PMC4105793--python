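# Methods

This note documents the model implemented in `pulsedecomp`, the defaults
and numerical choices, what the synthetic-data generator does and does not
emulate, and the known limitations of the detector.

## The decomposition model

A heartbeat's peripheral pressure envelope is modeled as

```
p(t) = A · [ k(t) + c₂ · k(t − t₁₂) + r_i · k(t − t₁₃) + Σⱼ hⱼ · k(t − t₁₃ − j·Δ) ]
```

where `k` is a unit-amplitude component kernel of duration LVET (the
left-ventricular ejection time — all components share the ejection
pulse's width), `t₁₂` and `t₁₃` are the renal and iliac reflection
arrival delays, `Δ = t₁₃ − t₁₂` is the harmonic spacing, `r_i` the iliac
reflection coefficient and `hⱼ = r_i · (r_r·r_i)ʲ` the re-reflection
chain (each harmonic makes one extra round trip between the two sites,
costing a factor `r_r·r_i`).  The sensor emits the time derivative of
this envelope, digitized at 500 Hz.

Two affine couplings connect the decomposition to blood pressure and are
the basis of both tracking and simulation:

* `systole = g_s · P2P1 + b_s` with the population gain `g_s = 100`;
* `pulse pressure = g_p · T13 + b_p` with `g_p = 0.2` (mmHg/ms);
* `diastole = systole − pulse pressure` (the only arithmetic consistent
  with T13 tracking pulse pressure; the source material never states the
  diastole construction explicitly).

Offsets are patient specific.  "Chi-square minimization" of the offset at
fixed gain is unweighted least squares and has the closed form
`b = mean(ref − g·x)`; no iteration is performed.

## Component kernel

The kernel is an asymmetric raised-cosine lobe: a half-cosine rise over
20% of the LVET and a **squared** half-cosine fall over the remaining
80%, normalized to a unit peak, zero at both ends.

Both asymmetries are load-bearing, not cosmetic:

* *Identifiability.*  Two overlapping symmetric (Hann) lobes of equal
  width have second derivatives that are pure cosines of the same
  frequency; their sum is a single cosine with **one** curvature trough,
  so the components would be provably indistinguishable in the second
  derivative exactly where detection must work (normal LVET ≈ 300 ms with
  `t₁₂ ≈ 100 ms`).  A fast rise breaks the degeneracy and matches the
  physiological upstroke.
* *Smooth landing.*  A plain cosine fall ends with a curvature step at
  the support edge, which bleeds a spurious feature into the second
  derivative right where the next component's trough lies (measured:
  P3 localization errors of +40–70 ms).  Squaring the falling lobe makes
  the pulse land on zero with vanishing curvature, like the exponential
  diastolic decay of real pulses.

Tail elongation — the peripheral-resistance effect that stacks each
component on the previous one's decaying tail — is a causal exponential
filter (unit DC gain) with time constant `tail_tau_ms`, default **30 ms**.
Larger constants are available per `ComponentSpec`; above ~60 ms the
overlap interference degrades noise-free component timing beyond the
package's own accuracy targets (±4 ms), so the default stays small and
the P2 prominence that tail stacking produces in real pulses is instead
carried by the coupling-driven P2 amplitude (below).

## Ground-truth conventions in the simulator

Ground truth is only meaningful if it is measured the way the detector
measures.  Component "arrival times" are therefore defined as the
curvature-trough mark of an *isolated* tail-elongated kernel passed
through the full measurement chain (first difference, central difference,
20-point smoothing, trough search) — not the kernel's peak, which the
tail filter shifts by tens of ms.  Differences between component marks
(t₁₂, T13) are then exact in the absence of overlap interference.

For peripheral beat trains, each beat's P2 amplitude and P3 arrival are
*solved* so that the measured quantities equal the coupling-implied
targets: with the beat's spill-over background `s(t)` from earlier beats
already in the buffer, the P1 amplitude `A` and P2 amplitude `B` satisfy
the 2×2 linear system

* 50 ms-averaged envelope at the P2 mark, above the onset baseline,
  equals `P2P1 · (envelope at the P1 mark above baseline)`, and
* the beat's envelope peak above baseline equals the pulse pressure,

iterated over the (discrete) peak location until it stabilizes — usually
2–3 passes.  Targets are clamped to physiological ranges
(P2P1 ∈ (0, 1.5], T13 ∈ [180, 450] ms) with a per-beat flag.  The emitted
stream is the *first difference* of the envelope times the sampling rate,
so cumulative summation inverts it to machine precision; Gaussian sensor
noise is added on the derivative stream (the hardware's native domain).

What the generator does **not** emulate: arterial taper ("pulse narrowing
and heightening" toward the periphery), motion and contact artifacts,
baseline wander of non-integration origin, heart-rate-dependent LVET, and
any nonlinearity in the pressure couplings.  Passing tests therefore
demonstrate correctness of the algorithmic chain under the model's own
assumptions, not robustness to every failure mode of real recordings.

## Signal chain

* `differentiate` — central difference (one-sided at the ends), length
  preserving.
* `integrate` — trapezoidal running integral (the second-order inverse of
  the central difference, which keeps the round trip
  `integrate(differentiate(x)) ≈ x` below 1% of pulse amplitude), then a
  2nd-order low-pass **Bessel** filter applied forward–backward (zero
  phase; Bessel for its flat group delay, since T13 is a timing
  measurement), cutoff 80 Hz at 500 Hz sampling.  The cutoff sits well
  above the content of the narrowest physiological pulse (LVET 140 ms
  with a 28 ms rise) — reconstruction fidelity is the priority because
  noise is rejected later by the 20-point smoothing and the 50 ms P2
  averaging.  A final linear detrend removes the integration constant;
  beat segmentation reconstructs *without* the global detrend because
  every amplitude is referenced to its beat's onset value (the per-beat
  baseline correction), and a single global trend line would tilt short
  records.
* `smooth` — centered moving average, edge-truncated, default 20 samples
  (40 ms at 500 Hz).
* `detect_beats` — beats are anchored at the dominant positive upstroke
  peaks of the derivative stream (relative threshold 0.4 of the stream
  maximum, so detection is amplitude-scale invariant), with a 300 ms
  refractory period to reject P3-induced double triggers; the onset is
  the zero-crossing preceding the upstroke maximum, earliest sample on
  ties.  Indices are 0-based, intervals half-open.

## Detector

Candidate component locations are local minima of the smoothed second
derivative that are genuine curvature inversions (negative value) and
follow positive curvature (the upstroke edge counts when no interior
maximum exists), with prominence at least 1% of the beat's second-
derivative range.  P2 and P3 are the deepest candidates inside their
windows **relative to the detected P1** (70–140 ms and 180–450 ms); ties
go to the earliest candidate.  If no candidate follows the first trough
inside the P2 window, the first trough is taken to be the merged P1+P2
complex: the beat is flagged `p1_merged` and P1 is re-estimated as the
first positive-going inversion after the onset (first raw local minimum,
however shallow; falling back to the first upward zero-crossing, then to
the point of strongest descent deceleration).

*Known limitation:* once a merge has fully annihilated the P1 landmark,
no estimator recovers its isolated-component position accurately — across
a grid of merge severities the inversion estimate lands 14–50 ms early of
the isolated mark.  Merged beats are flagged for exactly this reason and
the flag should be treated as a timing-quality warning.  Amplitude
measurements reference the envelope value at beat onset, which makes
P2P1 invariant to DC offset and amplitude scaling; P1 uses a point value
while P2 uses the 50 ms centered average (the source algorithm specifies
the averaging only for P2).

The optional harmonic search (P4, P5) extends the same minima logic past
P3 with a spacing prior of `t₁₃ − t₁₂` (window ±50% of the spacing) and
no prominence floor, because the harmonics are attenuated by
`(r_r·r_i)ʲ` ≈ 6% per step.  It is disabled by default.

## Evaluation

Stream synchronization minimizes the mean squared difference between
inter-beat-interval sequences over an exhaustive integer-lag search; the
beat-to-beat IBI randomness acts as a fingerprint, and series without
variability are flagged degenerate rather than silently aligned.
Agreement uses Pearson R² with an OLS fit plus Bland-Altman statistics:
bias = mean difference, SD with `n−1`, limits of agreement ±1.96 SD
(reported alongside the SD; the AAMI SP-10 trend comparison uses the SD
itself, threshold 8 mmHg).

## Problem sizes and defaults

Reference test conditions, chosen once as representative physiology:
mean IBI 900 ms with 50 ms SD; systole drifting sinusoidally 110–140 mmHg
and pulse pressure 40–60 mmHg (periods of 120 s and 80 s — slow relative
to a 30 s calibration window); sensor noise 2% of the clean derivative
stream's peak amplitude; LVET 300 ms, `t₁₂` 100 ms, `t₁₃` 280 ms,
reflection coefficients 0.17 (renal) and 0.35 (iliac); the five-pulse
scenario uses LVET 140 ms with two harmonics.  The end-to-end acceptance
run covers 10 minutes of beats (~666) and completes in roughly a second;
the full test suite runs in a few seconds.
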