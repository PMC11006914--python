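# Methods

This note documents the models, detector definitions, parameter choices and
known limitations of `axospindle`. All timestamps are seconds, sample
indices are 0-based, and intervals are half-open `[start, end)`.

## Signal conditioning

The raw 25 kHz traces are reduced to a 1 kHz LFP by a 50th-order
Kaiser-window FIR low-pass followed by decimation by 25. The FIR cutoff is
400 Hz (80 % of the post-decimation Nyquist) with β = 5.65 (~60 dB
sidelobes). With only 51 taps the transition band is wide (≈ ±900 Hz), so
the filter's job is aliasing protection, not a brick wall: tones at or
above ~700 Hz, which would fold into the output band, are suppressed by
20 dB or more (a 1 kHz tone, which folds onto DC, by > 100 dB), while
everything the downstream analysis uses (< 100 Hz) passes with < 1 %
error. A tone sitting exactly at the 400 Hz cutoff is only ~6 dB down —
but it is below the new Nyquist and therefore not aliased.

Band filters: spindle band = 6th-order Butterworth high-pass at 8 Hz
cascaded with 8th-order low-pass at 16 Hz; spike band = 4th-order elliptic
300–3000 Hz (0.1 dB ripple / 40 dB attenuation — conventional spike-band
values, exposed as module constants). All IIR filters are applied
**zero-phase** (forward–backward) by default: the quantities of interest
are sub-millisecond event-time differences, and causal group delay would
bias them by more than the effects being measured. Causal application is
selectable (`zero_phase=False`). Zero-phase filtering squares the
magnitude response; the stated gains account for this.

Instantaneous phase uses the sine convention — 0° at the positive-going
zero crossing, 90° at the peak, 270° at the trough — implemented as
`angle(i·hilbert(x))`.

The time–frequency display uses an analytic generalized Morse wavelet with
γ = 3 and squared time-bandwidth P² = γβ = 60 (β = 20), implemented
directly in the frequency domain; the ridge of a pure tone falls on the
tone frequency to within one (log-spaced) frequency bin.

## Spike detection and axon identification

Negative peaks of the spike-band trace are detected against the channel
noise SD with two amplitude windows, 5–50 SD and 50.1–500 SD, so very
large tunnel spikes are not clipped away by a single upper bound; a 1 ms
refractory lockout follows each peak. The noise SD is the plain standard
deviation of the spike-band trace (a median-based robust estimator is
available via `robust_sd=True`; the plain SD is the default for fidelity
to the original detector).

Cross-electrode matching is greedy nearest-neighbour with each spike used
at most once, within ±2 ms (covers 0.1–0.6 m/s over 200 µm). Signed
delays (downstream − upstream) are binned at 0.04 ms (one 25 kHz sample).
The matched fraction is the normalized matching index. Axon candidates are
local maxima of the 3-bin-smoothed histogram; each axon's delay set is the
matched delays within ±0.2 ms of its mode, and an axon is excluded when
its delay SE exceeds the mean |delay| or is (numerically) zero — a
single-pair or degenerate mode carries no timing evidence. Velocities are
reported to 2 significant figures. No spike sorting is attempted: most
tunnels carry one axon, and multi-axon tunnels appear as multimodal delay
histograms.

## Spindle detection

Band-pass (8–16 Hz) → Hilbert envelope → two thresholds computed from the
**whole channel's** envelope: the event threshold mean + 2.5 SD (must be
exceeded at least once) and the boundary threshold mean + 1.5 SD (must be
exceeded continuously for > 300 ms; the crossings define the event
boundaries). Whole-channel baselines are appropriate because recordings
are short (5 min) and stationary; per-epoch baselines are unnecessary.
Detections < 500 ms apart are merged and all metrics recomputed over the
merged span. Since both thresholds are in SD units of the channel's own
envelope, detection is invariant to amplitude rescaling.

Metrics: area = trapezoidal integral of the envelope over the event;
amplitude = area / duration; inter-spindle interval = next start − this
end. Events shorter than 0.4 s stay in the event table but are flagged and
excluded from distribution statistics, as are channels contributing fewer
than two spindles.

The detection band is 8–16 Hz while the phase analysis uses 10–16 Hz
(`phase_band_hz`), reflecting the narrower band conventionally used for
phase extraction.

## Slow waves and conduction delays

Sub-millisecond slow-wave delays are unresolvable at 1 kHz, so trough
detection runs on the 25 kHz raw trace low-passed at 50 Hz (zero-phase,
4th-order Butterworth; the cutoff is this package's choice, exposed as
`SMOOTH_HZ`). Troughs must satisfy all of: ≥ 100 ms spacing, |amplitude| ≥
20 % of the channel's largest negative deflection (computed per channel
per recording), amplitude ≤ −100 µV, width at half prominence ≥ 4 ms
(rejects spike transients). Pairing across the tunnel is greedy minimum
|Δt| with a 5 ms cap; unmatched troughs are reported.

Slow-oscillation epochs for nesting are peak → positive-to-negative zero
crossing → trough triplets on the 0.5–4 Hz component, retaining epochs in
the top 40 % of peak amplitudes *and* top 40 % (most negative) of troughs,
ties kept.

`summarize_delays` compares spike and slow-wave delay populations with a
Welch two-sample t-test and derives percent-slower from the group
velocities **after rounding to two decimals**, matching how such figures
are conventionally printed (e.g. spike 0.35 ms → 0.57 m/s vs slow-wave
1.32 ms → 0.15 m/s gives 74 % slower; 0.4 ms/0.86 ms → 0.5 vs 0.23 m/s →
54 %). The amplitude-attenuation check is a one-sided paired t-test of
|near| > |far| trough amplitude by axon.

## Nesting

Each spindle's lag is its envelope-peak time minus the peak time of the
latest preceding slow oscillation (an onset-based reference is
selectable). Lags are histogrammed on 50 log-spaced bins; the power-law
tail is fit by OLS of log10(count) on log10(bin center) over non-empty
bins above a short-time boundary, grid-searched over the bin left edges
within [0.001, 0.5] s for maximal R². Empty bins are skipped, not
floor-imputed — imputation biases the slope. For a lag sample drawn from
p(t) ∝ t^−α, log-spaced bin counts scale as t^(1−α), so the expected
fitted slope is −(α − 1). The median lag is reported alongside, being
binning-independent.

## Phase coupling and correlations

Spikes inside spindle windows get the instantaneous phase of the 10–16 Hz
component at their peak time; 50 bins over [0°, 360°). Uniformity is
tested with the Hodges–Ajne omnibus statistic m (minimum count in any
closed half-circle): exact p = (n − 2m)·C(n, m)·2^(1−n) for n ≤ 50, the
standard asymptotic approximation above; when 2m = n (perfectly balanced
half-circles) p is 1 by construction, which the raw formula does not
handle. The resultant vector length r̄ is always reported. The
multi-array effect size is (max − min pooled normalized bin) divided by
the SD of the per-array normalized bin values — a range-based measure that
can be small even when the omnibus test is significant.

Envelope correlations zero each channel's spindle envelope outside its own
spindle windows, then evaluate the coefficient-normalized
cross-correlation over lags |ℓ| ≤ 0.1 s; the peak r and its lag are
returned, and distance/|lag| bounds the propagation velocity from below.
Group comparisons use one-way ANOVA with Tukey HSD (statsmodels); metric
comparisons log-transform first.

## Synthetic recordings

The generator emulates, per tunnel and at 25 kHz: biphasic 1.2 ms spikes
(Poisson, 2 ms refractory), slow oscillations (0.3 s positive lobe +
0.2 s negative lobe, depth 400 µV, quasi-rhythmic at ~1 Hz), spindle
bursts (Gaussian-envelope 12 Hz carrier, envelope-peak-aligned to carrier
phase 90°, duration log-normal with mode 0.65 s, onset lagged after a
slow-oscillation peak by a power-law draw with α = 1.5 on [0.05, 3] s),
optional von Mises phase locking of in-spindle spikes, and independent
Gaussian noise (10 µV SD). Conduction delays are applied as integer
sample shifts (spikes 0.40 ms = 10 samples; slow waves/spindles 0.86 ms →
22 samples = 0.88 ms recorded as truth). The four-tunnel preset
(`preset_hippocampal_tunnels`) places these values inside the reported ranges
(velocities 0.5 m/s spikes vs 0.23 m/s slow waves; 10 spindles/min;
duration modes 0.43–0.75 s).

What the generator does **not** emulate: electrode-coupling variability,
non-stationary baselines, bursting spike statistics, multi-axon tunnels
with overlapping amplitude distributions, 1/f background, or
volume-conducted cross-talk. Passing recovery tests therefore demonstrates
correctness of the detectors and estimators under their stated model, not
robustness to every property of real MEA data.

Spindles are drawn ~1 s apart at minimum so that ground-truth windows map
1:1 onto detections; spindle-count recovery and recall/precision are
evaluated against what was actually rendered into the trace.

## Problem sizes and numerical choices

The shipped test suite and acceptance script use 60–120 s single-tunnel
recordings for unit-level recovery and the 300 s four-tunnel preset for
end-to-end recovery — sizes at which every estimator's sampling error is
comfortably inside its stated tolerance (spike delay within one 25 kHz
sample; slow-wave mean delay within 0.25 ms, with per-trough timing jitter
~1–2 ms averaged over ~200 pairs). The slow-wave trough jitter is set by
smoothed-noise slope vs trough curvature; sharper trough lobes or lower
smoothing cutoffs would reduce it further.

Degenerate inputs: flat channels yield no spindle/trough events and raise
on spike detection (SD = 0); all-equal values give a flagged degenerate
log-normal fit; identical groups produce a "no variance" notice instead of
an F-test; delay SEs below 1e-9 ms are treated as exactly zero for the
exclusion rule.

## Known limitations

* The matched-fraction normalization of the matching index is a
  documented reconstruction; published variants differ in the denominator.
* The log-log nesting fit needs pooled lags (hundreds); per-channel fits
  on 5-minute recordings are noisy, and the grid search will overfit small
  samples.
* Two-component log-normal fits are retained only when they improve R² by
  > 0.02; heavily overlapping modes (ratio < ~1.3) may collapse to one
  component.
* Only integer decimation ratios are supported (25 kHz → 1 kHz).
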