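# Methods

This note documents the models, estimators, and design choices behind
`lfpac`, and what the synthetic-data validation does and does not show.

## Recording and schedule model

A session is a multichannel LFP recording (left/right hippocampal depth
channels, optional epidural channels) in µV at a nominal 5 kHz. Time is
seconds from recording start; intervals are half-open `[start, end)` and
the sample index of time *t* is `floor(t·fs)`, so adjacent epochs
concatenate without overlap. The daily stimulation schedule is
parameterized as *n* trains of duration *d* with pauses *p* and flanking
windows: train *k* (1-based) starts at `pre + (k−1)(d+p)`; the defaults
(4 × 50 s, 5-min pauses, 5-min flanks) give a 1700-s session. Analysis
epochs are derived from the schedule — `pre5`/`post5` are the flanking
windows adjacent to the first train onset and last train offset, and
`pre30`/`post30` are 30-s windows at the same boundaries. Sessions without
a schedule (sham) contribute their first and last 5 minutes. Epochs never
overlap a train, so no stimulus-artifact removal is attempted beyond this
exclusion.

EDF (16-bit, physical dimension µV, one 1-s record per second) is the
on-disk interchange format; writing uses a built-in encoder with per-channel
physical ranges set to the observed min/max (quantization error ≤
range/2¹⁶), and reading goes through MNE. An `.npz` + JSON-header container
is provided where bit-exactness matters. The acquisition chain's analog
filter corner frequencies are carried as metadata only and never applied:
the recorded values are internally inconsistent (the printed high-pass and
low-pass corners appear transposed) and they describe the amplifier, not
the analysis.

## Synthetic LFP generator

The generator produces sessions whose statistical structure matches what
the analysis assumes, with ground truth for every injected feature.

* **Background**: 1/f^β noise synthesized in the frequency domain
  (amplitudes ∝ f^(−β/2), flattened below 1 Hz to bound drift; uniform
  random phases), demeaned and scaled to a target RMS. Default β = 1,
  RMS 50 µV.
* **Delta rhythm and coupling**: a delta oscillation `A_δ·cos φδ(t)` plus,
  per coupled carrier, `a·(1+κ·cos φδ)/(1+κ)·cos(2πf_c t)`. The normalized
  envelope makes the peak amplitude κ-independent, so modulation depth
  varies without changing band power. By default the delta frequency
  wanders (an AR-smoothed deviation, SD 0.3 Hz, 2-s correlation time)
  because in-vivo delta is irregular; a strictly periodic rhythm is
  unrealistic, and its envelope–phase relation is invariant under circular
  shifts, which would make shift surrogates blind to true coupling. The
  low-level waveform builder keeps jitter optional (default off) so its
  deterministic contract — envelope maxima exactly at delta phase 0 for
  κ = 1 — remains testable.
* **Theta**: a sinusoid (default 7 Hz, 30 µV) whose amplitude can step by a
  multiplier after the last stimulation train; κ can step simultaneously.
  The analytic theta share of the deterministic components'
  mean-square power is recorded as ground truth (Parseval bookkeeping;
  the carrier mean square is `a²(1+κ²/2)/(2(1+κ)²)`).
* **Discharges**: per subtype, homogeneous Poisson event times. Spikes are
  raised-cosine deflections of nominal width 20–70 ms, sharp waves
  70–200 ms, and a polyspike is 2–4 spike deflections within 500 ms counted
  as ONE event (per-event, not per-peak, counting). A raised-cosine bump's
  full width at half maximum is half its nominal width, so twice the
  measured FWHM recovers the template width — the convention the detector
  uses. Event amplitude is a multiple (default 6) of the composite
  background SD (noise + rhythms, known analytically), so detector tests
  are SNR-controlled. Left and right channels share the deterministic
  components and event stream but carry independent noise.
* **Cohort logs**: per animal, daily seizure counts Poisson(baseline) for
  10 "before" days and Poisson(baseline × rate multiplier) for 10 "DBS"
  days; durations lognormal with a stated mean and CV (σ² = ln(1+CV²)),
  scaled during DBS; Racine grades uniform on 3–6 (lower grades are not
  quantified). Each animal carries a latent PAC level
  `base + slope·(rate_before − rate_dbs) + noise` linking coupling strength
  to outcome.

What the generator does **not** emulate: ictal waveforms, electrode drift
and movement artifacts, line noise, non-Poisson discharge clustering,
state-dependent (sleep/wake) rhythm changes, and volume-conduction
asymmetries. Tests passing on this generator therefore certify estimator
correctness under the assumed signal model, not robustness to every
artifact of in-vivo data.

## IED detection

The published criterion — amplitude greater than 2 SD of background — was
applied by manual scoring; an amplitude floor alone fires continuously on
broadband noise. The automated detector therefore stacks four stages:

1. **Candidate stage**: local extrema of the 3–250 Hz band-passed signal
   exceeding 4.5× that band's robust SD. Discharges concentrate their
   energy in this band while the 1/f background does not; for band-limited
   Gaussian noise of bandwidth B the level-upcrossing rate is
   ≈ B·exp(−m²/2), which falls below 1/min near m = 4.5 for B ≈ 250 Hz.
   This stage controls the false-alarm rate; it is deliberately below the
   amplitude of any event satisfying the published criterion at realistic
   SNR.
2. **Amplitude criterion**: the candidate, refined to the nearest raw-trace
   extremum, must exceed k·SD on the raw trace (k = 2 by default,
   configurable). Background SD is 1.4826 × the median absolute deviation
   of the demeaned trace — robust, so sparse large events do not inflate
   their own threshold and no circular event-masking pass is needed.
   Baseline-to-peak amplitude is used (the peak-to-peak reading of the
   criterion is not).
3. **Duration gate**: twice the FWHM of the principal deflection must lie
   within [20, 200] ms with a ±25% measurement allowance (the FWHM read
   off a raw trace jitters with the background; class boundaries stay
   exact).
4. **Slope gate**: the band-limited slope (difference of 10-ms means 10 ms
   apart) within ±100 ms of the peak must exceed 3× the robust SD of that
   slope over the whole trace. A per-sample first difference would be
   dominated by broadband noise and would reject every sharp wave; the
   10-ms scale preserves the gate's intent — rejecting slow high-amplitude
   waves — while admitting the 70–200 ms event class.

Peaks closer than 500 ms merge into one event timestamped at the first
peak. Classification is by principal-deflection duration (spike 20–70 ms,
sharp wave 70–200 ms), with ≥2 event-scale deflections (supra-threshold
and prominent at ≥25% of the principal one — prominence separates distinct
deflections from noise texture on a single broad wave) within 500 ms
classed as a polyspike. Out-of-range durations are kept as `unclassified`:
they count toward total rates but not subtype proportions. Events inside
stimulation trains are excluded from counting. Rates: per-channel
events/min, bilateral mean (L+R)/2, lateralization (L−R)/(L+R) with 0 for
silent channels.

On the generator's study conditions (8×SD events) the detector achieves
recall ≥ 0.9 and precision ≥ 0.8 with < 1 false event/min on pure noise;
residual misses are mostly pairs of independent events closer than the
500-ms merge window, which the per-event counting convention fuses.

## Spectral analysis

Welch averaged periodograms with Hann tapers on 10-s windows, 50% overlap
(0.1-Hz resolution), mean averaging. Bands are half-open [low, high):
delta 1–4, theta 4–12, beta 15–30, gamma–fast-ripple 30–600 Hz; the shared
4-Hz edge belongs to theta. Relative power divides by the total over
[1, 600) Hz — the union support of the named bands — making relative
powers invariant under amplitude scaling; the four bands sum to ≤ 1 since
12–15 Hz is uncovered. The taper and the denominator are package
conventions (only the window length, overlap, and band edges are given by
the study design). The pre/post theta comparison reports per-side relative
theta and percent changes plus the overall percent change computed from
side-averaged values; 100 × (30.3 − 25.9)/25.9 ≈ 17% reproduces the
published amplification from its published operands.

## Time-resolved PAC

For each 18-s window (50% overlap; 18 windows of the 1-Hz phase lower edge
per window, 32 windows per 300-s epoch):

1. the window is band-passed to the fast band of interest and the dominant
   modulated frequency fA\* is the frequency of maximum spectral power in
   the band (Hann periodogram);
2. the raw window is re-filtered to fA\* ± 1.5× the upper phase-band edge —
   at least the modulation sidebands fA\* ± fP — and the analytic envelope
   A(t) is taken;
3. delta phase φ(t) comes from the 1–4 Hz band of the full epoch;
4. coupling = |⟨A·e^{iφ}⟩|/√⟨A²⟩, preferred phase = arg⟨A·e^{iφ}⟩. The
   statistic is bounded by 1 (Cauchy–Schwarz) and invariant under amplitude
   scaling. For the generator's envelope model it evaluates to
   κ/(2√(1+κ²/2)) in the noiseless limit — strictly increasing in κ.

All band-pass filters are zero-phase FIR (Hamming-windowed sinc, applied
by FFT convolution of a symmetric kernel; transition width scales with the
lower band edge). Two seconds of filter/Hilbert edge are trimmed from each
window before averaging — at a 1-Hz phase edge the Hilbert transient is
substantial. MaxPAC is the maximum over the fast-frequency grid (2-Hz
steps below 150 Hz, 5-Hz above) of the across-window mean coupling of the
windows whose dominant frequency landed on that grid point, ties broken
toward the lowest frequency. Whether the published "maximum PAC" is this
(peak of across-window means) or the mean of per-window peaks is not
stated in the source method description; the former is adopted because it
is deterministic and matches "peak value of coupling strength".

The comodulogram scans explicit (fP, fA) grids, filtering per cell rather
than detecting a dominant frequency. Per session, epoch-level PAC yields
2 epochs × 2 channels × 4 fast bands = 16 MaxPAC values.

**Independent cross-check.** The Kullback–Leibler modulation index bins
the phase into 18 bins, averages the envelope per bin, normalizes to a
distribution P and reports KL(P‖uniform)/log 18 ∈ [0, 1]. It shares no
code path with the mean-vector statistic beyond filtering, and the two
agree in rank (Spearman ≥ 0.9) over the κ sweep.

**Surrogate control.** Circular shifts of the envelope against the phase
(by ≥ one slow cycle, per window) give a null distribution of the
across-window mean coupling; the (1−α) quantile is the significance
threshold. The headline coupling values remain raw (un-normalized) to
match the published table conventions; surrogates are an optional
extension. Note the caveat above: shift surrogates require an aperiodic
phase signal, which the generator's default frequency jitter provides.

## Study statistics

Percent change is relative to the "before" value; reduction and increase
modes are exact negatives. Seizure-rate change is before − during
(positive = improvement). Group comparisons: paired t, unpaired t with
Welch correction by default (group sizes are unequal in this design;
pooled-variance is available), or one-way ANOVA; identical paired samples
return (t = 0, p = 1) rather than the 0/0 indeterminate. Correlations are
sample Pearson r with two-sided p, emitted into an (epoch × side × band)
grid. No multiple-testing correction is applied across bands or sides by
default, matching the per-band reporting convention; a Holm option exists.
Cohort-level percent rate reduction is computed from group mean rates (a
ratio of means): the mean of per-animal ratios is Jensen-biased upward at
Poisson(10) counts (~8 points at this design) and undefined for animals
with zero baseline seizures. The outcome table keeps one row per animal
with explicit NaNs for missing predictors; unmatched predictor animals
raise a join error rather than dropping silently.

## Numerical and scale choices

* FIR kernels are odd-length and symmetric; `mode="same"` FFT convolution
  gives exact zero phase. Kernel length is capped at a third of the signal.
* The envelope-spectrum frequency resolution at 18-s windows is ≈ 0.06 Hz;
  carrier-recovery tests allow the fast-frequency grid step (2 Hz).
* Tests and the acceptance script run at reduced sampling rates
  (1000–1500 Hz; fast-ripple analyses need fs ≥ 1200) and shortened
  schedules (2 × 10-s trains, 60-s flanks) — the estimators are
  rate-independent and these sizes keep the whole validation suite under a
  minute while preserving ≥ 5 PAC windows per epoch. Full-scale 1700-s
  sessions at 5 kHz run identically (the README example uses 1700 s at
  1 kHz).
* Degenerate inputs: constant traces yield SD 0 with a warning and no
  detections; zero envelopes make the modulation index undefined (error);
  zero pre-theta makes the percent change undefined (error); silent
  channels give lateralization 0 by convention.

## Known limitations

* The detector is tuned for transient detection on a stationary
  background; slow baseline drift beyond the 1/f model, movement artifacts
  or electrode pops would enter the candidate stage and are not modeled.
* Polyspike recall is bounded by the 500-ms merge convention: independent
  events closer than the merge window are fused by design.
* tPAC values depend on the narrowband bandwidth convention (here
  3× the upper phase edge); absolute couplings are comparable within this
  package, not across PAC implementations — rank agreement with the
  modulation index is the portable statement.
* The cohort simulator draws i.i.d. daily counts; it does not model
  seizure clustering or day-to-day rate drift, so day-course trends beyond
  the imposed multipliers are flat by construction.
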