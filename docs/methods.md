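# Methods

## The forward model

The generator maps ground-truth spike trains to two-channel fluorescence.

**Burst grouping.** Spikes are grouped into bursts as maximal runs with
inter-spike gaps ≤ 250 ms (the widest event bin used by the detection
analysis). Amplitudes are defined per burst rather than per spike because
indicator responses to closely spaced spikes saturate: a burst of *n* APs
peaks at

    A(n) = A_max · (1 − (1 − A₁/A_max)ⁿ),

a two-parameter saturating curve anchored at the single-AP amplitude A₁ and
the dynamic-range ceiling A_max, monotone in *n*. Explicit `{n: amplitude}`
anchor points can override the closed form.

**Transient kernel.** Each burst contributes
k(t) = (1 − e^(−t/τ_r))·e^(−t/τ_d), scaled to peak A(n). Data sheets quote
half-rise/half-decay times rather than time constants, so (τ_r, τ_d) are
obtained by inverting the half-time equations: the kernel's shape depends
only on ρ = τ_r/τ_d and its half-rise/half-decay ratio is monotone in ρ, so
the inversion is a bracketed 1-D root solve plus a rescaling. The family
caps that ratio at ≈ 0.138 (the t·e^(−t/τ) limit); indicators with slower,
sigmoidal rises cannot be represented exactly, and the half-rise presets —
which are estimates anyway, see below — are kept inside this range.

**Kernel anchor.** The kernel is anchored at the burst's *last* spike:
calcium accumulates over a burst, so the fluorescence peak follows the final
AP. For single spikes this is the spike time. The choice matters only for
long trains: a 160 Hz, 2 s tetanus is one 320-spike burst whose response
peaks just after stimulus offset and then decays with the indicator's
half-decay time, which is how tetanus decay times are actually measured.
The model does not resolve the within-train rise dynamics of a tetanus.

**Imaging.** F_np = F₀(1 + slow fluctuation), where the fluctuation is
white noise smoothed by a 1 s Gaussian kernel and scaled to the configured
sd (a Gaussian process with ~1 s correlation length — slow relative to
transients, as shared neuropil activity is). F_cell = F₀(1 + ΔF/F₀) plus
additive white noise of sd `noise_sd · F₀` on raw fluorescence (shot noise
is not modelled); the ROI reads F_meas = F_cell + r_true·F_np. All
randomness flows from a single integer seed through `numpy` SeedSequences,
so identical configurations are bitwise reproducible.

## Indicator presets

Three settings reflect that the same protein behaves differently across
preparations. Values anchored to published measurements: the in vivo V1
post-stimulus half decays (0.390 s jRGECO1a, 0.640 s jRCaMP1a, 0.500 s
jRCaMP1b, 0.300 s R-GECO1), the fly NMJ single-AP amplitudes (11.6%
jRGECO1a, 8.6% jRCaMP1a, 4.5% GCaMP6s) and post-tetanus half decays
(0.42 s jRGECO1a, 0.43 s GCaMP6f), the jRCaMP1a culture dynamic range
(160%) and the stated amplitude ratios vs parents (8.5× jRGECO1a/R-GECO1,
24×/13× jRCaMP1a/jRCaMP1b over RCaMP1h). Everything else — all half-rise
times, in vivo and culture absolute amplitudes, saturation ceilings — is a
documented estimate; V1 presets carry `amplitude_anchored=False` because no
numeric in vivo single-AP amplitude was ever published for these
indicators. The NMJ decay preset reuses the post-tetanus value for all
burst sizes, since the kernel's decay is burst-size independent; this is a
model simplification, not a measured single-AP decay. The NMJ half-rise
estimate is 0.02 s: bouton transients rise within about one frame at
30 fps. R-CaMP2 (a published in vivo half decay of 0.330 s) is not in the
preset registry, which covers the seven indicators the screen and in vivo
comparisons revolve around.

## Analysis conventions and numerical choices

- **Eligibility.** The 3% baseline-over-neuropil criterion uses the same
  pre-stimulus windows as F₀ (the criterion is about F₀ reliability); the
  whole-recording alternative is not implemented.
- **Trial tables and ANOVA.** Each trial is normalized by its own F₀ (1 s
  before stimulus onset). The ANOVA uses nine groups of five: blank
  observations are condensed to one per repetition cycle (mean of the 8
  blank periods in the cycle) so all groups are balanced.
- **Tuning fit.** Classical one-way fixed-effects ANOVA; the amplitude gate
  uses trial-averaged stimulus-period means per direction (frame-wise
  maxima would be noise-dominated). The double-Gaussian fit uses minimal
  circular distance on [0°, 360°), bounds σ ∈ [5°, 180°] and amplitudes
  ≥ 0, and four deterministic multi-starts (seeded jitter of θ_pref and a
  ladder of σ initializations). The second Gaussian sits at Δ = 180° by
  default — stimuli are directions spanning 360°, so the paired peak of an
  orientation-tuned cell is the opposite direction; the literal Δ = 90°
  variant is available (`fit_tuning(..., delta=90.0)`). OSI evaluates the
  fitted model at θ_pref and θ_pref + 90°. A flat curve returns a
  degenerate-flagged fit rather than an error.
- **Half times.** Linear interpolation between the bracketing frames; the
  returned value is the elapsed time from the peak sample (or event time)
  to the interpolated crossing. Traces that never cross half peak are
  flagged censored, not errors. Peak detection is the global maximum of
  the analysis window. Population-average transients are aligned on their
  maxima before averaging; a 3-sample moving average exists for display
  only and is never applied before estimators.
- **Exponential fits.** "Small fitting error" is quantified as normalized
  RMS residual (default threshold 0.1) since no number was ever published.
- **Fourier tracking.** Rectangular window, no padding, magnitude spectrum
  normalized at 0 Hz, value read at the bin nearest the drive frequency.
  Spectra are computed per cell and then averaged where populations are
  summarized; computing on averaged traces is the caller's alternative.
- **Detection.** Event bins: jRGECO1a 100 ms for 2 APs, +25 ms per AP to
  250 ms at 8; jRCaMP1a 150 ms for 2 APs, +50 ms per AP capped at 350 ms.
  Snippets cover 10 baseline frames plus 1 s (fast indicators) or 2 s
  (slow) and are re-baselined per event (F₀ = mean of the 10 pre-frames).
  d′ uses pooled equal-weight sample variances. The accuracy threshold is
  the empirical (1 − FPR) noise quantile with the 'higher' convention —
  conservative, so the realized FPR never exceeds the target; with fewer
  than 1/FPR noise scores a warning is raised. Projections use per-class
  templates by default; `analyze_events(..., common_template=True)`
  projects every class on the 1-AP template instead.
- **Depth fits.** Unweighted log-linear least squares by default (the
  nonlinear refinement is available and agrees within 1% on noiseless
  data); non-decaying profiles are flagged with λ = ∞.
- **Screen.** The unit of replication is the cell, with per-well
  aggregation left to the caller (both units appear in practice). Baseline
  window 1 s at 35 Hz. Per-cell kinetics jitter is lognormal with one
  shared "speed" factor multiplying both half-times, so the kernel shape
  stays inside the representable family. For slow trains whose individual
  responses are resolved (e.g. 1 Hz NMJ stimulation), `well_metrics`
  accepts event times and then reports the per-event amplitude above the
  local 10-frame baseline, averaged over events — the global-maximum peak
  would otherwise carry both the summation tail of the preceding response
  and an extreme-value noise bias.

## Synthetic study conditions

The visual-cortex generator emulates the standard protocol: 4 s blank +
4 s drifting grating per trial, 8 directions × 5 trials (320 s at 15 Hz).
Responsive cells fire inhomogeneous-Poisson spikes with double-Gaussian
direction tuning; defaults are 0.2 Hz spontaneous, 0.5 Hz untuned evoked
baseline, 3–5 Hz at the preferred direction, widths 25–40° — typical
sparse L2/3 responses. Keeping evoked rates at a few Hz also keeps burst
saturation mild, which is the regime in which rate-domain tuning
parameters are identifiable from ΔF/F₀; at several-fold higher rates the
saturating amplitude curve visibly flattens tuning peaks and biases σ
upward, a real property of the measurement rather than an estimator
defect. Ground-truth OSI is defined on the rate-domain tuning curve.

Depth profiles span 100–500 μm in 10 μm steps with 10% multiplicative
noise; the benchmark uses 19 red and 14 green dendrites with generating
length constants of 130 μm and 75 μm. The NMJ benchmark uses 12 fields of
view × 4 boutons, 1 Hz stimulation for 2 s, additive ΔF/F₀ noise of sd
0.02, with the field of view (the mean bouton transient) as the unit of
analysis. The culture screen runs 83 Hz trains of {1, 2, 3, 5, 10, 20,
40, 80, 160} APs at 35 Hz imaging.

What the generator does *not* emulate: photobleaching and photoswitching,
lysosomal accumulation and other non-responsive fluorescent species,
shot-noise statistics, motion artifacts, ROI segmentation errors, and the
within-train rise of tetanic responses. Passing recovery tests therefore
demonstrates correctness of the estimators under the stated model, not
robustness to those real-data pathologies.

## Problem sizes

The test suite and the benchmark script run deterministic, seeded
simulations sized to the study they emulate where that study is small
(19/14 dendrites, 12 NMJ fields of view, 199 single-AP events, 8 × 5
trial protocols) and to a few tens of cells or tens of replicates for
calibration and recovery checks (10⁴ cells for the classifier's type-I
rate, 10⁵ scores for the Gaussian closed-form detection checks), which
keeps each suite comfortably within a desktop run.

## Known limitations

- The two-exponential kernel cannot represent half-rise/half-decay ratios
  above ≈ 0.138; presets are chosen inside the family, and the calibration
  raises a clear error otherwise.
- Tetanus responses peak at stimulus offset by construction (last-spike
  anchoring) instead of rising through the train.
- OSI recovery is compared against rate-domain truth; under strong
  saturation the ΔF/F₀-domain OSI is genuinely smaller.
- The depth fit assumes a single exponential and absorbs laser-power
  normalization into the fitted prefactor.
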