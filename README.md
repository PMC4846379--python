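# gecibench

Analysis pipeline for quantifying the performance of genetically encoded
calcium indicators (GECIs), with a spike-to-fluorescence forward model that
makes every stage verifiable by parameter recovery.

Red-shifted GECIs such as jRGECO1a and jRCaMP1a/b are attractive for in vivo
imaging — less scattering and blood absorption, deeper imaging, compatibility
with blue-light optogenetics — and their characterization rests on a standard
set of analyses: neuropil-corrected ΔF/F₀ extraction, visual-responsiveness
classification and orientation tuning in visual cortex, transient kinetics,
template-projection spike detection against ground-truth electrophysiology,
depth-attenuation fits, and high-throughput culture-screen statistics. This
package implements that analysis set as a tested library for people who build
or benchmark indicators and for anyone who wants a self-validating reference
implementation of these widely used procedures.

## The model and the statistics

**Forward model.** Spikes are grouped into bursts (inter-spike gaps ≤ 250 ms).
A burst of *n* action potentials contributes a difference-of-exponentials
kernel anchored at its last spike,

    k(t) = (1 − e^(−t/τ_r)) · e^(−t/τ_d),

scaled so its peak equals the indicator's saturating burst-amplitude curve
A(n) = A_max(1 − (1 − A₁/A_max)ⁿ); bursts superpose additively. (τ_r, τ_d) are
solved numerically so that the kernel's half-rise and half-decay equal the
indicator's published half-times. The measured ROI signal is
F_meas = F₀(1 + ΔF/F₀) + noise + r·F_neuropil, with a slow shared neuropil
fluctuation (1 s correlation length).

**Analyses.**
- Neuropil correction `F_cell(t) = F_meas(t) − r·F_np(t)` with r = 0.7,
  applied only to cells whose baseline exceeds the neuropil baseline by > 3%;
  ΔF/F₀ = (F − F₀)/F₀ with F₀ the mean over 1 s before stimulus onset.
- Responsive cells: trial-averaged stimulus ΔF/F₀ > 0.05 for some direction
  AND one-way ANOVA across blank + 8 directions, p < 0.01. Tuning curves are
  fitted with B + A₁G(θ; θ_pref, σ) + A₂G(θ; θ_pref + Δ, σ) (wrapped
  Gaussians, Δ = 180° by default) and OSI = (R_pref − R_ortho)/(R_pref + R_ortho).
- Kinetics: half-rise/half-decay by linear interpolation between frames,
  single-exponential fits, and stimulus tracking as the Fourier amplitude at
  the drive frequency normalized to 0 Hz.
- Detection: n-AP events (n spikes inside an indicator-specific bin, isolated
  by > 1 s) and no-AP noise bins are projected on mean-subtracted unit-norm
  templates; d′ = (μ_s − μ_n)/√((σ_s² + σ_n²)/2), empirical ROC curves, and
  detection accuracy at a fixed false-positive rate.
- Depth attenuation: per-dendrite log-linear fits of F(z) = F₀e^(−z/λ);
  group medians compared by Wilcoxon rank-sum.
- Culture screen: per-cell peak ΔF/F₀, SNR (peak over pre-stimulus sd) and
  half decay per AP-train; variant-vs-parent rank-sum tests and lexicographic
  ranking with a guard against losing the 160-AP maximal response.

## Worked example

```python
from gecibench import ImagingConfig, generate_tuned_population, kinetics_preset
from gecibench.pipeline import tuning_results

kin = kinetics_preset("jRGECO1a", "v1")     # half_decay_s = 0.39
cfg = ImagingConfig(fs=15.0, noise_sd=0.02, neuropil_amp=0.05, r_true=0.7, seed=1)
pop = generate_tuned_population(20, 0.7, kin, cfg)   # 8 directions x 5 trials
res = tuning_results(pop)                   # correct -> classify -> fit
print(res.responsive.sum(), res[res.responsive].OSI.median())
```

Running the numbered drivers reproduces the full story
(`python analysis/02_correct_and_tune.py` and friends print):

```
responsive: 14/20 flagged (truth 14), agreement 100%
median |theta_pref error| over responsive cells: 3.3 deg
median OSI of responsive cells: 0.80
```

i.e. the classifier recovers exactly the 14 cells built to be responsive, the
preferred direction is recovered to ~3° (well inside the 45° stimulus
spacing), and the population is strongly orientation tuned. The other drivers
report, for example, a fitted depth length constant of 129.1 μm (median of 19
simulated red-GECI dendrites, truth 130 μm) vs 74.8 μm (14 green dendrites,
truth 75 μm; rank-sum p = 1.4e-06), and single-AP detection with d′ = 3.3 and
92% accuracy at a 5% false-positive rate under 10% imaging noise.

## Layout

- `src/gecibench/` — the library: `synth` (forward model), `traceproc`,
  `tuning`, `kinetics`, `detection`, `depth`, `screen`, `presets`,
  `benchmarks`, `io`, `cli`.
- `analysis/` — numbered narrative drivers writing tables under `results/`.
- `tests/` — unit, property and acceptance tests.
- `docs/methods.md` — model assumptions, parameter choices, limitations.

A `geci-bench` command (simulate / correct / tune / kinetics / detect /
depth / screen) wraps the library for shell use; see `geci-bench --help`.
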