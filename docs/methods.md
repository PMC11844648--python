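# Methods note

This note records the models, parameter conventions, generator fidelity,
and numerical choices behind `imeqc`, plus the limitations a user should
keep in mind when interpreting outputs.

## 1. Electrophysiology processing chain

**Referencing.** `common_median_reference` subtracts the per-sample
median across channels. The median (not mean) is used so that a single
large-amplitude channel cannot drag the reference.

**Filtering.** 4th-order Butterworth band-pass, 300–3000 Hz by default,
applied zero-phase with `scipy.signal.sosfiltfilt` (second-order
sections for numerical stability at 24.414 kHz). Zero-phase filtering
preserves spike peak timing but effectively doubles the filter order,
which attenuates sharp biphasic peaks by a few percent — recovered unit
Vpp runs systematically ~3–10 % below the planted template Vpp. This is
a property of the filter, not an estimation error, and the acceptance
tolerance (10 %) is set around it.

**Detection.** Per-channel threshold at −4σ̂ with
σ̂ = median(|x|)/0.6745, the standard robust Gaussian scale estimate
(unbiased by spikes, unlike sample SD). Crossings are resolved to the
local minimum and a 1 ms lockout suppresses re-triggering; snippets span
0.5 ms before to 1.0 ms after the trough.

**Artifact rules.** Two screens run on detected events before sorting:

- *Amplitude*: any event whose snippet exceeds ±500 μV anywhere is
  removed (physiological spikes do not reach that amplitude at these
  gains).
- *Coincidence*: events across channels are grouped by single-linkage
  chaining with a 0.5 ms link; a group spanning **more than 14 distinct
  channels** (of 16) is removed as a motion artifact. Both the 14-channel
  count and the 0.5 ms link are `DetectionConfig` fields.

**Impedance QC.** Channels are usable when 1 kHz impedance lies in
[100 kΩ, 1 MΩ]; out-of-range channels are excluded before analysis.

## 2. Sorting and verification

Per channel, event snippets are reduced to 2 principal components and
clustered with seeded k-means over k = 2…5; k is chosen by silhouette
score (subsampled to ≤ 2000 events, seeded subsample) with a floor of
0.5 — below the floor the channel is treated as a single cluster.
Clusters become *verified* units when they satisfy all of:

- ≥ 30 spikes (stable mean waveform),
- ≤ 5 % of ISIs below 1 ms (refractory violations),
- mean-waveform trough at least 5σ̂ deep, when the per-channel σ̂ is
  supplied (`SortConfig.verify_min_trough_sigma`, default 5.0).

The trough rule exists because a −4σ̂ threshold inevitably harvests a
coherent cluster of threshold-riding noise crossings on every channel;
their mean waveform troughs sit just past 4σ̂, while real units planted
well above threshold sort far deeper. Without it, noise clusters pass
the count and ISI rules and poison event-level precision.

## 3. Unit metrics and outlier screening

- Vpp = max − min of the mean waveform (μV).
- Channel noise RMS: RMS of the filtered trace after excising a
  snippet-sized window around every kept event. On synthetic data this
  matches an identically processed noise-only recording to < 3 %.
- SNR = Vpp / channel noise RMS.
- Spike rate = 1 / median(ISI). For a Poisson train of rate λ the
  median ISI is ln 2 / λ, so this estimator reads ≈ 1.44 λ for
  unstructured trains; it is used because it is robust to silent
  periods. Generator ground truth is compared with the *same statistic*
  (never with λ) in tests.
- Putative units require Vpp ≥ 40 μV.
- ROUT outlier screening (Q = 5 %): median-centered residuals scaled by
  the robust standard deviation of the residuals
  (RSDR = 68.27th percentile of |residuals| × n/(n−1)), two-sided t
  p-values with df = n−1, Benjamini–Hochberg step-up at q·j/n. This is
  the constant-model specialization of the regression-outlier method.
- Channel × phase aggregation averages unit metrics per channel over
  weeks 1–4 (`W1_4`) and 5–8 (`W5_8`).

## 4. Active electrode yield (AEY)

A channel is active in a week if it carries ≥ 1 unit that is putative,
verified, and not an SNR outlier. Channels never active across the
whole study are dropped from every denominator (*ever-active*
exclusion). Weekly AEY = active / ever-active per group; phase
proportions pool weekly numerators and denominators over weeks 1–4 and
5–8 respectively, so a group with 107 ever-active channels present for
4 weeks contributes a denominator of 428. Group comparisons use the
pooled two-proportion z-test (normal approximation); the implementation
warns when either proportion is degenerate (0 or 1).

## 5. Histology quantification

Distance from the explant hole is computed with an exact Euclidean
distance transform of the hole mask, converted to μm via the supplied
scale, and binned into 50 μm annuli out to 650 μm; the 600–650 μm
annulus is the background reference. Intensity normalization:

    N_k = I_k / I_bg − (1 − f)

with f = 1 for markers expressed in healthy tissue (GFAP, NeuN), so
background normalizes to 1, and f = 0 for markers absent in healthy
tissue (CD68, IgG), so background normalizes to 0. Neuron density is
centroid count per unmasked annulus area (counts/mm²), normalized to the
background annulus. All binning geometry lives in `RadialBinning` and is
overridable; tests verify the analysis is covariant under changes of
pixel scale when the binning is scaled consistently.

## 6. Release chemistry

- Encapsulation efficiency: EE% = (total − free) / total × 100.
- Calibration: ordinary least squares line of analyte/internal-standard
  peak-area ratio vs concentration; inversion rejects a zero slope.
- Sample-and-replace dialysis mass balance: when an aliquot of volume
  V_al is removed and replaced with fresh buffer at each time point,
  the drug released by time t_i is

      M_cum(t_i) = C_i · V_reservoir + Σ_{j<i} C_j · V_aliquot,

  i.e. what is in the reservoir now plus everything carried away by
  earlier aliquots. The naive estimate C_i·V_res ignores the second term
  and increasingly underestimates late-time release. Non-monotone
  corrected curves are flagged (measurement noise), and cumulative
  release above the loaded mass raises an error.
- The default release model is biexponential,
  F(t) = a(1 − e^{−k₁t}) + (1 − a)(1 − e^{−k₂t}) with a = 0.63,
  k₁ = 0.15 h⁻¹, k₂ = ln(18.5)/576 h⁻¹, giving a burst phase reaching
  ~65.5 % at 24 h and ~98 % at 24 d.

## 7. Synthetic generators (fidelity notes)

- **Spike templates** are band-limited biphasic shapes (difference of
  Gaussians-like, scaled to a requested Vpp) so they survive the
  300–3000 Hz filter roughly intact.
- **Spike trains** are Poisson with an enforced refractory period; the
  ground truth stores exact sample-resolved times.
- **Noise** is Gaussian, rescaled so that the requested SD is the
  *in-band* (post-filter) RMS; otherwise the band-pass would silently
  shrink the effective noise floor and all SNRs would be optimistic.
- **Motion artifacts** are oscillatory wave packets: 6 ms Hann-windowed
  1300 Hz carrier with trough depth `amplitude_uv`, applied to
  `n_channels_hit` channels with a 0.25 ms per-channel onset stagger.
  Two properties are deliberate. The stagger places channels at
  different carrier phases, so the common-median reference cannot cancel
  the transient (a perfectly common-mode artifact is removed exactly by
  CMR and would never reach the coincidence rule). The multi-cycle
  carrier gives each channel several troughs, so the 0.5 ms
  single-linkage chain across channels is redundant — the 1 ms detection
  lockout on any one channel cannot fragment the group below the
  >14-channel criterion.
- **Amplitude outliers** are single 800 μV transients on one channel,
  above the ±500 μV rule but far from saturating float32.
- **Histology images** draw per-pixel intensities from a radial profile
  plus noise, and neuron centroids from an inhomogeneous Poisson point
  process with the requested density profile.
- **Release series** sample the biexponential model with exact
  sample-and-replace bookkeeping (optional multiplicative measurement
  noise), so the mass-balance correction inverts the simulation to
  machine precision when noise is zero.

## 8. Determinism and numerics

- One global seed per run; every stage derives a child seed as the
  first 4 bytes of SHA-256 over `"{seed}:{stage}"`, masked below 2³¹.
  No OS entropy is used anywhere; pipeline re-runs are byte-identical
  (verified file-by-file in tests).
- Voltages are stored float32 (raw-format economy); all reductions
  (RMS, means, OLS) are performed in float64.
- `sosfiltfilt` is used over `filtfilt`-with-ba for stability; PCA and
  k-means are seeded; silhouette subsampling is seeded.
- Config provenance: result directories carry a `provenance.json` with
  the SHA-256 of the canonical YAML config and the seed.

## 9. Limitations

- 1/median-ISI overstates Poisson rates by ~1.44×; comparisons must use
  the same statistic on both sides (the package's tests do).
- CMR reduces uncorrelated noise by a small channel-count-dependent
  factor; noise RMS comparisons are therefore made against identically
  processed references, not against the generator SD.
- ROUT on small batches (n ≲ 10 units) can flag the strongest genuine
  units as SNR outliers — the method assumes the batch is dominated by
  a homogeneous population. Screen at the channel × phase population
  level, not on a handful of units.
- The verification trough rule (5σ̂) assumes the noise estimate comes
  from the same filtered trace the events were detected on.
- The synthetic generators are designed to exercise the analysis rules,
  not to reproduce cortical biophysics; absolute in vivo group outcomes
  (yields, histology effect sizes) are not claims this package can
  reproduce, only the computations applied to such data.
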