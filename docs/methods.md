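# Methods

This note documents the models implemented in `sleepomics`, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical choices made where the design was genuinely
open. No empirical claim here goes beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Sleep staging and architecture

Vigilance states are defined by EEG spectral content and EMG tone: WAKE has
high muscle tone with fast low-amplitude EEG; NREM has atonia with slow
high-amplitude (delta, 1–4 Hz) EEG; REM has atonia with fast low-amplitude
(theta, 4–8 Hz) EEG. Real studies score these manually; an unattended
pipeline needs an automated stand-in, so `ThresholdSleepScorer` implements
the same criteria as a transparent two-rule tree:

```
EMG RMS > emg_rms_hi                  -> WAKE
elif delta/(delta+theta) > delta_ratio_hi -> NREM
else                                  -> REM
```

Externally scored hypnograms can always be ingested verbatim instead
(`io.read_hypnogram`). Defaults and rationale:

* **Epoching** — 5 s epochs for stand-alone sleep recordings, 1 s when
  synchronized with photometry; trailing partial epochs are dropped, not
  padded. Per-epoch band power is the mean Welch PSD over the half-open
  band `[f_lo, f_hi)`; half-open intervals avoid double-counting the shared
  4 Hz edge between delta and theta.
* **EMG threshold** — scale-dependent, so auto-calibrated as the geometric
  midpoint of the (10th, 90th) percentile range of epoch EMG RMS. This is
  robust for the strongly bimodal tone distribution but assumes both wake
  and sleep are present in the recording.
* **Delta-ratio threshold** — the delta fraction delta/(delta+theta) is
  already normalized to (0, 1) with NREM near 1 and REM near 0, so the
  default is the fixed midpoint 0.5. Quantile auto-calibration is available
  (`delta_ratio_hi=None`) but is only sensible when both NREM and REM occur.
* **Bouts** — maximal same-state runs; runs shorter than `min_bout_s` are
  merged into the longer neighbour (ties to the preceding one), shortest
  offender first, re-coalescing as needed.
* **Architecture** — time-in-state percentages are exact rationals on epoch
  counts (they sum to 100 exactly); latency is measured from the recording
  start, since no other reference is defined for unattended data.
* **State spectra** — Welch with 4 s Hann windows and 50% overlap by
  default (1 Hz bins resolve the 1–4 Hz delta band), averaged over
  qualifying bouts with bout-duration weights.
* **SWA** — per time bin (default 1 h), mean NREM delta power expressed as
  a percentage of a caller-supplied baseline delta power
  (`nrem_delta_power` computes one). Bins without NREM yield NaN, never 0.
  Because band power is quadratic in amplitude, a 1.5× delta amplitude
  yields 225% SWA — the scaling the acceptance suite checks.

## Photometry and infraslow NE oscillations

`scaled405 = a·F405 + b` is fit by ordinary least squares (`np.polyfit`),
and `ΔF/F(%) = (F465 − scaled405)·100/scaled405`. A baseline crossing zero
is a hard error reported with the first offending sample, since the ratio
is meaningless there. A `self_median` mode divides by the median of the
signal channel itself.

Open parameters and the defaults chosen:

* **Welch segments for the infraslow PSD**: 120 s Hann, 50% overlap,
  minimum qualifying bout 120 s. This resolves 0.0083 Hz bins around the
  ~0.02 Hz phenomenon (several cycles per segment) while still admitting
  typical NREM bouts. All configurable.
* **Detrending**: polynomial order 2 per bout (configurable 0–5); order 2
  removes bleaching curvature left after isosbestic correction without
  touching the oscillation band.
* **"Power" vs "amplitude"**: both are emitted — `psd_amplitude` is the
  maximum of the averaged PSD, `infraslow_power` the trapezoid integral
  over a configurable band (default 0.005–0.1 Hz), and `psd_peak_freq_hz`
  the argmax restricted to that band. The discrete-peak rate is an
  independent frequency estimate and is also reported.
* **Peak detection**: peaks are sought within NREM bout spans only, with
  hard bout edges (no cross-boundary interval enforcement). Amplitude is
  measured as prominence on the detrended trace, matching the detrended
  analysis context. Candidates below 0.5 %ΔF/F prominence are discarded;
  among candidates closer than 10 s the taller survives (ties to the
  earlier), which the test suite verifies against an exhaustive
  subset-enumeration oracle. Because the rule set itself declares events
  closer than 10 s meaningless, the detrended trace is zero-phase low-pass
  filtered at 1/(10 s) = 0.1 Hz first; without this, sample-rate noise on
  a kHz-class trace registers as spurious peaks. The cutoff is
  configurable and can be disabled (`lowpass_hz=None`).
* **Bout averaging**: PSDs are averaged with bout-duration weights; an
  unweighted mean is available via `duration_weighted=False`.

## LFQ proteomics

* **Sample QC** drops samples detecting fewer proteins than 50% of the
  median detected count (when the median is ~90 this is the familiar
  45-proteins-per-sample rule).
* **Completeness filter** keeps proteins observed in at least a fraction
  (70% or 90% depending on stringency) of the samples of *at least one*
  group of the comparison; the fraction is converted to a whole-sample
  count by ceiling before the ≥ comparison.
* **Mixed imputation** splits proteins at a fraction-valid cutoff of 0.6:
  above it, missingness is treated as MCAR and imputed by averaging the
  k = 3 most Pearson-correlated proteins (over shared observed samples)
  that carry a value in the missing sample; below it, missingness is
  treated as below-detection MNAR and imputed per sample from a Gaussian
  with mean = sample mean − 1.8·SD and width 0.3·SD. Observed cells are
  never altered, and draws are deterministic given the seed. KNN cells
  with no eligible donor fall back to the Gaussian branch.
* **Differential testing** uses the pooled-variance (Student) t with an
  s0 = 0.5 offset in the denominator; s0 moderation presumes a pooled SE,
  but a Welch option exists (`equal_var=False`). 0/0 is defined as 0 so a
  protein identical in both groups is exactly null. Permutations are
  distinct group-label splits sampled without replacement (all splits
  enumerated when fewer exist than requested, with a warning). q-values
  use the pooled-permutation estimator, made monotone by a suffix minimum
  and clipped to [0, 1]; a per-protein permutation-p + Benjamini–Hochberg
  alternative is available (`fdr_method="bh"`). Under a pure null the mean
  false-discovery proportion equals the family-wise discovery rate; the
  acceptance suite verifies it is at the nominal 0.05 within Monte-Carlo
  error. Exact q-value invariance under group-label exchange holds for
  balanced designs (the sampled index subsets coincide and |t| is
  complement-symmetric); for unbalanced subsampled designs it is
  approximate.
* **CVs** are computed on linear-scale intensities (2^log2), since a
  coefficient of variation is only meaningful on a ratio scale; Pearson
  sample correlations use pairwise-complete observations; PCA runs on the
  centered complete (or imputed) matrix with samples as observations.
* **Enrichment** intersects each gene set with the background, tests the
  2×2 table with a two-sided Fisher exact test, and corrects across tested
  sets by Benjamini–Hochberg. Sets with no background overlap are skipped
  and reported; an infinite odds ratio is returned as `inf`. Note a large
  set completely disjoint from the hits is significantly *depleted* under
  a two-sided test — that is correct behaviour, not a defect.

## Histology

Particle analysis labels 8-connected components (4-connectivity available)
and bins areas as: < 5 μm² excluded, [5, 30) μm² ramifications,
[30, 90] μm² cells, and > 90 μm² counted separately as oversize (real
pipelines leave the upper tail unspecified; reporting it preserves the
partition `total = cells + ramifications + excluded + oversize`).

The AQP4 background at "5 μm" is read as the mean of the linearly
interpolated intensities exactly 5 μm to each side of the profile peak
(one-sided when the profile ends sooner); vessels too short for any
background are skipped with a warning. Per-image indices are vessel means;
cohort normalization divides by the maximum so exactly one image scores 1.
Subtracting a point background makes the index invariant to constant
intensity offsets, which the tests assert.

## Synthetic generators: what they emulate and what they do not

All generators are pure functions of their spec (seed included): identical
seeds give bit-identical outputs.

* **Hypnograms** are first-order Markov chains over WAKE/NREM/REM with a
  dwell-heavy default transition matrix giving realistic mouse bout lengths
  at 5 s epochs. Real sleep has longer-range structure (ultradian cycling,
  circadian modulation) that a first-order chain does not capture.
* **EEG/EMG** are per-state weighted mixtures of unit-variance band-limited
  noises (delta 1–4 Hz, theta 4–8 Hz, broadband) and white EMG noise with a
  20:1 wake/sleep RMS ratio. This reproduces the *features the scorer
  uses*, not spindles, K-complexes or artifacts — so the ≥95% scoring
  accuracy on synthetic data demonstrates that the rule tree recovers the
  generating labels, not that it matches human scoring of real EEG.
* **Photometry**: the isosbestic channel is exponential bleach (τ = 2000 s)
  plus low-pass motion plus white noise; the signal channel is the affine
  image of the same bleach+motion (gain 2.0, offset 0.1) times
  `1 + ne/100`, where `ne` is a 0.02 Hz sinusoid (2 %ΔF/F) during NREM, a
  3 %ΔF/F plateau in WAKE, 0 in REM. Motion enters both channels *before*
  the gain so isosbestic correction can remove it exactly — the design
  rationale for the 405 nm channel. Real NE dynamics are not sinusoidal
  and sensor kinetics are not modelled; amplitude/noise defaults are chosen
  for testability since no SNR figures exist for the sensor traces.
* **LFQ matrices**: protein baselines ~ N(25, 2) log2 units, replicate
  noise N(0, 0.5), a ±effect shift (default 2 log2 units, random sign) on
  a regulated fraction (default 10%) of proteins in the second group, and
  logistic intensity-dependent dropout (midpoint 22, slope 1) — the MNAR
  mechanism the downshifted imputation assumes. Real data add correlated
  proteins, batch effects and non-Gaussian tails.
* **Images**: compact pixel blocks of exactly the requested areas placed on
  a jittered grid with a 2-pixel margin (components never touch, even
  diagonally); vessel profiles are Gaussian bumps (σ = 1.2 μm) on flat
  background, with the analytic corrected peak returned as truth.

## Problem sizes and determinism

The acceptance suite and `scripts/acceptance.py` run photometry sessions at
25 Hz with a single 3000 s NREM bout flanked by wake (the infraslow band is
fully resolved several hundred times below Nyquist, and one long bout makes
the injected peak-count/rate identity exact to ±1 cycle), 2000-epoch
recordings at 200 Hz for scoring, 100 null repetitions of the 1000-protein
6 vs 6 design for FDR calibration, 10⁴ Gaussian-branch draws for imputation
moments, and 500 random 48×48 images for the flood-fill oracle. These sizes
were chosen so the full verification runs in minutes on one CPU while every
statistical check retains comfortable Monte-Carlo margins.

All stochastic stages take explicit seeds; pipeline outputs carry
`# key=value` provenance headers (package version, seed, config hash), and
same-seed reruns are byte-identical up to the config hash, which the
determinism audit checks.

## Known limitations

* The threshold scorer is a stand-in for manual staging; on real EEG it
  would need artifact rejection and possibly per-animal calibration, both
  out of scope.
* The isosbestic regression absorbs any NE component that is correlated
  with the bleaching trend (e.g. a plateau occupying one contiguous half of
  a short recording); this is a property of the method itself, visible in
  the tests.
* The pooled-permutation FDR is an estimator, not a guarantee; its null
  calibration is verified empirically at the default design only.
* EDF ingest (via `mne`) is optional and read-only; the canonical exchange
  formats are the TSVs documented in `sleepomics.io`.
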