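# Methods

`abrgap` reimplements, on synthetic data, an analysis of auditory
brainstem responses (ABRs) to paired noise bursts: a leading burst (NB1),
a silent gap, and a trailing burst (NB2).  The scientific claim under
test is categorical: the brainstem's response to the trailing burst is
not a smooth function of the stimulus timing but falls into two classes
governed by the ratio of gap duration to NB1 duration,

```
R = gap / NB1,    suppressed if R <= 0.5,    balanced/enhanced if R > 0.5.
```

The pipeline synthesizes averaged ABRs for the 4x4 grid of NB1 durations
{5, 10, 30, 100} ms x gap durations {2, 3, 5, 10} ms (NB2 fixed at
50 ms), then asks whether blind time-frequency analysis plus clustering
recovers that boundary.

## Synthetic ABR generator

Each burst onset evokes a stereotyped response modelled as a sum of
Gabor atoms `a * exp(-(t - t0)^2 / 2w^2) * cos(2*pi*f*(t - t0))`.  The
default template has four components:

| latency (ms) | amplitude (uV) | frequency (Hz) | envelope SD (ms) | role |
|---|---|---|---|---|
| 3.5 | 1.10 | 775 | 1.40 | dominant carrier (superimposed main waves, peak = wave III) |
| 1.6 | 0.35 | 820 | 0.45 | sharp early wave (wave I/II) |
| 3.8 | 0.35 | 520 | 1.10 | low-band slow component |
| 3.25 | 0.40 | 1020 | 0.90 | high-band synchrony component |

The carrier period (1/775 Hz = 1.3 ms) lies in the 1.1-1.5 ms range
typical of ABR waves, and the template's spectral power is dominated by
the 650-900 Hz middle band.  Atoms are truncated to +-5 envelope widths
(exactly zero outside), so well-separated onset responses cannot bleed
into each other, and both responses are evaluated on integer-sample
offsets from their onsets, so an unmodulated generator produces
bit-identical NB1 and NB2 epochs.

The modulation rule is deliberately mechanism-free — it reproduces the
band-power phenomenology the analysis is supposed to detect, nothing
more.  For the NB2 response only:

* `R <= 0.5` (suppressed): components with centre frequency in
  650-900 Hz are scaled by `mfb_suppression = 0.6`;
* `R > 0.5` (balanced/enhanced): components in 400-650 and 900-1150 Hz
  are scaled by `lfb_hfb_gain = 1.4`.

No quantitative effect size is available for either regime, so these
defaults were chosen once to give clearly detectable but not caricatured
effects: NB2/NB1 RMS ratios of ~0.64 (suppressed) and ~1.03-1.08
(enhanced), comparable with a strong forward-masking effect.  The
boundary is a sharp step by default; `boundary_width > 0` replaces it by
a logistic blend for threshold-recovery experiments.  Coherent spectral
overlap between atoms matters at these bandwidths (a 250 Hz analysis
band is narrower than a 0.5 ms atom's spectral spread), so the default
amplitudes/envelopes were checked against a plain FFT band-power oracle
to confirm that the enhanced regime actually raises low- and high-band
power of the trailing epoch.

Averaging of the 600 sweeps is emulated by adding Gaussian noise of SD
`noise_sd_uv / sqrt(n_sweeps)` (default 5 uV / sqrt(600) ~ 0.2 uV)
directly to the averaged trace; single sweeps and polarity alternation
are not simulated because only the average is analyzed.  Subject
variability is a per-subject log-normal amplitude factor (SD 10%) and a
Gaussian latency shift (SD 0.1 ms) shared across that subject's
recordings — enough within-group scatter to make the clustering
non-trivial without destroying group separation.  All randomness flows
from `numpy.random.SeedSequence`, so datasets are bit-reproducible.

What the generator does *not* emulate: real single-sweep artifacts,
adaptation across the burst (only onset responses are modelled), any
cochlear or neural mechanism, acoustic calibration, and any genuine
uncertainty about where the category boundary lies.  Passing tests
therefore show that the analysis machinery recovers the structure the
generator encodes — they say nothing about guinea-pig physiology.

## Preprocessing and time-domain parameters

Recordings are band-pass filtered 300-3000 Hz with a 4th-order
Butterworth filter applied forward and backward (`sosfiltfilt`; zero net
phase).  The two analysis epochs are the half-open 8 ms windows
[onset, onset + 8 ms) after each burst onset.  Time-domain parameters
use the 1-7 ms sub-window (closed at both ends; at 100 kHz the choice of
boundary convention moves the RMS by < 0.1%): the NB2/NB1 RMS ratio, and
the wave-III peak-to-trough ratio, where wave III is the largest
positive peak in a configurable 2.5-4.5 ms window and its amplitude is
measured to the following local minimum.

## Time-frequency analysis

The Wigner-Ville distribution (WVD) of the epoch's analytic signal
(frequency-domain Hilbert transform) is computed from the instantaneous
autocorrelation `K[n, m] = z[n+m] z*[n-m]` with a 2048-point FFT over
the lag axis.  Because the lag variable is sampled at twice the sample
period, frequency bin k maps to `k * fs / (2 * 2048)` (~24.4 Hz at
100 kHz), spanning 0 to Nyquist; time resolution stays at the sample
grid.  The normalization satisfies the energy property: total TFR power
times dt*df equals the analytic signal's energy (tested to 1%).

Cross-terms — the oscillatory artifacts any quadratic TFR places midway
between signal components — are attenuated with the Choi-Williams
kernel `exp(-(theta*tau)^2 / sigma)` applied in the ambiguity (doppler
theta x lag tau) domain.  `sigma` defaults to 1, a common literature
choice; as sigma grows the output converges monotonically to the raw
WVD (tested over sigma = 0.1 ... 1e6).

Differential TFRs are `TFR(ABR1) - TFR(ABR2)` elementwise, so positive
values mean more power in the leading response.  They are reduced to
mean powers over half-open rectangles of 0.5 ms x one frequency band,
with the three contiguous 250 Hz bands LFB 400-650, MFB 650-900 and
HFB 900-1150 Hz partitioning 400-1150 Hz.  An 8 ms epoch gives 16 bins.
Classifier features are per-band means over the 3-5 ms window (bins
6-9), where the main power change concentrates; clustering uses the
(LFB, HFB) pair.  A "relative power" variant (differential band power
divided by the ABR1 epoch's same-band power in the same window) is
carried in the feature table for scatter plots; the exact normalization
behind that quantity was an open choice and this definition is the
package's own.

Only the 350-1200 Hz slice of each TFR is retained by the pipeline
(covering all three bands with margin); full matrices for 256 epochs
would cost gigabytes and contribute nothing to the analysis.

Per-subject differential TFRs are averaged across subjects for
grand-mean maps (averaging TFRs, not transforming averaged waveforms —
the alternative was undocumented and this choice keeps per-subject TFRs
available for statistics).

## Grouping, classification, clustering

* Ratio and labels: `R = gap/NB1` exactly; display helper rounds to two
  decimals (2/30 prints as 0.07).  The boundary condition `R = 0.5` is
  suppressed (boundary inclusive).
* SVM: linear kernel on standardized 3-band features (the observed
  separation is essentially linear; RBF available via config), with
  stratified, seeded 10-fold cross-validation.  Reported: resubstitution
  and cross-validated accuracy and precision (precision for the
  balanced/enhanced class), plus ROC/AUC from the cross-validated
  decision scores.  If the minority class is smaller than the fold
  count, folds are reduced with a warning.
* k-means: Lloyd's algorithm under cosine distance (MATLAB-style:
  normalized points, centroids are normalized member means), 20 seeded
  restarts, best inertia kept.  Cosine distance makes the partition
  invariant to per-point positive scaling, which is what cancels the
  per-subject amplitude factor.  Written in-package because no installed
  library implements cosine-distance k-means with this update rule.
* Cluster count: mean cosine silhouette over k = 2..10, ties to the
  smallest k; a best silhouette below 0.25 flags likely absence of
  structure.  (Note that cosine silhouettes of low-dimensional
  direction-spread data are generically inflated; the warning threshold
  is calibrated for the degenerate isotropic case.)
* Cluster-to-group mapping: the larger cluster is the suppressed group
  (12 of 16 grid conditions are suppressed); an exact size tie goes to
  the cluster with the lower mean summed feature value.  Confusion
  counts treat balanced/enhanced as the positive class; sensitivity
  TP/(TP+FN), specificity TN/(TN+FP), informedness SE+SP-1.  (A source
  formula printing specificity as TP/(TN+FP) is internally inconsistent
  with its own reported values and is treated as a typo.)
* Boundary estimate: the largest grid ratio whose points' majority falls
  in the suppressed cluster.  Per-0.5-ms-bin clustering repeats the
  k-means scoring with bin-specific (LF, HF) features, yielding the
  informedness-vs-latency trace.

## Statistics

* TFRs: paired sign-flip permutation test on the per-cell paired
  t-statistic, corrected by the max-statistic (t-max) distribution, so
  family-wise error over all time-frequency cells is <= alpha (0.05).
  With n subjects <= log2(n_permutations) the 2^n sign patterns are
  enumerated exactly (2^8 = 256 for the default 8 subjects); otherwise
  1000 random patterns (seeded, observed labelling included).  The sum
  of squared differences is sign-invariant, which reduces each
  permutation to a flipped mean — the whole null distribution is two
  matrix products.
* Waveforms: per-sample two-sided Wilcoxon rank-sum, Benjamini-Hochberg
  FDR across samples, alpha 0.01.  The pipeline pools epochs per group
  (96 suppressed / 32 balanced-enhanced pairs) rather than testing per
  condition: with 8 epochs per side the rank-sum normal approximation
  bottoms out at p ~ 8e-4, which cannot survive FDR at 0.01 over 800
  samples — per-condition masks would be empty by arithmetic, not by
  evidence.  The operation itself accepts any two epoch groups.
* Time-domain parameters: two-way ANOVA (type II) on NB1 duration x gap
  duration with interaction, Tukey HSD post-hoc per factor, alpha 0.05.
  Effects whose sum of squares is numerically zero report F = 0, p = 1
  rather than 0/0 artifacts.

## Pipeline, sizes, determinism

`run_pipeline` chains simulate -> preprocess -> TFR -> grouping ->
stats.  A single master seed spawns per-stage seeds via
`SeedSequence`; identical configurations give byte-identical metrics
JSON.  Outputs are written only after all stages succeed; stage
failures raise a stage-tagged `PipelineError`.

The default run is the full study geometry — 8 subjects x 16 conditions
= 128 recordings at 100 kHz — and completes in about a minute on one
core; the TFR stage dominates.  Tests that only exercise plumbing use
2-4 subjects.  Null-calibration tests (permutation family-wise error,
FDR, ANOVA type-I error) run 100-500 replicates on small synthetic
matrices, sized to keep binomial confidence intervals meaningful.

## Known limitations

* The generator's effect sizes are stipulated, not fitted to any
  recorded data; headline classification metrics on synthetic data
  (typically at or near 100%) exceed what heterogeneous real recordings
  give and should not be quoted as reproducing measured values.
* The sharp modulation step plus a grid that contains the boundary
  ratio makes boundary recovery exact by construction when clustering is
  perfect; the interesting failure modes appear at higher noise or with
  `boundary_width > 0`.
* The WVD frequency axis above fs/4 is aliased (lag decimation); ABR
  content lives below 3 kHz, three orders of magnitude below that edge.
* Wave-III detection assumes a positive dominant peak inside its search
  window; polarity-inverted recordings need the window/convention
  adjusted.
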