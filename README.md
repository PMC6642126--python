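# abrgap

Analysis pipeline for auditory brainstem responses (ABRs) to paired
noise bursts, built around a tested synthetic-data generator.

## The problem

When two noise bursts are separated by a silent gap, the brainstem's
onset response to the trailing burst (ABR₂) is not a smooth function of
the timing parameters.  Responses group into two categories governed by
a single ratio of stimulus durations,

```
R = gap / NB1
```

with a sharp boundary at R = 0.5: for R ≤ 0.5 the trailing response is
*suppressed* — it loses power in the dominant ABR frequency band
(650–900 Hz, the ~1.1–1.5 ms period of the main waves) — while for
R > 0.5 it is *balanced/enhanced*, with slightly raised power in the
flanking low (400–650 Hz) and high (900–1150 Hz) bands.  This package
implements the full analysis chain that detects that categorical
structure, for anyone who wants to study or extend the method: auditory
electrophysiologists, and anyone using quadratic time-frequency
representations of short evoked potentials.

Because the original recordings are not publicly deposited, the package
ships a documented generator that synthesizes averaged ABRs with exactly
this modulation structure for the 4×4 stimulus grid (NB1 ∈ {5, 10, 30,
100} ms × gap ∈ {2, 3, 5, 10} ms, NB2 = 50 ms, 8 subjects).  The
analysis itself never sees the generator's rule — it has to recover the
boundary blindly.

## The method

1. **Preprocess** — zero-phase 300–3000 Hz band-pass; two 8 ms
   post-onset epochs per recording; time-domain parameters (NB2/NB1 RMS
   ratio over 1–7 ms, wave-III peak-to-trough ratio).
2. **Time-frequency** — Wigner–Ville distribution (2048-point, analytic
   signal) with Choi–Williams cross-term suppression; differential TFR
   (leading − trailing); mean band powers on a 0.5 ms × 250 Hz-band
   grid; per-point features = band means over 3–5 ms.
3. **Grouping** — linear SVM (10-fold stratified CV, ROC/AUC) on the
   3-band features; cosine-distance k-means with silhouette selection of
   the cluster count (2–10); larger cluster ↦ suppressed group;
   confusion matrix with sensitivity SE = TP/(TP+FN), specificity
   SP = TN/(TN+FP) and informedness I = SE + SP − 1; per-0.5-ms-bin
   informedness trace; boundary estimate = largest grid ratio in the
   suppressed cluster.
4. **Statistics** — paired t-max permutation test on per-subject TFRs
   (family-wise α = 0.05, exact sign-flip enumeration for 8 subjects);
   per-sample Wilcoxon rank-sum on pooled waveforms with
   Benjamini–Hochberg FDR (α = 0.01); two-way ANOVA (NB1 × gap) with
   Tukey post-hoc on the time-domain parameters.

See `docs/methods.md` for the model, parameter defaults and numerical
choices.

## Worked example

The numbered scripts under `analysis/` run the study end to end
(`scratch/` holds the recording container, `results/` the tables):

```
$ python analysis/01_simulate.py
wrote 128 recordings to scratch/recordings.h5
  96 in suppressed conditions, 32 in balanced/enhanced conditions

$ python analysis/02_time_domain.py
                   rms_ratio  peak3_ratio
group
balanced/enhanced      1.078        0.974
suppressed             0.682        0.600
```

The suppressed conditions lose ~30% of trailing-response RMS and ~40% of
wave-III amplitude; balanced/enhanced conditions sit at or slightly
above parity.

```
$ python analysis/03_tfr_band_power.py
                        lfb       mfb       hfb
group
balanced_enhanced -0.000152 -0.000049 -0.000057
suppressed         0.000452  0.001370  0.000363

$ python analysis/04_grouping.py
SVM: accuracy 100.0% (100.0% cross-validated), precision 100.0% (100.0% CV), AUC 1.000
silhouette selects k = 2 (scores: 2: 0.980, 3: 0.953, ...)
k-means vs ratio rule: TP=32 FN=0 TN=96 FP=0 -> SE=1.000 SP=1.000 I=1.000
largest grid ratio in the suppressed cluster: 0.5
```

Differential band powers (TFR₁ − TFR₂, 3–5 ms window) are positive and
MFB-dominated for suppressed conditions, negative for the
balanced/enhanced group — opposite feature directions, which is why the
scale-invariant cosine clustering separates them cleanly.  Silhouette
analysis confirms two clusters, and the unsupervised partition places
every condition with R ≤ 0.5 — and none above — in the suppressed
cluster, recovering the 0.5 boundary.  (On synthetic data with the
default effect sizes the classifiers saturate; real recordings are
messier.)

```
$ python analysis/05_statistics.py
nb1_100ms_gap_2ms            TFR sig 67.1%
...
suppressed         pooled waveform samples significant: 62.4%
balanced_enhanced  pooled waveform samples significant:  4.9%
ANOVA rms_ratio: p(nb1)=4.69e-97 p(gap)=4.12e-70 p(interaction)=3.82e-83
```

Equivalently, `abrgap.run_pipeline(PipelineConfig(seed=1))` runs all
stages in one call and returns the tables and metrics as one bundle.

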