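# Methods

`lbnpdet` re-implements, as a tested pipeline over synthetic data, a
detection analysis for early central hypovolemia in the stepped
lower-body-negative-pressure (LBNP) model: multi-modal metric extraction,
absolute and relative diagnostic evaluation with bootstrap ROC, and a
rolling-slope random-forest classification stage with majority-vote fusion.
This note documents the model, the choices made where the design was open,
and what the synthetic experiments do and do not show.

## The LBNP protocol and its blood-loss reading

LBNP is applied in 5-minute steps — 0 (baseline), 15, 30, 45, 60 mmHg, then
10 mmHg increments to at most 100 mmHg — until a subject reaches tolerance
(hypotension or symptoms), somewhere in 60–100 mmHg.  The pump transition
takes ~48 s at the start of each step, leaving a 4.2-min stable period over
which metrics are averaged.  The diagnostic analyses keep only the
clinically occult range 0–60 mmHg.  Published calibration equates levels
15/30/45/60 mmHg with cumulative central volume losses of 93/193/313/451 ml,
so consecutive changes correspond to increments of 93/100/120/138 ml; the
`BloodLossMap` utility performs exactly this lookup (no interpolation —
asking for an uncalibrated level is an error).

## Metrics

* **HR** — beat-to-beat rate from R-peak times, `60 / RR`, timestamped at
  interval midpoints.  R-peak extraction from raw ECG is out of scope; peaks
  are an input.
* **Pleth_A** — per-beat trough-to-trough area under the plethysmography
  waveform.  Troughs are local minima of a 0.25 s-smoothed waveform below a
  2 s rolling median, with a 0.3 s refractory period; the straight line
  between bounding trough values is subtracted before trapezoidal
  integration, making the metric invariant to DC drift.  All three
  constants are exposed as parameters.
* **EIT_thx / EIT_ab** — per-frame mean ± SD of valid channel magnitudes of
  a 16-electrode belt (208 adjacent-drive/adjacent-measure channels).
  Validity: contact-flagged channels are dropped wholesale; per frame, a
  channel beyond 5 median-absolute-deviations from the cross-channel median
  is dropped (`outlier`), as are values above a saturation limit (10 kΩ).
  Every exclusion carries a reason code.  Frames with no valid channels
  become missing; a level whose stable window is more than half missing is
  skipped with a warning, never silently zeroed.  The exact channel subset
  and thresholds used by any given acquisition are configuration, not
  constants of the method.
* **EIS_thx / EIS_ab / EIS_arm** — impedance magnitude per frequency on the
  canonical grid of 100 log-spaced frequencies, 100 Hz–1 MHz, ~1 spectrum
  per minute.  No frequency is selected at extraction time; the diagnostic
  stage screens all 100 and reports the max-AUC frequency, explicitly
  flagged as optimistically biased (see below).
* **HRV** — 20 features per minute window: 8 time-domain (mean RR, SDNN,
  RMSSD, pNN50, pNN20, mean HR, SD of HR, CV of RR), 7 frequency-domain
  from a Welch periodogram of the 4 Hz-interpolated RR series (VLF/LF/HF
  power, total power, LF/HF, normalized LF/HF), 5 nonlinear (Poincaré
  SD1/SD2/ratio, sample entropy with m=2 and r=0.2·SD, DFA α1 over box
  sizes 4–16).  Windows with fewer than 2 RR intervals are missing, not
  zero.  Sample entropy of a constant series is defined as 0; when no
  template matches exist it is NaN.  The 20-feature inventory is a
  conventional default and overridable — different studies enumerate
  different sets.

Stable-period averaging applies the transition skip (default 48 s)
uniformly to every level, including baseline, so every level is averaged
over a window of equal length.

## Absolute vs relative evaluation

The **absolute** analysis compares raw per-level values against baseline
values across subjects (ROC; paired Wilcoxon signed-rank for the matched
level-vs-baseline and level-vs-previous contrasts).  Absolute impedance
discriminates poorly by construction: between-subject anatomy (electrode
spacing, tissue composition) dominates the within-subject effect, which is
exactly what the synthetic generator's per-subject impedance scale
reproduces.

The **relative** analysis is the interesting one: the change of a metric
across a consecutive level pair is classified against the same metric's
change over the baseline period ("baseline variability").  Baseline
variability is defined as the mean over the second half of the 5-min
baseline minus the mean over the first half — duration-matched to a level
change and computable from the same averaging machinery.  Impedance changes
are expressed in percent of the lower level (removing the subject scale);
vital-sign changes stay in native units.  Both representations are options.

Statistical machinery:

* **Wilcoxon** — rank-sum between groups; signed-rank within subjects.
  Exact null distribution when min(n) ≤ 12 without ties, else the normal
  approximation with tie/continuity correction.  Two identical samples are
  a degenerate case reported as p = 1 with a flag.  No multiple-testing
  correction is applied; p-values are reported raw and flagged as such.
* **ROC/AUC** — trapezoidal area over the full threshold sweep; ties get
  half credit, so the AUC equals the Mann–Whitney U statistic divided by
  n₁n₀ (asserted against an all-pairs counting oracle in the tests).
  Scores are oriented a priori by the known physiological sign of each
  effect (impedance ↑ and HR ↑ under hypovolemia; MAP ↓, pleth area ↓).
  Auto-flipping orientation per dataset would inflate AUC and is not done.
* **Bootstrap CI** — 500 stratified resamples (within class, so every
  replicate keeps both classes), percentile interval with the small-sample
  quantile expansion (t-quantile widening).  The plain percentile interval
  undercovers at study-scale group sizes — measured 92.1% coverage of a
  true AUC of 0.8 at n = 16+16 — while the expanded interval restores
  ~94.5%; `expand=False` recovers the plain interval.
* **Specificity at 100% sensitivity** — the fraction of negatives strictly
  below the smallest positive score; the operating point of an alarm that
  may not miss.
* **EIS frequency selection** — the max-AUC frequency per site and level
  pair, ties broken toward the lowest frequency.  Because the selection
  maximizes over ~100 (correlated) candidates it is optimistically biased;
  the report carries a `selection_biased` flag and the test suite
  quantifies the bias under a zero-effect generator instead of pretending
  it away.

## Slope-based classification

Minute-level feature matrices per technology (1 column for MAP, HR,
Pleth_A and each EIT belt; 20 for HRV; 10 log-spaced frequencies for each
EIS site — a stand-in inventory, overridable) are reduced to
ordinary-least-squares slopes over rolling windows with 1-minute stride.
Windows fully inside the baseline step are class 0; to enlarge the scarce
normovolemic set, class-0 slopes are pooled across 2-, 3- and 4-point
windows, giving (m−1)+(m−2)+(m−3) samples per subject for m usable baseline
minutes (9 at the 5-minute baseline).  Hypovolemic windows are attributed
to a consecutive change (L1, L2) when they lie fully inside
[start(L1), end(L2)] and reach into the L2 step; for the 0-to-15 change
this necessarily includes part of the baseline, which is unavoidable — a
7-point window cannot fit inside a single 5-minute step — and is precisely
what lets the window witness the transition.  With 7-point windows each
subject contributes 4 windows per change.

A consequence of the length-mismatched augmentation is worth stating
plainly: class-0 slopes (2–4 points) have higher sampling variance than
class-1 slopes (7 points), so a classifier can exploit slope magnitude as a
window-length signature independent of any physiological effect.  This is
inherent to the design (the same augmentation is used at both ends) and is
most visible for HRV, whose 20 noisy features give the forest many chances
to use it; HRV consequently posts stronger AUCs than its univariate signal
would justify.  The zero-effect control (all mean AUCs near 0.5 when no
effects are injected) bounds how far this artifact can reach, because the
variance signature alone, being present in both train and test classes,
does not create class separation — it only amplifies weak real trends.

Cross-validation is subject-wise: 15 folds, each holding out 3 randomly
drawn subjects (13 train at study scale).  Fifteen disjoint triples cannot
partition 16 subjects, so folds are independent random draws with distinct
test sets (possible whenever C(n,3) ≥ 15); subjects recur across folds but
never cross the train/test line within a fold, which is asserted on every
fit.  The forest is 500 trees, Gini splits, unlimited depth, fixed seed.
AUC uses out-of-sample vote fractions; F1 (hypovolemia positive) thresholds
votes at 0.5.  Fold-wise 95% CIs use the normal approximation across the 15
fold scores.

Fusion is a per-sample majority vote over each technology's binary
prediction; ties — possible for the 4-member vitals fusion — resolve to
hypovolemia, since in an alarm context a false positive is cheaper than a
miss.  The fused vote fraction serves as the score for the fused AUC.
Fusions evaluated: Fused_Vitals (MAP, HR, HRV, Pleth_A), Fused_EIT,EIS (the
five impedance technologies), Fused_All (all nine).

## The synthetic generator

The generator is phenomenological: no biophysical forward model, no ECG or
EIT image morphology — just the statistical structure the analyses consume.
Per subject: R-peak times from an instantaneous-rate model (base HR ~
N(65, 5) bpm, level offsets, slow Ornstein–Uhlenbeck wander, 3% beat
jitter); 1 Hz MAP (base ~ N(90, 8) mmHg); a raised-cosine pleth pulse train
locked to the R-peaks with level-dependent amplitude attenuation; 1 Hz EIT
frames (208 channels, lognormal channel gains, common-mode effect and
drift, cardiac ~1.1 Hz and respiratory 0.25 Hz oscillations, 1% channel
noise); one Cole-model EIS spectrum per minute per site; and the LBNP
channel with linear ramps over the 48 s transitions.

The injected effects are the study conditions:

* Thoracic impedance rises per step by a shifted-lognormal percent drawn
  per subject: `floor_k + (median_k − floor_k)·exp(σz)`, with medians
  1.09/0.89/0.83/0.79% and floors 0.36/0.24/0.31/0.29% for the four occult
  changes (later steps reuse the last value), σ = 0.4.  The cohort median
  equals the configured median and the support respects the floor.  σ is a
  stand-in — the heterogeneity shape is not identifiable from cohort
  summaries; values much above ~0.5 skew the distribution enough that the
  *measured* cohort median (effect plus symmetric measurement noise) drifts
  above the configured one.
* The abdominal belt sees 0.6 of the thoracic effect; EIS sites see
  0.8/0.7/0.25 (thorax/abdomen/arm) of an independent draw, shaped over
  frequency by a log-Gaussian band weight peaking near 14.7 kHz (half
  weight at 8 and 27 kHz, floor 0.15), so max-AUC frequency selection lands
  in the mid-frequency band.
* HR offsets: +0.5/+1.5/+5/+12 bpm at 15/30/45/60 mmHg — detectable
  against baseline only from 45 mmHg at n=16.  Pleth amplitude: −3/−12/−22/
  −35% — detectable from 30 mmHg.  MAP: −0.5/−1/−2/−4 mmHg — near-stable
  (relative AUC ~0.5–0.6 in the occult range).
* Slow physiological wander is OU with a 5-minute time constant per
  channel; the impedance drift SDs (0.4% EIT, 0.45% EIS of the absolute
  level) set the baseline-variability scale and were calibrated so the
  study-scale relative EIT_thx performance sits at AUC ≈ 0.98–1.0 with
  specificity at full sensitivity mostly 0.85–1.0, rather than degenerate
  perfect separation.
* A per-subject lognormal scale (σ = 0.2) multiplies all absolute
  impedances (body habitus), which is what ruins the absolute impedance
  analysis, as intended.
* Tolerances are uniform on {60, 70, 80, 90, 100} mmHg (mean 80).

What the generator does **not** emulate: waveform morphology and its
artifacts (motion, electrode pops), heavy-tailed or 1/f physiological
drift (OU is short-memory, so baseline variability is slightly tamer at
short lags than real data), inter-channel EIT correlation structure beyond
a single common mode, EIS phase effects, and any dependence of effects on
age/sex/BMI.  Passing tests therefore show that the *pipeline* recovers
the structure it assumes, at the study's effect sizes and sample sizes —
not that the real instruments achieve these numbers.

Determinism: one integer seed drives everything through
`numpy.random.SeedSequence` spawning; identical (config, seed) give
bit-identical recordings, and the end-to-end CLI writes byte-identical
JSON summaries on repeated runs.

## Numerical and degenerate-input conventions

Empty stable windows and overly-missing levels warn and produce no entry.
A flat pleth waveform (no troughs), a single R-peak, single-class labels,
or an empty frequency map raise typed errors.  Identical Wilcoxon samples
return p = 1 with a degenerate flag.  ROC ties take half credit.  Slope
windows tolerate missing minutes per feature column as long as two finite
points remain; windows that cannot be attributed to baseline or to a single
consecutive change are dropped.  All seeds are plumbed explicitly.

## Problem sizes used by the test suite and acceptance script

Chosen to make the checks statistically meaningful at interactive cost:
bootstrap coverage uses 500 replicate datasets at n = 16+16; the Wilcoxon
null uses 1000 replicates; the null-cohort control uses 4 zero-effect
16-subject cohorts (the family straddle-rate bound of 85% reflects that
~128 nominal-95% intervals cannot all cover); median recovery uses 64
subjects in the tests and 256 (generated in chunks) in the acceptance
script; the
classification orderings use five replicate 16-subject cohorts with
100-tree forests (forest defaults remain 500 trees; the replicate design
trades trees for replicates, which is the right variance trade-off for an
ordering claim).  The acceptance script reports a mean over 8 study-scale
cohorts for the relative EIT_thx AUC.

## Known limitations

* The zenodo read dialect maps a documented per-subject CSV layout; the
  real deposit's internal schema has not been inspected from this
  environment, so that adapter is a stand-in confined to one module.
* Fused F1 magnitudes on real recordings depend on inter-subject and
  inter-technology correlation structure that the generator does not claim
  to match; on synthetic cohorts the pipeline reproduces orderings
  (impedance > vitals at the first change; Fused_All ≥ sub-fusions), not
  any particular F1 value.
* Baseline variability uses the full 5-minute baseline halves; other
  duration-matched definitions (e.g. disjoint 2.5-min windows after the
  skip) are reasonable and exposed as the natural place to extend.
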