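# lbnpdet — early hypovolemia detection in a stepped LBNP model

Occult hemorrhage can progress silently: blood pressure, heart rate and
plethysmography often stay unremarkable until a patient abruptly
decompensates.  Lower body negative pressure (LBNP) is the standard safe
human model of this progression — suction below the iliac crest sequesters
blood in the legs, mimicking central volume loss, applied in 5-minute steps
(0, 15, 30, 45, 60, … mmHg; level 15–60 mmHg correspond to cumulative
losses of 93–451 ml).  `lbnpdet` is an analysis pipeline for asking, from
multi-modal physiological recordings of such a protocol, *how early can
non-invasive impedance measurements flag the loss, and how do they compare
with vital signs?*

It is aimed at biomedical-signal researchers working with LBNP or
hemorrhage-model data.  Because such recordings are bulky and access-
restricted, the package ships a calibrated synthetic-cohort generator that
emulates the statistical structure of a 16-subject study — small, consistent
per-step thoracic impedance increases (cohort medians ≈ 1.09/0.89/0.83/0.79 %
with floors at 0.36/0.24/0.31/0.29 %), HR responding only at high suction,
pleth pulse area declining from mid suction, MAP near-stable, strong
between-subject variation in absolute impedance — so every stage is testable
end to end without any download.

## What it computes

**Metrics** (per subject, per level, averaged over each step's 4.2-min
stable period): MAP; beat-to-beat HR from R-peaks; Pleth_A (trough-to-trough
pulse area); mean belt impedance from two 16-electrode EIT belts (thorax,
abdomen); EIS impedance magnitude |Z(f)| on 100 log-spaced frequencies
(100 Hz–1 MHz) at thorax, abdomen, arm; plus 20 minute-level HRV features.

**Absolute analysis** — raw level values vs baseline values across
subjects: Wilcoxon tests and ROC/AUC with stratified-bootstrap CIs
(500 resamples, expanded-percentile interval).

**Relative analysis** — the change across consecutive levels
(Δ = x(L₂) − x(L₁), in percent for impedance) classified against the
metric's own baseline variability (second-half minus first-half baseline
mean).  AUC equals the Mann–Whitney statistic U/(n₁n₀); the specificity at
100 % sensitivity is the fraction of negatives below the smallest positive
score.  EIS metrics are screened per frequency and the max-AUC frequency
reported, flagged as selection-biased.

**Slope classification** — per technology, ordinary-least-squares slopes
over 7-point rolling minute windows feed a random forest (500 trees, Gini,
unlimited depth) under subject-wise 15-fold cross-validation (13 train /
3 test); the normovolemic class is augmented by pooling 2-, 3- and 4-point
baseline windows ((m−1)+(m−2)+(m−3) samples per subject).  Per-technology
votes fuse by majority (Fused_Vitals, Fused_EIT,EIS, Fused_All; ties →
alarm).  Performance is out-of-sample mean AUC and F1 with fold-wise CIs.

## Worked example

The numbered drivers under `analysis/` run the full study on a synthetic
16-subject cohort (intermediate data in `scratch/`, tables in `results/`):

```sh
python analysis/01_simulate_cohort.py      # 16 subjects, seed 7
python analysis/02_extract_metrics.py
python analysis/03_level_analysis.py
python analysis/04_slope_ml.py             # ~6 min: 500-tree forests
```

`03_level_analysis.py` prints, for this cohort:

```
first level significantly different from baseline (p < 0.05):
HR         45
MAP        60
PlethA     30

== relative analysis (AUC of change vs baseline variability) ==
to_level    15    30    45    60
EIS_ab    0.98  0.98  0.97  0.90
EIS_thx   0.97  0.91  0.93  0.93
EIT_thx   1.00  0.93  0.98  0.98
HR        0.62  0.74  0.97  1.00
MAP       0.48  0.38  0.54  0.66
PlethA    0.56  0.93  0.99  1.00

EIT_thx at the 0-to-15 mmHg change: AUC 1.00 (CI 0.98-1.00),
specificity at 100% sensitivity 93.8%
selected EIS frequencies span 9.5-24.2 kHz (max-AUC selection; biased)
```

Read: as an *absolute* metric nothing flags the first step (vital signs
react only from 30–45 mmHg, ≈ 200–300 ml of equivalent loss), but the
*relative* thoracic-EIT metric separates a 93 ml-equivalent shift from
baseline variability almost perfectly — detection without any calibrated
healthy reference.  `04_slope_ml.py` then shows the out-of-sample
classification ordering: impedance technologies beat vital signs at the
0-to-15 change (mean F1 0.65 vs 0.53 here), and fusing all nine
technologies is at least as good as either sub-fusion (mean F1 across
changes 0.79 / 0.79 / 0.72 for Fused_All / Fused_EIT,EIS / Fused_Vitals).

The same stages are scriptable via the `lbnpdet` CLI
(`simulate`, `extract`, `analyze`, `ml`, `report`), each writing a
provenance block (config hash, seed, versions) next to its outputs.

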