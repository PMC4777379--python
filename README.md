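# physioaffect

Subject-specific affect classification from peripheral physiology.

`physioaffect` is a tested, reusable implementation of a picture-block
affect-induction analysis for affective-computing research: from raw
multimodal recordings — facial EMG over the corrugator supercilii and
zygomaticus major, skin conductance level (SCL), and blood-volume pulse
(BVP) — it extracts 20 canonical psychophysiological features, screens
subject variables (age, gender-role and personality scale scores) for
their influence on those features, and quantifies how gender- and
age-specific subgroup classification changes affect-recognition accuracy.
A synthetic-data module generates full cohorts with the statistical
structure the analysis assumes, so every stage is testable without any
recordings.

It is aimed at affective-computing and psychophysiology researchers who
want a reproducible reference pipeline, and at methodologists studying
how subject-specific variables (age, gender) propagate into biosignal
classifiers.

## The analysis

**Induction design.** Five core affects — neutral and the four quadrants of
the valence–arousal plane (HVHA, HVLA, LVHA, LVLA; H/L = high/low,
V/A = valence/arousal) — are each induced by two blocks of pictures shown
back to back (2 s per picture), every block preceded by a 20 s fixation
cross.

**Features** (per subject × condition; the two blocks of a condition are
averaged):

- *HRV*, from the NN-interval series detected on the BVP: mean_RR, std_RR,
  mean_HR, std_HR and RMSSD = √( 1/(n−1) · Σⱼ (NNⱼ₊₁ − NNⱼ)² ).
- *fEMG*: the 20–250 Hz band-passed, 50 Hz-notched, 125 ms RMS envelope of
  each site, baseline-corrected against the 2 s before block onset and
  z-scored within subject and site (mean_amp_Corr, mean_amp_Zyg).
- *SCL*, on the 0.2 Hz low-passed signal X of each block: mean, SD, mean
  absolute first/second differences of the raw and the within-segment
  z-scored signal, counts and mean amplitudes of maxima/minima with
  amplitude > 0.05 μS, trapezoidal integral, and least-squares slope.

**Feature reduction.** Pairs of features with |Pearson r| ≥ 0.95 carry
redundant information; the higher-indexed member of the most-correlated
pair is dropped iteratively (`CorrelationThresholdReducer`).

**Screening.** Every feature × condition is correlated across subjects
with age and six trait scores (BSRI masculinity/femininity, NEO-FFI
extraversion/neuroticism, BIS, BAS); significance at the
Bonferroni-corrected level 0.05/7 ≈ 0.007.

**Classification.** Within each gender × age subgroup, an RBF-kernel SVM is
evaluated under leave-one-subject-out (LOSO) cross-validation for three
task families (3-class valence, 5-class affect, neutral-vs-condition
binaries). Each outer fold fits scaling on the training subjects only and
runs wrapper feature selection — sequential forward selection and backward
elimination, scored by inner subject-wise cross-validation — and the
higher-accuracy method is reported. Selected features are aggregated into
a selection-frequency ranking and per-signal-group shares.

## Worked example

```python
import physioaffect as pa

design = pa.scaled_design(n_subjects=16, seed=314)   # short blocks, fast
profiles, timeline, recordings = pa.simulate_cohort(design)
matrix = pa.build_feature_matrix(recordings, timeline)

reducer = pa.CorrelationThresholdReducer(threshold=0.95).fit(matrix)
reduced = reducer.transform(matrix)
print(len(reducer.retained_), "features retained of", len(pa.FEATURE_NAMES))

table = pa.screen_variables(matrix, profiles)
print("corrected alpha:", round(table.attrs["corrected_alpha"], 3))

sg = pa.Subgroup("all", tuple(reduced["subject_id"].unique()))
res = pa.classify_task(reduced, sg, pa.affect5_task(), inner_cv=3)
print(f"affect5 LOSO accuracy: {res.accuracy:.1f}% via {res.method}")
```

prints

```
12 features retained of 20
corrected alpha: 0.007
affect5 LOSO accuracy: 63.8% via forward
```

12 of the 20 features survive the redundancy threshold on this small
cohort (short synthetic blocks collapse more SCL variants than a full
session would); the screening level reproduces the 0.05/7 Bonferroni
correction; and the five-class LOSO accuracy of 63.8% is well above the
20% chance level, driven by the injected condition effects in the
generator. A command-line front end (`physioaffect simulate / extract /
reduce / screen / classify / run-all`) wraps the same functions.

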