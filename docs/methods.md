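# Methods

This note documents the models, conventions and numerical choices behind
`physioaffect`, in the order the pipeline runs them.

## Synthetic cohorts

The generator emulates a picture-block affect-induction session: five core
affects (neutral, HVHA, HVLA, LVHA, LVLA), two 20 s blocks per affect of
ten 2 s pictures each, every block preceded by a 20 s fixation cross —
400 s per session, block order a seeded permutation. The default cohort is
100 subjects, 64% female, ages uniform on 20–75 years. Trait scale scores
are truncated normals within instrument ranges (NEO-FFI subscales 0–48,
BIS 7–28, BAS 13–52, BSRI subscale means 1–7, the own-gender BSRI role
score shifted upward by 0.8 points).

Sampling rates default to 1000 Hz (EMG), 32 Hz (SCL) and 128 Hz (BVP),
typical for multichannel biosignal amplifiers of the class this paradigm
uses; all are configurable per channel.

### Signal models

**SCL** = tonic level + phasic responses + drift + noise. The tonic level
is `8 μS + slope·(age − 47.5) + N(0, 1.55²)` with slope −0.05 μS/yr: for
uniform ages on [20, 75] (SD 15.88 yr) this injects a population
age–tonic correlation of −0.05·15.88 / √((0.05·15.88)² + 1.55²) ≈ −0.46.
Each picture onset triggers one skin-conductance response (SCR), a
difference of exponentials (rise 0.75 s, decay 2 s, unit peak) scaled by a
per-condition amplitude (0.15 μS neutral up to 0.35 μS for high-arousal
conditions). Spontaneous non-specific SCRs occur at 2/min with 0.15 μS
amplitude, a slow sinusoidal drift (0.1 μS, 120 s period) and white noise
(0.02 μS) complete the channel; samples are clipped to stay positive.

**BVP** is a train of raised-cosine pulses whose inter-beat intervals are
drawn per beat as a condition mean heart period (850 ms neutral, down to
820 ms for high-arousal conditions) plus per-beat Gaussian jitter
(~20–45 ms; larger under low arousal, emulating vagal variability) plus a
slow per-interval drift of the mean period (SD 15 ms).

**EMG** (each site) is zero-mean Gaussian noise whose standard deviation
follows a per-condition envelope target — corrugator supercilii reactive
to negative valence (up to 0.018 mV vs 0.008 mV neutral), zygomaticus
major to positive valence — plus a 50 Hz power-line sinusoid (0.01 mV).
The resting tone (0.005 mV) is re-drawn per interval with log-SD 0.4.

### Heterogeneity and the gender × condition effect

Phasic reactivity (SCR amplitudes, EMG envelope excursions) is multiplied
by a per-subject factor (log-SD 0.5) and a per-block factor (log-SD 0.8).
These dispersions are deliberate: psychophysiological reactivity varies
strongly across people and trials, and without them every classification
saturates at 100% and subgroup contrasts are unmeasurable. The injected
gender effect makes females hyper-reactive to LVHA (gain 1.8) and
hypo-reactive to HVHA (0.4), and symmetrically for males. The calibration
was chosen so that (i) binary neutral-vs-condition LOSO accuracy sits in
the 70–95% band rather than at ceiling, and (ii) pooled-cohort training
is measurably worse than gender-homogeneous training on the
gender-signature conditions — the phenomenon the subgroup analysis is
designed to detect.

What the generator does **not** emulate: realistic cardiac waveform
morphology, respiration and its coupling into HRV and EDA, motion
artifacts, electrode drift, non-stationary habituation across the
session, or item-level questionnaire responses. Passing tests therefore
demonstrate that the pipeline recovers effects of the injected kind at
realistic noise levels — not that it is robust to every artifact class of
real recordings.

All randomness flows from one integer seed through `SeedSequence`
spawning (per-subject substreams keyed by subject index), so cohorts are
byte-reproducible and generating a channel subset leaves the other
channels' streams untouched.

## Preprocessing

All IIR filters run forward–backward (zero phase) so filtered signals
stay aligned with the event timeline. EMG: 4th-order Butterworth 20–250 Hz
band-pass, then a second-order IIR notch at 50 Hz (Q = 30) — a notch was
chosen over an LMS adaptive canceller because the contract (line-frequency
suppression ≥ 20 dB, < 3 dB at ±10 Hz) is identical and far easier to
verify — then a 125 ms centred sliding RMS envelope with truncated windows
at the edges (no padding). SCL: 4th-order Butterworth 0.2 Hz low-pass
(the family/order is the package's choice; only the cutoff is prescribed
by the paradigm), unit DC gain.

Beat detection finds pulse peaks on a 0.5–8 Hz band-passed copy of the
BVP with a 300 ms minimum inter-peak distance and both prominence and
height gates at 0.5 SD of the filtered signal (the height gate rejects
near-zero "ringing" maxima that the narrowband filter produces where a
beat is missing). An automatic artifact rule replaces interactive visual
correction of the NN series: intervals outside [300, 2000] ms or deviating
more than 25% from the running median of five are discarded; after
rejection the NN series stores each retained interval with its
terminating beat, so intervals need not equal `diff(beat_times)` across a
gap.

Segmentation attaches to each stimulation block the 2 s of samples
preceding its onset as the baseline window. EMG features are
baseline-subtracted per block and z-scored within subject and site across
all blocks. SCL and HRV features are computed on the block content
directly; an optional fixation-baseline correction for level-type SCL
features exists but is off by default so the printed formulas are exact
(2 s is too short a window for beat statistics, and the shape/count
features have no meaningful baseline analogue).

## Features, reduction, screening

The 20 features and their formulas are listed in the README. Choices the
formulas leave open: the "normalized" signal X̃ for the
first/second-difference variants is the within-segment z-score (the
standard convention in the feature-set literature this analysis follows);
an extremum's amplitude is the difference to the preceding opposite
extremum (the first extremum is measured from the segment's first
sample); minima amplitudes are reported as positive drop magnitudes, and
the minima count keeps drops exceeding the same 0.05 μS threshold as the
maxima (reading the printed "> −0.05 μS" literally would count nearly
every fluctuation). Block pairs of a condition are pooled by arithmetic
mean into one row per (subject, condition).

Reduction removes, while any feature pair correlates at |r| ≥ 0.95 over
all rows, the higher-canonical-index member of the most-correlated pair
(ties by canonical order), which is deterministic given the matrix.
Constant columns have undefined correlations; they are retained with a
warning rather than silently dropped. Screening correlates every
feature × condition with age and the six trait scores (gender, being
categorical, enters through subgrouping instead); p-values are two-sided
via the t-transform with n−2 df, and significance uses the
Bonferroni-corrected level `family_alpha / n_variables` (0.05/7 ≈ 0.007).

## Classification

Subjects split at 45 years (between the young and elderly group means of
this design) into nine gender × age subgroups. Evaluation is
leave-one-subject-out: feature scaling is fit on training subjects only;
wrapper selection (sequential forward selection and backward elimination)
is re-run inside every outer fold, scored by inner subject-wise
cross-validation, so no information from the held-out subject reaches
selection or scaling. Forward adds a feature only on strict improvement
of inner accuracy; backward removes a feature when removal is not worse —
the asymmetry makes ties collapse (duplicated features reduce to one)
while jointly-required feature pairs survive. Both methods run and the
higher LOSO accuracy is reported, matching the analysis convention of
keeping the better selection pass.

The classifier is an RBF-kernel SVM with inverse-frequency class weights
(the 3-class valence task maps 1:2:2 condition rows per subject). C = 1
and gamma = "scale" by default; a grid search over C/gamma inside the
training folds is implemented (`param_grid`) but off by default — nested
grid search multiplies the LOSO × wrapper cost roughly ninefold and no
parameter values are prescribed, so the fixed defaults keep runs
tractable and deterministic. The wrapper's inner loop standardises each
inner split once and refits only the SVM per candidate subset, with
precomputed class weights; this is a pure performance refactor of the
same computation.

Selection sets are aggregated per run by majority across folds (a feature
counts as selected when chosen in more than half the folds), then counted
across subgroup × task runs into the ranking table; per-signal-group
shares divide each group's count by the number of available features in
the group (after reduction) and normalise to sum 1 per subgroup.

## Problem sizes

Statistical conditions that define the analysis are kept at full size:
100 subjects (and 100 seeded replicates) for the age-effect recovery
check, 60 subjects and 20 replicates for the subgroup-direction check.
For cohort-level resampling studies the package uses `scaled_design()` —
the same block structure and effect parameters with 3 pictures per block,
5 s fixation and reduced sampling rates (512/32/64 Hz) — and inner
3-fold subject-wise CV inside the wrapper; these sizes are the package's
choice for simulation studies, while generator defaults remain the full
session. Classification checks that only need the SCL channel generate
only that channel.

## Known limitations

- The backward-elimination path is O(p²) SVM fits per fold and dominates
  runtime for large feature sets.
- The artifact rule is tuned for missing/spurious pulses, not for
  sustained noise; a long corrupted stretch yields a short NN series
  rather than an explicit quality flag.
- The per-fold wrapper selection is the leakage-free reading of a single
  reported selection per classification; analyses that selected features
  once on all data would report optimistically higher accuracies, and the
  two are not numerically comparable.
- `SCL_sd_raw`/`SCL_sd_norm` use the span difference |X_{n+2} − X_n| as
  printed, which on smooth signals is nearly twice the first difference;
  they are therefore usually removed by reduction, as intended.
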