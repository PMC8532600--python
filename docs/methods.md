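# Methods

This note documents the models, conventions and design choices behind
`flanksense`, in the spirit of a statistical-software methods appendix.

## Problem and data model

A triaxial accelerometer on the left paralumbar fossa of a dairy cow logs
acceleration in units of g at 5 Hz (one sample every 0.2 s). With the
animal standing, the sensor's x axis is vertical, y is horizontal
fore–aft, and z points orthogonally out of the left flank. The static
component of the signal is the gravity vector, whose direction in the
sensor frame changes with posture; the dynamic component carries the
behavior (jaw cycles, steps, quiescence). Observers annotate the recording
with intervals of posture (S, RSR, LSR) and behavior (feeding, moving,
resting, ruminating, standing still); samples they cannot assign
univocally — including everything not covered by any interval — are
labeled `ambiguous` and removed before windowing. Annotation intervals are
half-open `[start, end)`, so a boundary sample belongs to the later
interval and no sample is labeled twice.

Acceleration units are taken as g throughout. The logger's export format
does not pin them down, but only g makes the static magnitude ≈ 1 and the
posture conventions self-consistent; nothing downstream depends on the
absolute scale except the simulator's defaults.

## Windowing

The observation unit is a window of 40 consecutive samples (8 s), advanced
by a stride of 13 samples, i.e. consecutive windows share 27 of 40
samples. A candidate window is retained only if all 40 samples carry one
identical, non-ambiguous label for the task at hand; the posture and
behavior streams are filtered independently, so the two tasks have
different row counts. For a stream of N samples the exact candidate count
is `⌊(N − 40)/13⌋ + 1`; the conventional shorthand `⌊N/13⌋`
(`windows.nominal_row_count`) overstates it by at most 3 windows and is
reported alongside the exact count because it is the figure usually quoted
for datasets of this design. Window length and stride are parameters with
defaults (40, 13) so the 8 s design can be re-examined.

## Features

Nine statistics per channel (x, y, z, amag), 36 features per window, named
`{channel}.{stat}`:

| stat | definition | conventions fixed here |
| --- | --- | --- |
| avg | mean | — |
| sd | standard deviation | n−1 denominator |
| zc | zero crossings | signal mean-centered first; exact zeros adopt the previous non-zero sign, so a touch of zero is not a crossing |
| p2p | max − min | — |
| rms | √(mean of squares) | — |
| kur | excess kurtosis m₄/m₂² − 3 | population moments (n); 0 on constant windows |
| skw | skewness m₃/m₂^1.5 | population moments (n); 0 on constant windows |
| cf | max&#124;w&#124; / rms | maximum *absolute* value; 0 on all-zero windows |
| Vrms | rms of the running sum | raw (uncentered) signal, zero initial condition, no Δt factor; units g·sample |

Rationale for the zc centering: without removing the ~1 g gravity offset
the x, z and amag channels would almost never cross zero and the feature
would be uninformative; z-scoring instead of centering would give the same
counts (the count is scale-invariant), so centering suffices. Degenerate
(constant or all-zero) windows return the conventions above instead of
NaN, keeping the feature table rectangular; occurrences are logged.

Useful identities, enforced by tests: `rms² = avg² + m₂` per window; skw
and kur are invariant under positive affine maps; zc and cf are invariant
under positive scaling.

## Feature pruning

Pairwise absolute Pearson correlations are computed on the full feature
table; while any retained pair has |r| ≥ the cutoff (default 0.8), the
member of the currently worst pair with the larger mean absolute
correlation against the remaining features is removed (ties break on
column order); constant columns are removed up front. This is the standard
greedy correlation filter. The exact removal list depends on the data, so
on synthetic sessions it will not equal any particular published list; the
guaranteed post-state — no retained pair with |r| ≥ cutoff — is asserted on
every run.

## Split, normalization, classifiers

Rows are split 75/25 by a seeded uniform permutation — *not* stratified
and not grouped by animal, matching the simple random split of the study
design. Because consecutive windows overlap, a random split leaks
temporally adjacent windows across partitions; accuracies from it measure
within-session interpolation, not animal-to-animal generalization. Both
partitions are z-scored with the training partition's
mean and (n−1) SD; a feature constant on the training rows is an error.

Four backends, with package-default hyperparameters (the study specifies
none): random forest (500 trees, √p features per split), k-nearest
neighbors (k = 5, Euclidean), XGBoost (200 rounds, depth 6, η = 0.3,
softmax objective for ≥ 3 classes), SVM (RBF, C = 1, γ = 1/p). All are
overridable per run; RF/XGB/SVM are seeded and reproducible.

## Assessment

Confusion matrices are predicted-in-rows × actual-in-columns. Overall:
accuracy T/N; Cohen's kappa with marginal chance agreement
p_e = Σ row·col/N² (undefined, returned NaN, when p_e = 1); an exact
Clopper–Pearson 95% CI for the accuracy; the no-information rate
NIR = largest actual-class share; and a one-sided exact binomial
P(X ≥ T | N, NIR) as the accuracy p-value — the null being "the classifier
does no better than always predicting the most prevalent class".
Per class, one-vs-rest sensitivity, specificity, precision, NPV,
prevalence and balanced accuracy; ratios with zero denominators are NaN.

**Reference-table comparison.** The packaged published panels are compared
at their printed precision ("1.00" = two decimals). A computed value
matches a printed one if printing it at that precision under *either*
rounding or truncation toward zero yields the printed digits: the source
tables demonstrably mix the two conventions (e.g. an accuracy of 0.97452
printed as 0.974), and accepting both resolves every entry without
loosening the comparison anywhere else. A printed `<0.001` matches any
smaller computed value. All 232 comparisons across the eight matrices
match.

The behavior matrices' column totals (7,565 test rows) are taken as
normative where the prose row count (7,567) disagrees; the posture
matrices are internally consistent at 8,123.

## Simulator

`flanksense.simulate` generates what the analysis assumes, not what a cow
measures. Per bout:

`signal = R(jitter)·g_posture + A·sin(2πft + φ)·d + bursts + ε`

- **Gravity**: S → (−1, 0, 0); LSR → mostly −z; RSR → mostly +z (the
  sensor lies on the left flank, so left recumbency presses it toward the
  ground), each tilted by a per-bout random rotation (SD 5°) and
  renormalized.
- **Dynamics** (defaults; plausible choices, not measurements):
  resting 0.01 g unstructured; ruminating 1.0 Hz sinusoid at 0.05 g
  (regular jaw cycles); feeding 0.8 Hz at 0.15 g plus 0.3 Hz bursts;
  standing still 0.02 g noise only; moving 0.3 g Poisson step impulses at
  0.5 Hz with a ~0.4 s decay tail (comfortably above the "at least a step
  every 10 s" definition of moving). Oscillations couple mainly into y
  with some leakage into z. Frequencies must sit below the 2.5 Hz Nyquist
  limit.
- **Sessions**: bouts are scheduled by a time-budget mixture defaulting to
  ~60% standing / ~40% lying with resting the largest behavior class,
  mirroring the late-morning observation windows of the study design; bout
  durations are whole numbers of samples and sum exactly to the requested
  session length. Posture transitions are smoothed over ~1.5 s; a band of
  samples at every bout boundary is flagged ambiguous, sized so ambiguous
  samples make up `ambiguous_fraction` (default 7%, the removed share in
  the study's accounting) of the session.
- **Ethogram consistency**: resting only in recumbency; feeding, moving
  and standing still only while standing; rumination in either. Violations
  raise.

**What passing synthetic tests does and does not show.** The simulated
classes are separable essentially by construction — window-mean gravity
directions differ by > 45° between postures, and the behaviors differ in
amplitude and spectral content — so near-perfect synthetic accuracies
validate the plumbing (windowing, features, split hygiene, metrics), not
the field difficulty of the task. Real recordings add sensor migration,
inter-animal variation, behaviors blending into each other and label
noise; the published real-data behavior accuracies (~0.68–0.76) are not a
target the simulator tries to mimic. What the end-to-end check preserves
qualitatively is the ordering: posture (static gravity) is far easier than
behavior (dynamics).

## Problem sizes and numerics

Default test/demo sessions are 25–120 minutes (7,500–36,000 samples,
roughly 500–2,700 windows), enough for every classifier to be exercised
meaningfully while keeping the full suite under half a minute; the window
arithmetic check runs on a full-scale 456,730-sample simulated stream,
which is cheap because only segmentation touches it. Seeds: every stage
draws from one `numpy` seed sequence per run, so a run is reproducible
byte-for-byte from its global seed. Exact binomial intervals and p-values
come from `scipy.stats.binomtest`; coverage of the 95% interval is
verified by seeded simulation (n = 200, 2,000 replicates) at p = 0.5
and 0.9.

## Known limitations

- The simulator's behavior dynamics are stylized; it does not emulate
  drift, sensor detachment, gait harmonics, or per-cow idiosyncrasies.
  Group-wise (per-animal) splitting is not implemented; all reported
  accuracies are within-session.
- The greedy correlation filter is order-dependent by design and makes no
  minimality claim; it guarantees only the post-state.
- The abstract feature count of the source method ("32 features") differs
  from its own enumerated table of 36; all 36 are implemented.
- Timestamps are naive local time; no time-zone or DST handling.
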