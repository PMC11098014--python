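# Methods

## Scope and model

`dancekin` summarizes a fixed-skeleton 3D joint trajectory by time-averaged
kinematic statistics and classifies genre from that summary. The model of a
"dance sequence" is deliberately minimal: an `(N, J, 3)` position array at a
constant frame rate, COCO-17 joint layout, Y-up, coordinates in meters. No
mesh, no joint angles, no music. The encoding is stationary by design — every
feature is an average, SD, rate or spectral summary over the whole sequence —
so sequences of different durations are directly comparable, at the cost of
discarding within-sequence structure (choruses, drops, phrase boundaries).

## Kinematic substrate

The COCO layout has no spine keypoints, so the sacrum is estimated as the
midpoint of the hips. Velocity, acceleration and jerk are forward finite
differences, each followed by an optional Savitzky–Golay pass
(least-squares local polynomial fit). Smoothing **between** differencing
stages, rather than once on positions, is what keeps repeated
differentiation from amplifying keypoint jitter by `1/ΔT` per stage.

Numerical choices:

* **Window 31 frames (~0.52 s at 60 fps), polyorder 3** by default.
  Dance-relevant motion lives at a few Hz and below; a cubic fit over half
  a second passes it nearly untouched while strongly attenuating per-frame
  jitter. Both parameters are exposed in configuration and recorded in
  output metadata. Note that smoothing is a filter, not a free lunch: for a
  clean 1 Hz sinusoid the window-31 filter introduces ~1.6% RMS carrier
  distortion, so when input noise is well below that level smoothing can
  *increase* RMSE. The defaults assume keypoint noise at the centimeter
  scale, where denoising dominates.
* **Forward differences, trimmed to `N' = N - 3`.** All three derivative
  arrays share one valid frame range so every feature averages over an
  identical set of frames. With smoothing disabled, jerk equals the direct
  third-difference formula `(P_{i+3} - 3P_{i+2} + 3P_{i+1} - P_i)/ΔT³`
  exactly — this is a test invariant.
* **Edge handling**: polynomial-interpolated edges (`mode="interp"`), so
  smoothing preserves array length.
* Population (ddof=0) standard deviations everywhere.

## Feature definitions and conventions

The registry is data (name, category, units, description), so alternative
encodings are pluggable; the default has 5 sacrum + 4 extremity + 6
angular-momentum + 2 expandedness features.

* **Floor and ankle height.** The floor is the minimum vertical coordinate
  either ankle reaches across the sequence; per-frame height is the two
  ankles' mean vertical coordinate minus that floor.
* **Angular momentum** is unit-mass: `L_ij = R_ij × V_ij` with `R` the
  joint position relative to the sacrum and `V` the joint's (vector)
  velocity. Hips count as joints; the synthetic sacrum does not. For a
  joint at horizontal radius `r` and height `y` above the sacrum rotating
  rigidly at `w` about the vertical axis, `|L| = w·r·sqrt(r² + y²)` and the
  vertical component is `w·r²` — the latter is the quantity "horizontal
  rotation" reports, because rotation in the floor plane produces angular
  momentum along the vertical axis. A literal variant that instead averages
  the magnitude of the (x, z) components is available behind a flag for
  comparison with axis conventions that read "horizontal" as "the X and Z
  components of L".
* **Sharp movements.** Per axis, the per-joint momenta are summed into one
  series; local maxima of its absolute value with prominence at least
  1.0 x the series SD are counted and divided by the duration. Emitting
  *rates* rather than raw counts keeps sequence duration (7–48 s in the
  motivating corpus) from leaking into the encoding. The prominence
  criterion assumes sharp events stand out against a smoother background
  trace; against white-noise-dominated traces the folded absolute value
  gives noise peaks prominence comparable to the series SD, which is one
  reason smoothing precedes feature extraction by default.
* **Bounce frequency and regularity.** On the mean-removed vertical sacrum
  series, frequency is the arg-max of the magnitude spectrum (zero bin
  excluded) and regularity is the height of the first prominent peak of the
  *unbiased* normalized autocorrelation at positive lags, clipped to
  [0, 1]. A constant series returns (0, 0); white noise gives regularity
  near zero. "Regularity" has no canonical definition in the movement
  literature; the autocorrelation first-peak height is this package's
  documented operationalization.
* **Autocorrelation peak rates (augmented registry).** Per axis, peaks of
  the *biased* normalized autocorrelation over lags up to half the sequence
  are counted when their prominence exceeds 1.0 x the autocorrelation's SD
  *and* their height clears a `3/sqrt(N)` white-noise significance band,
  then normalized by duration. The biased estimator is used here (unlike
  the regularity feature) because its variance under white noise is
  uniformly bounded in lag, which is what makes a single significance band
  valid across the lag window; without the band, the expected upper tail of
  noise lags would register as "peaks" on aperiodic data.

Symmetry properties (all enforced by tests): global translation changes no
feature; rotation about the vertical axis changes only the x/z-resolved
sharp rates; uniform spatial scaling by `c` scales lengths by `c`,
accelerations/jerk by `c`, momentum statistics by `c²`, and leaves rates,
frequencies and regularity unchanged.

## Input handling

Three dialects are read: the AIST-style pickled container (key
`keypoints3d`), a JSON document (which can carry genre/tier labels), and a
long-format CSV. Single missing (all-NaN) frames are linearly interpolated
per coordinate; runs longer than 0.5 s, or missing data at the sequence
boundaries, abort with an error — the encoding averages over time, so
fabricating long stretches of motion would silently bias every feature.
Inputs are treated as meters; a Z-up flag converts at read time. Genre and
tier are decoded from AIST-style file names through an editable token
table (the ten genre codes map bijectively onto the vocabulary).

The **advanced-heavy split** mirrors a generalization-oriented study
design: short repetitive "basic" sequences train a model evaluated only on
long individualized "advanced" choreography. Per genre, a fraction
(default 0.52, round half up) of advanced sequences is sampled into the
test set; everything else trains. The default fraction reproduces a
103-vs-96 advanced split on a corpus with ~199 advanced sequences.

## The simulator and what it does (and does not) emulate

`motionsim` composes rigid-body motion primitives on a fixed 1.7 m
standing skeleton: whole-body vertical bounce `A·sin(2πft)`, rigid spin
about the vertical axis through the sacrum, antiphase sinusoidal
wrist/ankle oscillation, a scale factor on joint–sacrum offsets,
Poisson-timed 3-frame jerk impulses on the wrists, and iid Gaussian
keypoint noise added last. Each dial has a closed-form consequence
(`expected_features`), valid when noise is off and at most one dynamic
dial class is active: e.g. bounce jerkiness `A(2πf)³·2/π`, height SD
`A/√2`, spin momentum `w·r·sqrt(r²+y²)` per joint, expandedness linear in
the scale factor.

The ten default genre templates spread bounce, spin, limb oscillation,
expandedness and sharp-event rate over distinct combinations with 12%
relative parameter jitter and 1 cm keypoint noise; durations are drawn
from N(9.25 s, 1.6) for basic and N(36.5 s, 6.1) for advanced sequences
(clipped to 7.4–48 s), matching the short-repetitive vs. long-individual
structure of real dance corpora.

What the simulator does **not** emulate: articulated limb kinematics
(limbs translate, they do not rotate about joints), ground contact and
weight transfer, style variation within a sequence, correlated keypoint
noise from pose estimators, or any audio coupling. Passing the benchmark
therefore shows that the pipeline recovers the kinematic quantities it
claims to measure and separates classes that differ in those quantities —
it does not show that real genres are this separable. On real
motion-capture corpora the expected ordering is ensemble > linear
baselines > chance, with substantially lower absolute accuracy than the
synthetic benchmark's.

## Classification

Features are z-scored with training-set statistics only. The search draws
a budget (default 40) of candidate configurations from a model zoo —
regularized logistic/ridge linear models, random forests, extra trees,
histogram gradient boosting, RBF-SVM, k-NN, Gaussian naive Bayes — with
log-uniform/integer hyperparameter ranges, scores each by multiclass log
loss on a stratified inner validation split (default 25%, floored at one
row per class), and assembles a greedy weighted ensemble: repeated
selection with replacement of the candidate whose addition most lowers
the running validation log loss, up to 20 picks, stopping early when no
addition improves. Weights are selection counts normalized to one. Because
the first pick is the best single candidate and later picks must improve,
the ensemble's inner-validation loss never exceeds its best member's —
recorded in model metadata and asserted in tests. Selected members are
refitted on the full training set. Models without a probability interface
(ridge, perceptron, SVC) are wrapped with a softmax over decision margins —
a monotone surrogate that preserves the argmax, not a fitted calibration.
Argmax ties break toward the lowest class index so confusion matrices are
reproducible. Everything is deterministic given the seed.

## Analyses

* **LSA embedding**: truncated SVD (k=3) of the z-scored genre x feature
  matrix of per-genre *means* — one point per genre. Column signs follow a
  largest-loading-positive convention so embeddings are reproducible. A
  per-sequence variant is a one-liner (`lsa_embed` accepts any row table)
  but genre aggregates are the default reading.
* **Shapley values** are computed directly against a background sample:
  exact subset enumeration up to 12 features (local accuracy holds to
  machine precision), permutation sampling above. Global importance is the
  mean |value| over instances and classes; per-class summaries keep sign.
  Permutation importance (mean log-loss increase over shuffles) is the
  cheaper default.
* **Fingerprints**: per-genre feature means plus the within-genre Pearson
  correlation matrix; zero-variance features and genres with fewer than 3
  rows are flagged undefined (NaN entries listed by name) rather than
  silently zeroed.
* **Confusion comparison**: per-class accuracies (diagonal over row
  support) of two reports, their Spearman rank correlation, and the
  classes ranked by absolute disagreement — built for comparing a model's
  confusion matrix against an external study's (e.g. human raters), via
  `report_from_confusion` when only the matrix is published.

## Known limitations

* The encoding is stationary; two sequences with identical marginal
  statistics but different temporal organization are indistinguishable.
* The floor estimate assumes at least one ankle touches the lowest point
  reached during the sequence; choreography performed entirely on an
  elevated prop shifts ankle heights.
* The softmax probability surrogate for margin-only models is uncalibrated;
  log-loss comparisons across member families should be read accordingly.
* Peak-based rates depend on the prominence convention (1.0 x series SD);
  alternative conventions change absolute rates, though monotonicity in
  the underlying event rate is preserved.
* The benchmark's problem sizes (30 sequences per genre, budget 40) were
  chosen to exercise the full pipeline at interactive timescales; they are
  configuration, not limits.
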