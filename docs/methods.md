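# Methods

## Scope

The package implements a complete off-line two-class (move vs rest) EEG
decoding chain — filter-bank CSP, marginal-relevance feature selection,
Gaussian-process classification — plus the evaluation schemes used to
study how well such a decoder transfers across subjects and across a
stroke-recovery interval. No real recordings ship with the package; a
synthetic cohort generator provides sessions with the statistical
structure the analysis assumes, and the published accuracy tables are
packaged so their summary statistics can be recomputed exactly.

## Synthetic cohort generator

Each session is a 32-channel, 256 Hz recording of 40 alternating
move/rest trials of 10 s (move first, no gap). The signal model has two
parts:

* **Background**: 32 independent 1/f^α sources (α = 1, unit variance)
  mixed into channel space through a seeded random orthonormal matrix and
  scaled to 10 µV. This gives spatially correlated, stationary,
  spectrally realistic noise at trivial cost; it contains no class
  information.
* **Sensorimotor rhythm**: band-limited Gaussian noise (4th-order
  Butterworth band-pass of white noise) added to the channels through a
  fixed spatial gain profile centred on C3 (weights 1.0 at C3, 0.4 at
  FC1/FC5/CP1/CP5, 0.15 at C4 — a coarse left-motor-cortex field).
  During move trials its amplitude is multiplied by √erd_depth, so
  erd_depth is the move/rest band-power ratio of the rhythm
  (event-related desynchronization). The rhythm's within-band amplitude
  is set to 7× the background's own band-limited amplitude at the focus
  channel, so the measured power ratio is dominated by the modulation
  (a 1/f floor biases it mildly toward 1; with erd_depth 0.25 the
  measured ratio is ≈ 0.27).

ERD is implemented as amplitude modulation of a sustained oscillation,
not as burst trains: the analysis only ever uses 6-s window variances,
which this controls directly.

Cohort profiles fix the discriminative band per group: `healthy`
16–24 Hz at erd_depth 0.25; `stroke_early` 8–16 Hz at 0.35 (shallower,
lower — discriminative power shifted toward mu/low-beta); `stroke_late`
is derived from `stroke_early` by the between-session drift (band centre
× 0.75, depth × 1.25), landing near 5–13 Hz. These choices mirror the
empirical observation that stroke-affected datasets select CSP features
in progressively lower frequency ranges, and they make the late profile
the natural "drifted" continuation of the early one. Left-hand subjects
are generated by mirroring the spatial gain profile, which exercises the
preprocessing mirroring step.

Everything is driven by one integer seed (identical profile ⇒
bit-identical session). What the generator deliberately does *not*
emulate: volume-conduction head models, eye/muscle artefacts,
within-trial non-stationarity, inter-subject montage variability.
Passing tests therefore demonstrate correctness and statistical sanity
of the *pipeline*, not expected accuracy levels on real stroke EEG.

## Preprocessing

"Zero-phase 4th-order Butterworth" is realized as forward–backward
(`filtfilt`) application of the 4th-order design, giving zero net phase
and the squared magnitude response; recording edges use odd-reflection
padding (a documented implementation choice). Filtering precedes
epoching so filter transients stay outside analysis windows. Windows are
half-open in samples, [onset + 2 s, onset + 8 s), exactly
duration × fs samples.

The mirror-pair table for the BioSemi-32 10/20 layout is fixed in code
(Fp1/Fp2, AF3/AF4, F7/F8, F3/F4, FC1/FC2, FC5/FC6, T7/T8, C3/C4,
CP1/CP2, CP5/CP6, P7/P8, P3/P4, PO3/PO4, O1/O2; Fz/Cz/Pz/Oz midline).

## CSP and features

Class covariances are per-trial centered spatial covariances, normalized
by their trace and averaged over the class's trials; grouped ("general")
models pool the trials of all training sessions before averaging. No
shrinkage by default; an optional ridge ε·I on the composite covariance
is exposed for near-singular grouped fits. The generalized eigenproblem
is solved per band with `scipy.linalg.eigh(Σ_move, Σ_move + Σ_rest)`;
components are sorted by descending move-class whitened eigenvalue and
column signs are fixed (largest-magnitude entry positive) so fits are
bit-reproducible — signs are irrelevant to variance features.
Internally, component variances are evaluated as wᵀCw from cached
per-trial covariances, which is algebraically identical to the variance
of the projected time series and lets cross-validation folds reuse one
computation.

The feature of trial i, band b, component c is the log *proportional*
variance: the trial's component variance divided by the sum of that
component's variance over all trials of the batch being transformed.
This across-trials normalization (per column, batch exponentials sum
to 1) is unusual — the more common CSP feature normalizes across
components, available via `feature_norm="components"` — and it makes
features *batch-dependent*: the same trial transformed inside a batch of
different size is shifted by log of the batch variance sum. Since
training batches (e.g. 36 trials) and test batches (e.g. a 4-trial fold)
can differ in size, the classification pipeline compares features on a
batch-size-invariant scale by adding log(batch size), i.e. normalizing
by the batch *mean* rather than sum of trial variances. The two
conventions differ only by a per-column constant — to which the MRelv
ratio and a classifier standardized on training statistics are both
invariant — so with equal-size batches (whole-session transfer, the
method's native usage) they are indistinguishable, while unequal batch
sizes no longer inject a spurious log(n_train/n_test) offset into every
feature. Without this, temporally-blocked 10-fold CV of a perfectly
separable session sits at chance.

## Feature selection

MRelv = BSS/WSS per column (= F·(k−1)/(n−k) for k groups); ties are
broken by ascending (band, component), and a zero within-group variation
column scores +∞ and ranks first. The four top-ranked columns are the
*primary* picks; each contributes its same-band complementary partner
(component j pairs with c−1−j, the two extremes of the whitened
eigenvalue spectrum working together), with duplicates counted once —
because partners form a symmetric bijection, the selected set has size
8, 6 or 4. Frequency-range histograms count only the four primary picks
per dataset. Selections are frozen at training time; test batches are
restricted to the identical columns.

## Gaussian-process classifier

Binary GPC with an isotropic squared-exponential kernel times a
signal-variance factor, logistic likelihood, Laplace approximation, and
hyperparameters maximizing the approximate marginal likelihood from a
fixed initialization (unit length-scale and amplitude, no random
restarts) — fully deterministic. The implementation wraps
scikit-learn's Laplace GPC behind the package's {+1, −1} label and
0.5-threshold conventions (p = threshold classifies as +1). Features are
standardized per column with training-split statistics so one
length-scale is comparable across features; this standardization is an
artifact decision, as is the whole kernel/inference configuration — the
original analysis only specified "a sigmoidal squashing function".

## Evaluation schemes

* **k-fold CV** (default k = 10): folds are temporally contiguous blocks,
  never shuffled; with a trial count not divisible by k, block sizes
  differ by at most one with earlier blocks larger.
* **Cross matrices**: one individual BCI per training session, applied to
  every test session; self-pairs are left missing.
* **Grouped training**: trials pooled across sessions into one general
  CSP/selection/classifier model; leave-one-out applies this over a
  cohort.
* **Longitudinal**: early-session-trained BCI tested on the same
  subject's late session (subject identity enforced).

In every scheme, CSP fitting, MRelv ranking and classifier training see
only training trials.

## Group statistics

Rank-sum comparisons use mid-ranks, the tie-corrected normal
approximation *with* continuity correction, reported as |Z| with
r = |Z|/√N — this convention (Matlab's `ranksum`) reproduces the
published Z values on the heavily tied percentage data at printed
precision. Signed-rank tests drop zero differences, use exact
enumeration for n ≤ 15 pairs, and return p = 1 with a degeneracy flag
when all differences are zero. Sample SDs use the n−1 denominator.
Display rounding is to one decimal; tests compare raw values within half
a printed unit (the published tables round half-up, Python's `round`
half-even).

For the packaged cross-dataset table, the "healthy" group comprises the
90 off-diagonal healthy-test cells and the stroke groups all 50 early-
and 50 late-test cells, the grouping consistent with the published
effect sizes via r = |Z|/√N.

## Problem sizes and tolerances

Statistical property tests (band recovery, permutation null, transfer
degradation, longitudinal advantage) use 20 independent seeds at the
default session size (40 trials, 32 channels, 256 Hz); the grouped
healthy reference model pools 4 sessions. Whitening and complementarity
hold to 1e−6, feature-column normalization to 1e−9, CSP eigenvalues
match a brute-force generalized-eigendecomposition oracle to 1e−8, and
GPC refits reproduce probabilities to 1e−8. The permutation null is
accepted within 50 ± 10% averaged over seeds; one-sided paired tests use
α = 0.05.

## Known limitations

* The generator's stationarity and single-rhythm design make
  within-session decoding easier than real EEG; absolute accuracies on
  synthetic cohorts are not comparable to published values (which is why
  the published tables are reproduced as packaged data, not as model
  output).
* Across-trials proportional-variance features are transductive at the
  batch level; single-trial online operation would require a different
  normalization (out of scope).
* Multi-class CSP, expectation-propagation GPC inference, ARD kernels,
  artefact rejection and topographic rendering (beyond raw pattern
  export via `spatial_patterns`) are out of scope.
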