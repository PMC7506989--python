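# Methods

## Signal model and preprocessing

The pipeline operates on one EEG derivation sampled at `Fs` Hz. The raw
record is low-pass filtered once, end to end, with a zero-phase
forward–backward Butterworth filter (order 8 per pass, cutoff 35 Hz by
default), then cut into non-overlapping epochs of `Te` seconds
(`j = Te × Fs` samples). Sleep EEG below 35 Hz carries the stage-defining
rhythms (delta through beta); the low-pass removes line noise and most EMG
contamination. Zero phase matters because epoch boundaries must line up
with the expert's scoring grid: a causal filter's group delay would shift
oscillatory features across epoch boundaries. Trailing samples that do not
fill an epoch are dropped and logged — real records rarely divide evenly.

Epoch labels come from EDF+ annotation tracks or one-label-per-line text
hypnograms. Movement/unknown codes are preserved as an explicit `excluded`
sentinel and masked out of training rather than merged into wake: merging
would contaminate the wake class with artifact epochs, and the mask keeps
the bookkeeping auditable. Stage merging across the 2–6-class schemes
follows the two scoring manuals (R&K: S3+S4 merge first, then S1+S2, then
all NREM; AASM: N1+N2 merge before N3 joins).

## Wavelet-packet decomposition and locality energies

Each epoch is expanded into a *full* packet tree — both approximation and
detail branches split at every level — giving `2^l` equal-width sub-bands
at level `l`, kept in natural (filter-bank) order with node 1 the repeated
low-pass path. The transform uses **periodization** boundary handling, so a
level-`l` node has exactly `j / 2^l` coefficients and, for an orthonormal
filter pair, energy is conserved: `Σ_m ‖C_{l,m}‖² = ‖x‖²`. This makes the
energy feature a true partition of the epoch's power. The cost of that
exactness is a divisibility requirement: `j` must be divisible by `2^l`,
which the synthetic defaults satisfy by sampling at 128 Hz (30 s epochs →
j = 3840 = 2^8·15, supporting all levels up to 7). Recordings whose epoch
length lacks the divisor must be resampled or epoched accordingly.

Fifteen orthogonal wavelets are supported (db1–db32, sym2–sym16, coif1,
coif3, dmey). The stock discrete-Meyer approximation deserves a note: the
62-tap `dmey` filter shipped by wavelet toolboxes is a plain truncation of
the infinite Meyer filter and violates the paraunitary conditions by about
1.4 × 10⁻³, which would leak roughly 0.2 % of the signal energy per
decomposition level. This package therefore projects the taps onto the
perfect-reconstruction manifold (200 alternating projections between the PR
constraint set and the 62-tap support, then a Newton polish on the defect
equations), yielding a filter within 8 × 10⁻⁴ of the stock taps that
conserves energy to ~10⁻¹³. The projection runs once per process and is
cached; it is deterministic.

The locality-energy feature of node `m` is the sum of squared coefficients
— a sub-band energy in µV²·sample. Energies are invariant to sign flips and
scale quadratically with amplitude; no normalization is applied before
classification (an optional flag exists), matching the convention of
feeding raw energies to tree ensembles, which are scale-equivariant.

## Dual state-space models

The two first-level packet series (each `j/2` samples: a 0–Fs/4 band and a
Fs/4–Fs/2 band) are modelled as outputs of innovation-form linear systems

    u_{k+1} = A u_k + K e_k,        y_k = B u_k + e_k,

with `A ∈ R^{n×n}`, `B ∈ R^{1×n}`, `K ∈ R^{n×1}` and white innovations
`e_k`. Estimation is a classical stochastic subspace procedure:

1. subtract the series mean (the model has no affine term);
2. build a block-Hankel matrix of `2i` shifted copies (horizon
   `i = 2n + 1` by default, configurable), split into past and future;
3. project the future row space orthogonally onto the past (computed by
   least squares, never by explicit inversion);
4. whiten with the Cholesky factor of the future covariance (CVA
   weighting) and truncate the SVD at order `n`;
5. take `A` from the shift invariance of the extended observability matrix
   `Γ` and `B` from its first row — the shift-invariance route is
   consistent for the dynamics at fixed horizon, where a state-sequence
   regression would be biased at short horizons;
6. recover the state sequence as `Γ⁺` times the projection and estimate
   `K` by regressing the state residuals on the output residuals — in the
   innovation form `x_{k+1} − A x_k = K e_k` holds exactly, so this joint
   least squares is the natural estimator; the innovation variance is
   reported alongside.

`(A, B, K)` is identifiable only up to a similarity transform, but the
downstream classifier consumes the raw entries, so the decomposition is
canonicalized: states ordered by descending singular value, each left
singular vector signed to make its largest-magnitude entry positive. The
estimator is then a pure function of the series — bitwise repeatable across
runs, which the tests assert.

Two consequences worth knowing:

* **Sign invariance.** Subspace estimation sees only output covariances,
  which are identical for `x` and `−x`; together with the canonicalization
  this makes the model features exactly sign-invariant, like the energies.
  The full feature vector therefore cannot distinguish an epoch from its
  negation — irrelevant for staging, where polarity carries no meaning.
* **Identifiability limits.** Poles whose contribution nearly cancels
  against a zero of the minimum-phase spectral factor are unrecoverable
  from output data at any sample size (a maximum-likelihood ARMA fit shows
  the same scatter). The recovery tests therefore draw generators by
  explicit pole/zero placement (minimum phase, poles separated by ≥ 0.25,
  zeros kept away from poles) and state their tolerance — 0.15 on
  eigenvalues at T = 4000, frozen after calibration against the ARMA
  oracle — rather than pretending arbitrary random systems are
  identifiable.

Degenerate inputs fail loudly: constant series (zero variance), series
shorter than 10× the horizon, and orders beyond the numerically observable
rank raise with the effective rank reported.

## Feature fusion and dimensions

Per epoch: `[E_1 … E_{2^l_LE} ‖ s_1 ‖ s_2]`, with `s_m = [vec(Â) row-major
‖ B̂ ‖ K̂]`. Dimension `2^l_LE + 2(n² + 2n)`; the supported grid is
`l_LE ∈ {3…7}`, `n ∈ {5…10}` and the defaults (db1/6, db4/5) give
32 + 96 = 128. Only the first-level split feeds models (two models);
deeper splits would multiply the model count by `2^l` and inflate the
dimension past usefulness — the generalized multi-model layout is out of
scope and the split level is fixed at 1.

## Classification and evaluation

Six candidate classifiers are exposed by name, mapped to their scikit-learn
equivalents of the common GUI presets: linear/quadratic discriminant,
quadratic-kernel SVM, 1-NN ("fine" KNN), bagged trees
(`BaggingClassifier`, 30 unlimited-depth trees, all features per split —
bagging, not a random-subspace forest) and RUS-boosted trees (seeded random
undersampling of majority classes to the minority count, then AdaBoost with
tree learners; no imbalanced-learning dependency required). Bagged trees is
the default, having won the classifier search.

Evaluation is plain 10-fold cross-validation: uniform random fold
assignment (a stratified option exists, default off), every epoch validated
exactly once, fold sizes differing by at most one. The headline accuracy is
`trace/total` of the confusion matrix pooled over the out-of-fold
predictions; the per-fold mean is also reported (the two differ only
marginally). Cohen's kappa uses the pooled matrix's marginals. Per-class
sensitivity is the diagonal cell over the expert-row total, reported as
missing (NaN) for empty rows rather than raised.

## Parameter search

The two-step grid mirrors how the operating point was originally selected:
step 1 evaluates wavelet × order on the model features alone; step 2
freezes the winner and evaluates wavelet × level on the fused vector. Every
candidate draws its own fold assignment from the master seed plus a fixed
stride times the candidate index (all derived seeds < 2³¹), so candidates
are comparable yet independently resampled, and the whole search replays
exactly under one seed. Ties break by higher kappa, then smaller model
order, then candidate-list position — prefer the simpler model,
deterministically. A full 15-wavelet × 6-order × 6-classifier search at
database scale is hours of compute; the package runs the identical
procedure at smoke scale (small grids, short synthetic epochs) in seconds,
which is what the tests exercise.

## Synthetic data: what it does and does not show

The generator emulates exactly what the feature pipeline exploits:
stage-dependent band-limited oscillatory content. Each stage profile fixes
relative powers over the classical bands (delta 0.5–4, theta 4–8, alpha
8–13, sigma 12–16, beta 16–30 Hz) summing to one, plus an overall amplitude
(15 µV wake-like up to 60 µV deep-sleep-like, matching the amplitude
ordering of real sleep EEG). An epoch is the corresponding mixture of
band-passed Gaussian noise (same zero-phase Butterworth family as the
preprocessing, so bandpower oracles in the tests are self-consistent), plus
a 5 % broadband floor; a state-space model can replace the floor as a
colouring filter. Defaults: 30 s epochs at 128 Hz.

The five default profiles are well separated by construction, so the
end-to-end cross-validated accuracy on them (> 80 % asserted; in practice
≈ 100 %) certifies that features carry the spectral information through to
the classifier — it says nothing about real-data accuracy, where stages
overlap, transition epochs are mixtures, and N1 in particular shares its
rhythms with wake and REM. The shuffled-label control (accuracy within 3
points of 20 % for five balanced classes) certifies the absence of
information leakage across CV folds. Real-data features *not* emulated:
spindles and K-complexes as discrete transients, artifacts, inter-subject
variability, non-stationarity within an epoch.

Fixtures are written as genuine EDF (16-bit) with a text hypnogram sidecar,
and round-trip through the same readers used for real recordings, within
one quantization step of the declared physical range.

## Numerical and I/O choices

* EDF reading goes through MNE (physical units taken from the header, µV);
  channel matching is exact after whitespace/case normalization — no fuzzy
  matching, to avoid silently picking the wrong derivation.
* The fixture writer emits a fixed, dateless EDF header so identical data
  produce byte-identical files; physical min/max are floored/ceiled to
  8-character header fields that always enclose the data (no clipping).
* Feature CSVs carry a provenance header (package version, full
  configuration, input SHA-256 checksums; deliberately no timestamp) so a
  rerun with the same config and seed is byte-identical.
* All randomness flows from explicit seeds through `numpy` generators;
  derived sub-seeds stay below 2³¹.

## Known limitations

* The strict divisibility contract (`j` divisible by `2^level`) rejects
  epoch geometries like 3000 samples at level 5; padding variants of the
  packet transform would accept them at the cost of the exact node-length
  and energy-partition guarantees.
* The subspace estimator targets short, stationary sub-band series; it is
  not an ARMAX/exogenous-input identifier and offers no model-order
  selection of its own (the order is a searched hyperparameter).
* Headline accuracies on the public databases (e.g. 92 % six-class on
  Sleep-EDF) require the actual recordings and hours of feature
  extraction; nothing in this repository asserts them. The tests assert
  what is checkable at desk scale: exact metric recomputation from
  published confusion matrices, transform and estimator correctness, and
  end-to-end behaviour on synthetic data.
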