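# Methods

This note documents the models, conventions and design choices behind
`mi3d`, module by module, including what the synthetic generator does and
does not emulate.

## Preprocessing

All IIR filtering uses 4th-order Butterworth designs applied
forward–backward (`sosfiltfilt`), i.e. zero phase, so event latencies are
preserved.  The band-pass default is 0.5–40 Hz (the theta/alpha/beta range
relevant to motor imagery plus drift suppression); the mains notch is a
band-stop over 49.9–50.1 Hz.  A 0 Hz lower band edge — which occurs in the
fixed-start filter bank — is realised as a low-pass at the upper edge after
per-trial mean detrending, because a true 0 Hz high-pass is the identity.

Epochs are half-open windows `[cue, cue + 3 s)` with 0-based sample
indexing: at 250 Hz a trial is exactly 750 samples.  The epoch window start
relative to the cue is configurable; the default assumes imagery begins at
the cue marker.  Normalisation is per-trial, per-channel z-scoring with a
variance floor of 1e-12 for degenerate (constant) channels.

File reading for BrainVision and GDF is delegated to MNE; channel order is
preserved from the file and data are kept in microvolts.  The internal HDF5
container uses fixed dataset names (`/data`, `/labels`, `/fs`,
`/channel_names`, `/events`) so fixtures are bit-stable.

## ICA artifact rejection

Decomposition is scikit-learn FastICA (deflation, `tol=1e-4`, at most 500
iterations) with a seed, preset to 15 components; rank-deficient data
reduces the component count with a warning.  Removal subtracts the flagged
components' contribution (`mixing[:, k] @ sources[k]`) from the signal
rather than re-projecting through the retained subspace, so the residual
outside the ICA subspace is untouched and a threshold of 1.0 is the exact
identity.

Labelling is a pluggable interface with a built-in rule-based scorer (any
classifier producing `ComponentLabel`s can replace it):

| class | raw score | probability map |
|---|---|---|
| line | fraction of source power in 49–51 Hz | logistic(center 0.6, gain 12) |
| emg | fraction of power above 30 Hz, excluding 49–51 Hz | logistic(0.5, 12) |
| eog | \|corr\| with a <3 Hz frontal-average proxy, gated on >0.4 frontal mixing mass | logistic(0.7, 12) |
| ecg | autocorrelation peak at 0.8–1.5 s lag, gated on kurtosis > 2 | logistic(0.5, 10) |
| impedance | largest single-channel share of the mixing column's ℓ2 mass | logistic(0.8, 25) |

The EMG score excludes the mains band so a pure 50 Hz source cannot
masquerade as muscle activity.  A component is `neural` when no artifact
score maps above 0.5 (its probability is then one minus the largest
artifact probability); zero-variance sources are `other`.  A single global
removal threshold of 0.9 applies to all artifact classes.  Labelling is a
pure function of the decomposition and recording.

## CSP family

Class covariances are trial-normalised (`X Xᵀ / trace`) and averaged; the
filters solve `eig(R_a, R_a + R_b)` so whitened eigenvalues lie in [0, 1]
and pair to 1 between classes.  A singular composite covariance is
ridge-regularised with `eps = 1e-8 · trace` and a warning.  Eigenvalue sort
ties are broken by a stable sort.  Features are log normalised variance
over the retained rows — invariant to a global gain on the trial.  The
feature formula is the standard Ramoser convention; nothing else about the
feature definition is assumed.

The genetic algorithm searches binary row-selection genes: tournament
selection of size 2, single-point crossover at rate 0.5, per-bit flip
mutation at 0.06, elitism of one, defaults population 50 × 200 generations
(tests and the acceptance script use a reduced 20 × 30 budget, which
suffices for 6-channel fixtures).  Fitness is mean stratified 5-fold SVM
accuracy on the gene's feature subset; the filter matrix is fitted once on
the full binary training set and per-gene evaluation only re-normalises
pre-computed row variances, so exhaustive enumeration on small problems is
cheap and serves as the test oracle.  All-zero genes are assigned chance
fitness (0.5) instead of being evaluated.  Gene fitness values are memoised
within a run.

The SVM is an RBF SVC with kernel scale 0.783 and regularisation 0.922 as
defaults, mapped to scikit-learn as `gamma = 1/0.783², C = 0.922` (the
kernel-scale convention `K(x,y) = exp(−‖x−y‖²/s²)`); both are overridable.

Multi-class decoding decomposes into binary problems: OVO fits one CSP+SVM
per class pair (6 for four classes) and votes; OVR fits one per
class-vs-rest (4) and takes the largest decision value.  All voting ties —
pairwise votes and cross-band votes alike — resolve by the highest summed
decision-function margin, then the lowest class index; the rule is
deterministic and used everywhere.

Filter banks: `fixed_start` = (0,4), (0,8), …, (0,36) — nine expanding
bands; `sliding` = (0,8), (4,12), …, (28,36) — eight overlapping 8 Hz
bands; `merged` = their union with the shared (0,8) de-duplicated, 16
unique bands; `fbcsp` = eleven uniform 4 Hz bands stepping from 4 Hz.
SFB-CSP trains one multi-class CSP+SVM per band on band-filtered trials and
takes the majority vote across bands.  Bands reaching the Nyquist rate are
dropped with a warning at fit time.  Because the bands overlap heavily,
per-band features are never concatenated — each band votes independently.

## Welch PSD

Segments of length `L` start `D` samples apart (overlap `L − D`), are
windowed, periodogram-corrected by the window power `Σ w(n)²` and averaged.
Defaults: `L = fs` (1 s, 1 Hz resolution), 50 % overlap, Hamming window,
per-segment constant detrend, bins kept up to 40 Hz (41 bins at the
defaults — the PSD-input length of the convolutional model).  The one-sided
density convention (divide by `fs · Σ w²`, double interior bins) makes
Parseval hold: the integral of the PSD equals the variance of a broadband
signal.  With one rectangular segment and no detrending the estimator
reduces to the raw periodogram exactly (asserted to 1e-10 in tests).

## Topographic tensors

A packaged injective mapping places each electrode on a `W × W` grid (rows
anterior→posterior, columns left→right); unmapped cells are exactly zero,
so the tensor sum equals the 2-D sum and the mapping round-trips
bit-exactly.  The 64-channel 10-20/10-10 layout uses `W = 9` (64 filled, 17
empty cells).  The 22-channel four-class benchmark montage is packaged with
`W = 7`, the smallest width that can hold its seven-electrode central row
injectively.  Both ship as `channel,row,col` CSVs under `mi3d/data/` and
any user CSV can override them — every injective placement preserves the
invariants.

The 90° rotation used by the dual-branch network maps cell `(r, c)` to
`(c, W−1−r)` (a corner at (0,0) moves to (0, W−1)); four applications are
the identity and the mapping rotates with the tensor.

## Convolutional model

The `T` axis (time samples or PSD bins) is the channel axis of 2-D
convolutions over the spatial plane.  Per branch, with 'same' zero padding
and stride 1 throughout:

| layer | operation | output (C, H, W) for W=9 |
|---|---|---|
| L1 | conv (9,1) → W channels, ELU, dropout 0.25 | (9, 9, 9) |
| L2 | depthwise (3,6) + pointwise → 36, batch-norm, ELU, dropout 0.25, avg-pool (3,6) | (36, 3, 2) |
| L3 | depthwise (2,3) + pointwise → 72, batch-norm, ELU, avg-pool (2,4) | (72, 2, 1) |
| head | flatten → dense 256, ELU → dense n_classes → softmax | 4 |

The stated pool/kernel sizes cannot tile a 9×9 plane exactly, so pooling
uses ceil-mode zero padding (pad counted in the mean) and every shape is
validated at build time — a mismatch raises naming the layer, never silent
truncation.  "Depthwise with 36/72 output channels" is realised as grouped
convolution followed by a 1×1 pointwise expansion.  The L1 (W,1) kernel
spans a full grid column, so each kernel's receptive field is one column;
the dual-branch variant feeds the rotated tensor to a second, independently
weighted branch (supplying the orthogonal sweep) and concatenates the
flattened branch outputs before the dense head.

The implementation is pure numpy with hand-derived backpropagation (grouped
im2col-free convolutions, batch-norm, ELU, inverted dropout, ceil-mode
average pooling, dense layers) and an Adam optimiser — compact enough for
the small tensors involved and free of framework dependencies.  Training
defaults: Adam at 1e-3, cross-entropy, 200 epochs, batch 16, stratified
16 % validation split (skipped with a warning when the set is too small to
stratify).  One seeded generator drives weight initialisation, dropout and
shuffling, so runs are bit-reproducible at a fixed thread count; tests
assert identical weight checksums across repeated runs.  Epoch counts of
200 (default) and longer schedules are both just configuration.

Metrics: accuracy, confusion counts, and Cohen's kappa
`(p_o − p_e)/(1 − p_e)` with marginal-product expected agreement; the
degenerate single-cell matrix (p_e = 1) is defined as kappa 0 with a
warning.

## Synthetic generator

Each trial is per-channel pink noise (spectrally shaped white noise with
1/f amplitude, no DC) plus a shared common-mode pink term (gain 0.5)
standing in for volume conduction, scaled to a 10 µV background standard
deviation.  Each class adds one band-limited oscillation (8–13 Hz filtered
noise, new draw per trial) whose per-channel amplitude follows the class's
spatial pattern: Gaussian bumps (σ = 1.5 cells) centred on distinct grid
cells — left central (4,2), right central (4,6), anterior midline (2,4),
posterior midline (6,4) — so spatial filters and spatial kernels have
recoverable structure.  `snr` is the ratio of channel-averaged rhythm power
to background power; `snr = 0` removes the class signal entirely, making
classes statistically indistinguishable.

Artifacts: blink transients are 0.4 s raised-cosine pulses (80 µV) weighted
onto frontal channels; line noise is a 50 Hz sinusoid with a fixed random
per-channel gain profile (15 µV nominal) — rank-one spatially, hence
separable by ICA — and random phase; EMG bursts are 0.2 s of >30 Hz noise
(25 µV) on five random channels.  In continuous recordings the line noise
spans the whole recording, as real mains interference does.

What the generator does **not** emulate: biophysical forward models
(leadfields, realistic covariance structure), non-stationarity across a
session, inter-subject variability, and the genuine difficulty of
lower-limb imagery (deep, medial sources with high inter-class ambiguity).
Passing recovery tests therefore demonstrates the correctness of the
pipeline's machinery — filters recover planted structure, voting and
cross-validation are wired correctly — not the accuracy one should expect
on real recordings, where four-class lower-limb decoding typically lands
far below the near-perfect synthetic numbers.

## Evaluation harness

Stratified k-fold plans (default 10 folds) are seeded and balanced; the
benchmark fits every model strictly on training folds, with trial-index
bookkeeping asserting that train and test indices never overlap.  Per-cell
failures are recorded and the run continues.  The convolutional model's
default protocol is a 50/50 train/test split with a 16 % validation carve
out of training; the CSP family uses cross-validation.  Confusion counts
are stored per cell so kappa is recomputable from the report.

## Problem sizes used in the shipped checks

The test-suite and acceptance-script runs use deliberately compact problem
sizes, chosen as the smallest at which each property is statistically
unambiguous: 200 trials/class for covariance-recovery tolerances of 0.05;
100 trials/class × 64 channels × 3 seeds for end-to-end decoding; a
6-channel fixture for the GA (where the 2⁶ exhaustive oracle is exact);
8-trial memorisation at a reduced tensor length (T = 60) for the network's
capacity check, with the full (9, 9, 750) geometry exercised in forward
passes.

## Known limitations

* The component labeller is a transparent heuristic stand-in exposing the
  same interface as learned classifiers; it is reliable on planted
  artifacts but not validated on real recordings.
* SVM ensembles are not serialised; `CSPModel` round-trips through a
  documented HDF5 layout, and benchmark outputs are CSV/JSON.
* The numpy network is CPU-bound and intended for the package's trial
  counts, not large-scale training.
* GDF files are read (via MNE) but never written; round-trip fixtures use
  BrainVision and HDF5.
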