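# Methods

## Problem setting

The package decodes the category of a viewed natural image from fMRI
response amplitudes in five human visual areas (V1, V2, V3, V4, LO). Each
sample is one stimulus: per voxel a single deconvolved, standardized
amplitude (no time dimension), plus a three-level category label (5-, 10-,
and 23-way, nested). The method has two stages: voxel-wise sparse encoding
models select the most stimulus-driven voxels per area, and a bidirectional
LSTM classifies the five selected-voxel vectors as an ordered "space
sequence", so that both each area's content and the relationship between
areas inform the prediction.

## Encoding stage

**Model.** For a voxel response vector `y` (m samples) and a feature matrix
`X` (m × n, one feature layer), the encoding model is `y = Xw` with `w`
sparse, since n (feature dimension) typically far exceeds m.

**Solver.** Regularized Orthogonal Matching Pursuit. Per iteration:
correlate the residual with all columns (`u = Xᵀr`); keep the
`max_nonzeros` largest |u|; *regularize* this candidate set to the
contiguous magnitude-sorted window of maximal energy Σu² in which every
pair satisfies |u_i| ≤ 2|u_j| (the comparable-magnitude rule with factor 2);
add the window to the support (clipped to the sparsity budget); refit all
support coefficients by orthogonal least squares; update the residual.
Stopping: relative residual ≤ `residual_tol` (default 1e-4), support at the
budget, or a residual decrease below 1e-12·‖y‖. Because refitting is least
squares on a growing support, the residual norm is non-increasing; the
implementation also asserts this. Defaults: `max_nonzeros = min(m/4, 100)`.
Feature columns are z-scored with training-split statistics before fitting
so magnitude comparisons across columns are meaningful.

With the sparsity budget set exactly to the true sparsity, a single
regularized batch can admit a wrong column and exhaust the budget; at the
default budget the solver matches exhaustive best-subset least squares on
small noiseless problems (200/200 of the 20×8 2-sparse problems in the
acceptance script) while still producing sparse fits.

**Scoring and selection.** Every (voxel, layer) pair is fitted on the
training rows only and scored by Pearson correlation between prediction and
observation on the validation rows (selection on training correlation would
overfit). Correlation of a constant prediction is undefined and flagged as
NaN; NaN scores sort last. Per area, the layer whose top-200 voxels (by
validation correlation; clipped to the available count) have the best mean
correlation is chosen, ties toward the lower layer. The top-100 voxels of
each area on its chosen layer (ties by ascending voxel id) become the
area's node vector.

## Decoding stage

**Architecture.** The five K-dimensional node vectors (K = 100 after
selection) form a length-5 sequence. Two independent LSTMs (hidden width
H = 16) consume it in V1→LO and LO→V1 order from zero initial state; their
final hidden states are concatenated (forward half first) into a 2H = 32-D
feature, which a fully connected softmax layer maps to 5/10/23 classes.
Concatenation of the two final states is forced by the 16-D → 32-D
arithmetic of the architecture; per-node output pooling is not used.
Per direction the trainable parameter count is 4·((K+H)·H + H) — 7,488 at
K = 100, H = 16.

**Training.** Multiclass focal loss `−(1 − p_y)^γ log p_y` with γ = 5.0
(γ = 0 recovers cross-entropy; p_y floored at 1e-12), mean over the batch.
Adam (β₁ = 0.9, β₂ = 0.999), learning rate 1e-3, batch size 64, ~200
epochs. "Weight regularization 1e-3" is implemented as decoupled L2 decay
applied to weight matrices (not biases) in the optimizer step. Dropout 0.5
is applied to the combined 2H feature during training only (inverted
dropout), and identically to the single-direction ablations' H-dimensional
feature and the MLP baseline's last hidden layer, so the comparisons differ
only in connectivity. Initialization: weights uniform in ±1/√H, biases zero
except the forget-gate bias at +1 (standard practice to start with open
memory). No early stopping; the epoch budget is fixed and configurable.

All forward and backward passes are hand-written numpy in double precision;
gradients were verified against central finite differences (relative error
< 1e-4 on random parameter probes, and ~1e-7 in practice). Given a seed,
data order, dropout masks and initialization derive from one `Generator`,
so single-threaded runs are bit-reproducible. The guarded sigmoid/softmax
and the probability floor make the loss finite even under extreme
parameters; a non-finite loss (e.g. from corrupted inputs) aborts training
with a diagnostic rather than continuing.

**Baselines.** Decision tree, random forest (100 trees), AdaBoost, linear
and RBF SVM operate on the concatenated 5K vector (scikit-learn, seeded
where stochastic; SVMs and AdaBoost are deterministic given fixed data, so
their repeat variance is exactly zero). The non-recurrent neural baseline
is a 500→64→32→classes ReLU network trained with the identical loss and
optimizer recipe.

## Evaluation protocol

Validation accuracy in percent, reported as mean ± sample standard
deviation over five repeated runs with identical hyperparameters and
different seeds (the ± value is a standard deviation, not a variance, as it
is on the accuracy scale). Pairwise differences use Welch's two-sample
t-test on the per-seed accuracies; against a deterministic baseline the
one-sample variant tests the stochastic method's repeats against the
constant; two constant sides give p = 1 with a degenerate flag. Confusion
matrices are row-normalized, entry (i, j) = P(pred = j | true = i); rows
without support are NaN-flagged. On balanced data, trace/n_classes equals
balanced accuracy.

## Synthetic data generator

The generator emulates the statistical situation of the real data without
any download. One dataset seed fans out to fixed-offset child streams so
each component is independently reproducible.

* **Label hierarchy.** A random *balanced* nested partition of 23 fine
  labels into 10 mid (sizes 2–3) and 5 coarse groups (2 mids each, 4–5 fine
  labels). Balance keeps the label marginal near-uniform at every level, so
  chance accuracy is ~1/5, 1/10, 1/23 — a property the null-control tests
  rely on. Within-sample labels are always consistent across levels.
* **Features.** Per layer an i.i.d. standard-normal (samples × dim) matrix,
  a neutral stand-in for externally extracted image features (real feature
  extraction from a pretrained image model sits behind an optional provider
  interface and is not required anywhere).
* **Voxels from features.** Each voxel reads out its area's planted layer
  through a weight vector with exactly `sparsity_k` nonzeros; nonzero
  magnitudes are drawn U(0.5, 1.5) with random sign. Bounding magnitudes
  away from zero is the standard sparse-recovery benchmark convention: a
  nearly-zero "nonzero" coefficient would make the true support
  unidentifiable for any method and the recovery ground truth meaningless.
  Noise variance is signal variance / `snr` (`snr = inf` → noiseless);
  responses are standardized per voxel with training-split statistics,
  mirroring the preprocessing of real amplitudes.
* **Area sequences.** Area a of a sample with fine label l is
  `β_marginal[a]·μ(l,a) + β_relational·M(l,a)z/√K + N(0, I)`, with fixed
  unit mean patterns μ, fixed label-dependent mixing matrices M, and a
  per-sample shared latent z. The marginal term is a per-area category mean
  whose strength grows from V1 to LO (default β = 0.6…1.4), emulating the
  increase of semantic content along the ventral hierarchy; the relational
  term stores category information in how areas co-vary, which is what the
  bidirectional sequence model is designed to exploit. Sequence noise is
  fixed at unit variance, so the β coefficients are directly in noise-sd
  units; `snr` governs only the feature→voxel stage. Fine labels are
  stratified to balance within ±1 sample per class.
* **Composite dataset.** For the end-to-end pipeline the two structures are
  summed per voxel: standardized sparse feature readout (label-independent;
  the decoder's noise floor) plus the category components, so the encoding
  stage has supports to recover and the decoding stage has categories to
  decode in the *same* dataset.

What the generator does **not** emulate: hemodynamics or time series (the
real amplitudes are post-deconvolution scalars by construction), spatial
voxel correlations within an area, retinotopic organization, session
effects, or realistic CNN feature statistics. Passing tests therefore
demonstrate correctness and the intended qualitative orderings of the
method, not performance levels transferable to real recordings.

## Study conditions used by tests and the acceptance script

Problem sizes are scaled so the whole suite runs quickly on one CPU while
keeping each check statistically meaningful:

* Sparse-recovery oracle: 200 random 20×8 noiseless 2-sparse problems,
  compared against exhaustive C(8,2) best-subset least squares.
* Encoding recovery: 5 areas × 20 voxels, 64-D layers, `sparsity_k` = 3,
  m = 300, snr = 20; exact-support rate and planted-layer selection.
* Strong-marginal decoding: K = 20 voxels/area, 600/200 train/validation,
  β_marginal = (4.0…5.2) ("high": the Bayes accuracy of the task is ≈0.99),
  100 epochs, five seeds; plus a shuffled-label null averaged over three
  shuffles (99% binomial CI on the pooled count).
* Relational ordering: β_marginal = (0.2…0.3), β_relational = 1.5, same
  sizes; bidirectional vs forward-only mean accuracy over five seeds.

## Known limitations

* The LSTM is plain numpy: perfectly adequate at these dimensions
  (H = 16, L = 5), but not a GPU implementation.
* At the full default scale (K = 100 voxels per node, weak default signal
  strengths) the 16-unit sequence model underfits relative to the wide
  fully connected baseline; the bidirectional advantage is demonstrated in
  the relational regime at K = 20, where the cross-area signal dominates.
  How strongly it transfers to other regimes depends on the signal mix.
* The relational signal is one specific form of label-dependent cross-area
  coupling; real inter-area dependence is richer.
* The vim-1 adapter maps responses and the 1750/120 partition but the
  release ships no category labels; labels must be provided separately.
* Reported absolute accuracies on synthetic data are properties of the
  generator's conditions, not predictions for real fMRI.
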