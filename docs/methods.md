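# Methods

## Task and data model

The classifier labels the central adenine of a fixed-length DNA window
(length L, odd, default 41) as 6mA-methylated or not. Datasets follow the
common benchmark layout: one FASTA file per class, balanced, every window
ACGT-only with A at the center (position (L+1)/2, 1-based; 21 for a
41-mer). Class balance is checked but only warned about, so the tool
remains usable on unbalanced data. Sequences containing N are rejected
because the embedding alphabet is fixed at four symbols. All user-facing
coordinates are 1-based.

## Architecture

- **Embedding.** A trainable 4×N table (N = 32 by default) maps nucleotide
  indices (A,C,G,T → 0..3) to feature vectors, giving X ∈ R^{L×N}.
- **Branches.** One branch per window size K ∈ {3, 5, 7}; each branch
  stacks six layers. A layer: linear N→M (M = 64), position-specific
  convolution with F = M filters of width K (zero padding K//2; every
  position has independent weights, `conv_mode="shared"` ties them for
  ablations), SiLU, selective scan, layer normalization over the feature
  axis, linear F→N, residual addition of the layer input. Normalizing
  before the down-projection keeps the residual in R^{L×N}; layer
  normalization (not RMS) was chosen as the conventional default. No
  multiplicative gate branch is used — the layer is the plain
  projection → conv → SiLU → SSM → norm → residual composition.
- **Selective SSM.** Per channel, h_t = Ā_t ⊙ h_{t−1} + B̄_t·g_t with
  h_0 = 0 and z_t = ⟨C_t, h_t⟩; the state is updated with the current
  input before emission, so z_t depends on g_1..g_t (the standard
  selective-SSM convention; the alternative "emit before update" leaves
  the first output referencing an undefined state). B_t and C_t are affine
  in the post-SiLU conv output row; Δ_t = softplus(affine(g_t)) is a
  positive scalar step per timestep. Discretization is zero-order hold:
  Ā_t = exp(Δ_t·A) exactly (A diagonal), B̄_t = Δ_t·B_t (the customary
  first-order simplification of the exact ZOH input term). A is stored as
  −exp(A_log) with A_log initialized to log(1..S) (S = 16), so A stays
  negative and |Ā_t| ≤ 1 — the recurrence cannot diverge. softplus(b_Δ)
  is initialized at 0.1 so initial state decay is moderate.
- **Fusion.** Learnable query vectors Q_K ∈ R^N weight each scale
  (W_K = Q_K ⊙ Z_K, broadcast over positions); the per-cell triple is
  softmax-normalized across scales and the output is Σ_K W′_K ⊙ Z_K — a
  convex combination, so fused values stay within the per-cell range of
  the branch outputs.
- **Head.** Row-major flatten of Z ∈ R^{L×N} (41·32 = 1312), then fully
  connected 384 → 16 → 1 with ReLU and dropout 0.2 after the first two
  maps and a terminal sigmoid. The 16-wide post-ReLU activation is the
  "penultimate" embedding used for visualization.

N, M, F and S are not fixed by the architecture definition; the defaults
(32, 64, 64, 16) were chosen so the flattened fused matrix reasonably
feeds the 384-wide first head layer, and all are configurable. Affine
weights use fan-in-scaled uniform initialization, the embedding N(0, 1/N);
all initialization derives from one seed.

## Autodiff and numerics

No deep-learning framework is used: parameters are NumPy arrays and
gradients come from a small tape-based reverse-mode engine
(`ssm6ma.autodiff`). The position-specific convolution and the scan are
fused operations with hand-derived backward passes (the scan backward is
backprop-through-time over the stored states, compiled with numba); both
are validated against naive nested-loop oracles and finite differences in
the test suite. Default parameter dtype is float64; training runs use
float32 for speed, gradient-check tests float64. Training loss is binary
cross-entropy computed from logits (softplus(z) − y·z) for numerical
stability; the public `bce_loss` on probabilities clips scores to
[1e-7, 1−1e-7]. MCC uses the continuity convention (0 when a denominator
factor vanishes); SN/SP are NaN when undefined; AUC is the Mann–Whitney
rank statistic with tie correction (delegated to scikit-learn and
cross-checked against a brute-force pairwise count). Checkpoints store the
config as JSON and the weights as an .npz archive; save → load → predict
is bit-identical.

## Training protocol

Adam (conventional defaults) at batch size 64; learning rate 5e-5 for
small datasets and 1e-5 above a 40 000-sample threshold — the benchmark
protocol names its two largest species for the smaller rate, generalized
here to a size rule so it applies to any dataset. Early stopping on
validation accuracy (threshold 0.5) with patience 30 and a 500-epoch cap
(the cap is a safety bound, not part of the protocol); the returned model
is the best-validation checkpoint, earliest epoch on ties; patience 0
therefore trains exactly one epoch. Cross-validation is stratified
shuffled k-fold (k = 5): stratification balances folds and stabilizes
accuracy-based early stopping. Each fold's model is evaluated
independently on the held-out test set and summarized as mean ± stdev; an
optional flag adds the score-averaged ensemble. Validation accuracy for
early stopping is fold-internal.

## Synthetic benchmark

The generator emulates the benchmark's shape: balanced classes, length 41,
center A forced in both classes (negatives are unmethylated adenines, not
non-adenines). Background positions are i.i.d., uniform by default
(composition configurable). A motif — default GAG anchored at position 20,
encoding the G-flanked 6mA core — is planted in positives with
`plant_probability` 0.9 and in negatives with `decoy_probability` 0.1.
These defaults create a strong but imperfect signal, the regime where
metric comparisons are informative. A `scrambled` mode instead plants the
pattern in negatives at a uniformly random *other* valid anchor with the
same probability, so both classes contain the motif equally often and
only its position carries label information; this isolates the claim that
position-specific filters beat shared ones. The generator does not model
read-level noise or false-negative labels, so passing tests demonstrate
signal recovery, not robustness to label noise; real benchmarks also
carry species-specific background composition the uniform default lacks.

Under the default planting rates the information ceiling is explicit: the
only informative observables are "G at 20" and "G at 22", the likelihood
ratio exceeds 1 only when both hold, and the resulting Bayes-optimal rule
has accuracy 0.875 and MCC ≈ 0.75. The test suite asserts that the
trained model reaches this ceiling (within 0.05 MCC of the rule evaluated
on the same test set) rather than an arbitrary level above it.

## Scaled study sizes

The end-to-end studies run at desk scale, chosen once as the package's
standard validation conditions: 2000 sequences per class (1000 per class
held-out test), the default architecture, 5-fold cross-validation, with a
compressed schedule (learning rate 1e-3, patience 1, max 3 epochs) — the
planted-motif task converges within two or three epochs at this rate, and
the benchmark protocol (5e-5, patience 30) remains the package default
for real data. The ablation study uses a reduced architecture (N=16,
M=32, S=8, two layers, single window 3) at 500 sequences per class over
five generator seeds with 2-fold cross-validation; the reduced model
keeps the comparison about the convolution mode rather than capacity.

## Interpretation

Intensity profiles average the fused Z over the feature axis per sample,
then over ground-truth classes; the class contrast is reported per
position, and localization is judged on |contrast| because the sign of a
feature-mean is arbitrary. Penultimate embeddings are exported as TSV for
external projection; UMAP is delegated to umap-learn behind a thin
adapter. The enrichment table uses class-conditional frequencies with a
0.5 pseudocount per cell and a log2 odds score — deliberately a simple
statistic, not the pLogo binomial logo, and labeled as such; it carries
no significance testing.

## Known limitations

- The sequential scan is O(L) per layer with no parallel-scan kernel;
  adequate at L = 41, not intended for long sequences.
- Training at the full benchmark's scale (hundreds of thousands of
  sequences, patience-30 schedules) is supported but slow on one CPU.
- The synthetic generator's i.i.d. background understates real genomic
  structure; conclusions about relative architectures transfer, absolute
  metric levels do not.
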