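# Methods

## Sequence representation

A sequence of length L over {A,C,G,T,N} is cut into overlapping windows of
size m (default 3) with stride s (default 1): count = ⌊(L−m)/s⌋ + 1, so
the default 200-bp input yields 198 tokens. Each token indexes a
k-dimensional vector (default k = 100). Conceptually the sample is the
concatenation e₁ ⊕ ⋯ ⊕ e₁₉₈; the implementation stores the equivalent
(T, k) matrix, which is what the 1-D convolutions slide over.

Embedding sources:

- **Pretrained** (the default regime): a word2vec-text file of k-mer
  vectors, loaded and frozen. A config flag allows fine-tuning.
- **Fallback**: all 4^m k-mers with N(0, 1/k) entries, seeded. Used when
  no file is supplied and as the initialization of the
  trainable-embedding ablation ("Non-dna2vec"), where the replacement
  representation is an open choice; a trainable layer initialized from
  the fallback table is the standard alternative and is what this package
  does.
- Tokens containing N, or otherwise out of vocabulary, map to a shared
  slot that is a zero row under the `zero` unknown-policy (zero rows are
  inert under convolution) and a trainable row under `learned`.

## Architecture

Two encoders read the embedded matrix in parallel.

**Convolution blocks.** All convolutions are stride 1 without padding
(L_out = L_in − K + 1), each followed by ReLU and non-overlapping max-pool
of width 2 — the smallest non-trivial pooling, which also keeps the
198-token input valid through ConvBlock1's four-layer kernel chain
(198→190→95→95→47→43→21→14→7). Block structure:

| block | channels | kernels |
|---|---|---|
| ConvBlock1 | 160, 160, 160, 256 | 9, 1, 5, 8 |
| ConvBlock2 | 128, 256 | 11, 9 |
| ConvBlock3 | 180, 256 | 1, 8 |

The original description of the two-layer blocks lists their channel
counts and kernel sizes jointly, which admits two pairings; the default
preset pairs kernels (11, 9) with ConvBlock2 and (1, 8) with ConvBlock3,
and the alternative pairing ((11, 1) / (9, 8)) ships as the `alternate`
preset. A
`channel_multiplier` scales every block's output channels (the kernel*2 /
kernel*3 ablations). Block outputs are flattened and concatenated in
block order.

**BiLSTM.** Hidden size 128 per direction. The gate equations carry
diagonal peephole connections (input and forget gates see c_{t−1}, the
output gate sees c_t), following the printed recurrence; h_t = o_t ⊙
tanh(c_t). Peepholes can be disabled by config. Forward and backward
passes are combined by concatenation by default — matching the printed
combination operator — with elementwise summation available, since the
surrounding prose describes summation. The sequence summary is the final
combined state of each direction: the fusion stage needs a single vector
per sequence, and the source does not specify a pooling; this is recorded
as an open choice.

**Fusion, normalization, head.** CNN and BiLSTM features are linearly
projected to a common width D (default 128). With the residual connection
on, the fused vector is proj(cnn) + proj(lstm); the no-residual ablation
concatenates both and projects once. The fused vector is
layer-normalized and dropped out (rate 0.3 by default; the rate is not
specified upstream and is logged with every run). The layer-norm gain is
initialized at 0.5 so the fused features (≈ N(0, 0.25) at init) sit
almost entirely inside the spline grid's [−1, 1] domain rather than
saturating against its clamped boundary; the gain is trainable, so this
is purely an initialization choice. No attention module exists anywhere
in the pipeline; the mention of normalization "following attention" in
the source text has no accompanying attention description, so
normalization is applied at the only junction described — the fused
features.

**KAN head.** Widths [D, 32, 1] (one hidden layer of 32 — the source
specifies the hidden width but not the depth; one hidden layer is the
default here). Each edge (i → j) carries f(x) = Σₖ c_{j,i,k} Bₖ(x) +
w_{j,i}·silu(x): cubic B-splines (degree 3) on an open-uniform knot grid
of 5 intervals over [−1, 1], plus the silu base term of the reference KAN
formulation. The strict spline-only form (`kan_use_base = False`) is
available for ablation. Grid bounds are fixed; inputs are clamped to the
grid for the spline term (gradients vanish outside, as they must), while
the base term sees the raw input. The per-edge formulation is used: the
source's per-node notation together with "learnable activation functions
on the edges" resolves to one univariate function per input–output pair.
Spline coefficients initialize as small noise (σ = 0.1/√n_in), base
weights at linear-layer scale (σ = 1/√n_in). The MLP-head ablation uses
the same widths with ReLU.

The output is a single sigmoid logit trained with binary cross-entropy;
point metrics use the fixed threshold 0.5 (never tuned, always reported).

## Training protocol

Stratified splits: 10% validation, then 10% of the remaining 90% as test
(9% of the whole); per-class proportions preserved to within one sample;
fully seeded. Adam with lr 5 × 10⁻⁴ and canonical moments, batch size 64,
at most 20 epochs. Validation ROC AUC is evaluated every 100 batches by
default (the cadence is this package's choice; the patience — 5000
batches without improvement — is the protocol's). The best-validation
checkpoint is kept and restored, so the returned model is never worse
than the best evaluation seen. Training aborts with diagnostics on a
non-finite loss. With fixed seeds the entire pipeline is bit-reproducible
on one device: splits, initialization, batch order, dropout masks, and
all fused kernels are deterministic.

## Synthetic data

The generator emulates the data regime the model targets: fixed-length
sequences (default 200 bp), a positive class carrying one implanted motif
instance, negatives matched in length and GC content, class balance
constrained to [3:7, 7:3]. Background bases are i.i.d. with
P(G) = P(C) = gc/2 (default GC 0.41, the human genome average). The motif
is a random PWM whose sharpness is set by `motif_strength` s: each column
is ((1−t)·uniform + t·d + s·onehot(argmax d)) / (1 + s) with
t = s/(1+s) and d ~ Dirichlet(1,1,1,1) — exactly uniform at s = 0,
graded degeneracy at intermediate s, guaranteed near-consensus
(max ≥ s/(1+s)) at large s. A pure power-sharpening d^s was rejected
because near-tied Dirichlet draws leave a non-vanishing fraction of
ambiguous columns even at large s. Implant positions are uniform over the
admissible range and recorded in the FASTA headers;
`implant_probability < 1` leaves some positives unimplanted as a label
noise control (0 is allowed and produces an exact null dataset).
Negatives are drawn at the empirical GC of the realized positives
(matched to ±0.01), or — to preserve local composition as a surrogate for
the repeat-fraction matching used with real data — as
dinucleotide-preserving (Altschul–Erikson) shuffles of positives.

What the simulator does **not** emulate: ChIP-seq noise and peak-calling
artifacts, repeat families, chromatin context, strand effects, multiple
or clustered motif occurrences, and dna2vec's learned embedding geometry
(the fallback table is random). Passing the synthetic checks therefore
demonstrates that the architecture, training loop and metrics work and
that the model recovers planted PWM signal; it does not certify
performance on real ChIP-seq data.

## Numerical and engineering choices

- The network runs on a package-internal numpy autodiff engine with fused
  primitives (im2col convolution in channels-last layout, max-pool,
  peephole LSTM with a JIT-compiled backward loop, layer norm, KAN
  layer). Gradients of every primitive are verified against central
  finite differences in float64.
- B-spline evaluation uses the vectorized Cox–de Boor recursion on the
  open-uniform knot vector; the domain's right endpoint is treated as
  belonging to the last interval so the partition of unity holds on the
  closed domain. Tests cross-check against a scalar textbook recursion
  and scipy's `BSpline.design_matrix`.
- ROC AUC is the Mann–Whitney rank statistic with midrank tie handling;
  PR AUC uses step interpolation (trapezoidal PR interpolation is
  optimistically biased). MCC's zero-denominator convention is 0. F1 is 0
  when precision + recall is 0.
- Max-pool ties break toward the earlier position. Pool remainders are
  dropped.
- Parameters are float32 for speed; correctness tests run the same code
  paths in float64.

## Problem sizes used by the test suite and acceptance script

Training-based checks run the full architecture on the default simulated
regime (1000+1000 sequences of 200 bp, motif strength 10, split
1620/200/180) with an 8-epoch schedule — enough for the model to converge
on this regime (the checks assert test ROC AUC ≥ 0.9 there), while the
full 20-epoch protocol would only add compute on a single core. The
label-shuffle null trains 1 epoch (the null is flat regardless of
training length) and is scored on the combined held-out validation+test
split, averaged over 3 seeds, because a single 180-sequence null AUC has
sampling σ ≈ 0.04. The ablation-matrix check trains every variant for one
epoch on a 120+120-sequence dataset — it verifies machinery (building,
training, reporting), not relative quality, which is data-dependent. The
dataset-difficulty monotonicity check uses a 3-mer-count logistic
regression as the trained model: the property under test concerns the
data, and the surrogate makes it cheap.

## Known limitations

- Single-strand view; no reverse-complement augmentation (none is
  described for the original protocol either). Users scoring genomic
  regions should score both strands and combine.
- Fixed input length per trained model; no variable-length support.
- The KAN grid is static ([−1, 1], 5 intervals); no grid refinement or
  pruning from the original KAN toolbox.
- No significance testing across methods and no external baselines; the
  out-of-scope comparisons require external datasets.
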