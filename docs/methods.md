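# Methods

## Problem and model

The package infers *cooperating pairs* of sequence motifs — typically
transcription-factor (TF) binding sites — from a deep model trained to
classify DNA sequences. The model is a one-dimensional convolutional
network with a multi-head self-attention layer:

1. **Input.** A sequence of length *L* is one-hot encoded as a 4 × *L*
   matrix (channel order A, C, G, T). `N` bases encode as all-zero
   columns, so unknown positions contribute nothing to any filter score.
   Unequal-length inputs are center-cropped or symmetrically N-padded to
   the configured *L*, because the attention dimension must be constant
   within a batch.
2. **Convolution.** *F* filters of length *A* are applied without
   padding (`L' = L − A + 1`), followed by ReLU. Valid (unpadded)
   convolution keeps the filter → genomic-position mapping exact, which
   the interpretation stages rely on.
3. **Max pooling** over non-overlapping windows of *M_p* positions
   (trailing partial windows dropped, `d = floor(L'/M_p)`). *M_p* is
   deliberately small (default 6 bp) so that one pooled position still
   addresses a near-basepair-resolution window; this is what later lets
   an attention entry be attributed to individual filters.
4. **Optional bidirectional LSTM** over the *d* pooled positions
   (feature width 2 × hidden size). Off by default; the attention route
   works identically with or without it.
5. **Multi-head self-attention.** Per head,
   `Q = X W_Q`, `K = X W_K`, `V = X W_V`,
   `A = softmax(Q K^T / sqrt(d_k))` (row-stochastic),
   `Z = A V`. The features entering the projections are standardized
   per position (mean 0, sd 1 over the feature axis, no learned
   parameters). This is a numerical necessity: ReLU-conv activations
   grow without bound during training, the score matrix scales
   quadratically with them, and the softmax saturates — measured
   mid-training row entropies drop to ~3% of the uniform value and
   learning stalls. The standardization caps the score scale without
   changing what the attention matrix means.
6. **Combine and read out.** Head outputs are concatenated, passed
   through a linear map, collapsed **by addition over the d positions**
   into one feature vector, standardized (mean 0, sd 1, ε = 1e-8 guard
   so constant vectors map to zeros), and fed to a single fully
   connected readout: 2 logits with softmax cross entropy for binary
   tasks, or *C* sigmoid logits with the mean binary cross entropy
   `−(1/C) Σ_i [y_i log σ(ŷ_i) + (1−y_i) log(1−σ(ŷ_i))]` for
   multi-label tasks.

The collapse axis was a genuinely open design point: collapsing over
*features* (yielding a standardized positional profile read by a linear
layer) is the other defensible reading. We implemented both; the
positional-profile variant provably cannot generalize any
position-uniform signal — for a motif planted at a uniformly random
position, a linear functional of a per-example-standardized profile has
zero expected class signal — and empirically it stayed at chance AUC on
a trivially separable one-motif dataset while memorizing its training
split. Collapsing over positions makes the readout position-invariant
and is the variant shipped.

The whole network, its training loop, and the input-gradient machinery
run on a small reverse-mode autodiff engine over numpy arrays
(`attnteract.autodiff`). Its analytic gradients are validated
throughout the test suite against central finite differences, including
a full forward + loss check on a d = 4, F = 3 model.

## Training

Adam (β = 0.9/0.999), learning rate 3e-3, batch size 16, early stopping
on validation loss with patience 5; data split 80/10/10
train/validation/test by a seeded shuffle. The learning rate and batch
size were chosen so the reduced-scale benchmark (below) is learnable
within its 5-epoch protocol; with the more conventional lr 1e-3 /
batch 64 the same model needs several times more epochs to leave chance
level. Everything is seeded; two runs with the same seed give bitwise
identical loss histories (verified also across BLAS thread counts).

Model selection uses uniform random search over declared ranges (filter
length, filter count, pooling window, attention feature sizes),
maximizing validation AUC.

## Interpretation: from attention to interaction calls

**Example selection.** Only high-confidence predictions are
interpreted. Binary: positives with predicted probability > p (default
0.70) form the foreground; negatives scoring < 1 − p form the
background. Multi-label: examples whose prediction precision —
thresholding probabilities at 0.5 against the true labels — exceeds
0.50; their background is built by dinucleotide-preserving shuffling
(below).

**Motif extraction.** For each filter, every window whose post-ReLU
score strictly exceeds half of that filter's global maximum over the
selected sequences is collected; the substrings are stacked into a
counts + 0.5-pseudocount PWM (uniform background). Information content
is the Kullback–Leibler divergence from background in bits; filters
with IC > 3.0 are eligible for TF naming. Naming uses either a parsed
TomTom result table (real motif databases; we write the MEME input and
read the TSV output, recommending Euclidean distance) or the bundled
matcher, which slides a database PWM along the filter PWM (≥ 5 aligned
columns) and accepts the best mean per-column Euclidean distance below
0.5 — roughly the midpoint between a well-recovered motif (< 0.3) and
an unrelated sharp motif (> 0.8). Ties resolve by smallest q, then p,
then TF name, so the mapping is order-invariant.

**Interaction calling.** Per example, the k head matrices are collapsed
by an elementwise maximum into one d × d matrix. For every pair of
pooled positions (i₁ ≠ i₂), the symmetrized value
`max(A[i₁,i₂], A[i₂,i₁])` is assigned to every cross pair of the
filters active at i₁ and at i₂ (same half-of-global-max rule as motif
extraction, with the maxima taken from the foreground set so both
stages agree). Accumulated over examples this yields an *attention
profile* per canonical filter pair (j₁ < j₂); profiles whose maximum
never reaches the attention cutoff (0.10 default; 0.08 is the
higher-sensitivity preset) are discarded. Each surviving pair is tested
foreground vs background with a one-sided Mann–Whitney U test (exact
null for tie-free samples with n₁ + n₂ ≤ 20, normal approximation with
tie correction otherwise; one-sided because an interaction can only
*raise* attention). A pair never observed in the background is tested
against the pooled background values of all pairs — the generic null
for attention magnitude. P-values are Benjamini–Hochberg adjusted
across all tested pairs; calls with adjusted p < 0.05 are translated to
TF pairs, dropping self-pairs and pairs involving uncharacterized
filters, and collapsing redundant filter pairs onto one TF pair
(smallest adjusted p kept, supporting-example frequencies summed).
Distances are reported as pooled-index separation × M_p.

**Backgrounds for multi-label tasks** are built by the
Altschul–Erickson Euler-path shuffle, which preserves the overlapping
dinucleotide count table *exactly* (and the first base, by
construction), followed by re-embedding filter-derived PWMs in
proportion to each filter's activation count, with rejection sampling
so embedded instances do not overlap.

## FIS: the Integrated-Gradients comparison route

For each selected example, each activated filter (best-activation
window of length *A*; overlapping windows pruned keeping the stronger
activation) serves in turn as the *source*; the remaining windows are
*targets*. Attributions come from Integrated Gradients with a
right-point Riemann rule, m = 64 steps by default. The source window is
replaced by random bases matching the sequence's GC content (one draw
per source; a repeat count is exposed), attributions are recomputed,
and FIS = (target attribution before) − (after). Significance uses
|FIS| profiles through the identical Mann–Whitney U / BH pipeline, so
the two routes produce interchangeable call tables. For multi-label
models the attribution objective is the sum of logits over
true-positive predicted tasks only.

The IG baseline is the uniform 0.25-per-channel matrix, not the all-zero
matrix. The zero baseline is degenerate here: a zero input produces
constant features, and the two standardization steps then make the
network almost scale-invariant along the interpolation ray, so the
entire output change collapses into an ε-neighborhood of the baseline
and completeness fails at any practical step count (measured
attribution sums ~10⁻⁷ against output differences ~2). With the uniform
baseline, completeness holds within 1% at m = 128 on a small model, and
the signed difference is kept in the records while |FIS| is used for
testing (a flag restores signed testing).

## The synthetic benchmark

`generate_benchmark1` emulates the embedded-motif interaction design:
i.i.d. random background sequences (default 300 bp, GC 0.5 — unstated
in the design, chosen as typical of promoter-scale inputs); every
positive carries one instance each of ELF1 and SIX5 (the simulated
interaction), every negative exactly one of the two (chosen at random);
each decoy (TAL1, AP3) is embedded with probability 0.3 per sequence in
both classes. Embeddings are placed uniformly among positions that keep
all spans non-overlapping, instances are sampled column-wise from the
PWM, and exact coordinates are returned for recovery tests. At full
scale the generator emits 120 000 sequences (40 000 positive / 80 000
negative).

The four motifs are synthetic stand-ins built from each factor's core
consensus (ETS GGAA core for ELF1, an E-box for TAL1, a CArG box for
AP3), with 0.97 consensus probability per column. The sharpness was
calibrated against the benchmark's defining property of near-perfect
class separability: with the true PWMs, a likelihood-scan oracle
reaches AUC 0.994 at 0.97, whereas softer matrices (0.85) cap even the
ideal detector at 0.86 and no model could legitimately separate the
classes.

What the generator does *not* emulate: ChIP-seq peak shape, real GC
heterogeneity and repeats, motif–motif spacing preferences, indirect
cooperativity. Passing its recovery tests therefore demonstrates that
the inference machinery finds co-occurrence structure that attention
encodes — not that any particular biological interaction would be
found in real data.

## Problem sizes and reproducibility

The shipped end-to-end experiment uses 2 000 positives / 4 000
negatives, 32 filters, 4 heads, d_k = 32, 5 epochs — a deliberately
reduced rendition of the full-scale benchmark that completes in a few
minutes on one CPU while preserving its structure. At this scale the
trained models reach test AUC ≈ 0.95–0.97, and across three seeds the
attention route calls the planted ELF1–SIX5 pair (and nothing else)
significant in two of the three runs; in the remaining run the model
classifies well but its attention profiles do not separate foreground
from background and the method correctly reports nothing rather than a
false pair. Run-to-run variability of this kind is expected at reduced
scale; at the full scale (20× more data) the attention patterns
are far more stereotyped.

## Known limitations

- The concatenate/linear/collapse step is one concrete reading of an
  under-specified design point (see the collapse-axis discussion above);
  all sizes are exposed in `ModelConfig`.
- The half-of-global-max activation rule is reused for the interaction
  step; the right activation rule for that step is an open design choice.
- The bundled PWM matcher is a deliberately simple Euclidean aligner
  for self-contained runs; for real databases, TomTom remains the
  intended tool (the package writes its input and parses its output).
- The hypergeometric enrichment helper takes the candidate-universe
  size as an explicit argument rather than guessing which TF universe a
  reported count refers to.
- Binary classification is implemented as 2-logit softmax cross
  entropy; the reported probability is the positive-class softmax
  weight.
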