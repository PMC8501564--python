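# Methods

## Model

`orrcnn` predicts protein–protein interactions (PPIs) from primary sequence
by regressing the *confidence score* of a protein pair — a real number in
(0, 1) that quantifies how likely the pair interacts (STRING-style scored
pair tables are the canonical source) — and thresholding it.

The model has two parts.

**Pair encoder.** Each sequence is embedded residue-by-residue (one-hot,
a 7-class physicochemical indicator, or pre-trained skip-gram vectors),
zero-padded at the tail to a fixed length, and passed through a stack of
recurrent-convolutional (RCNN) units. One unit is

1. a width-*d* affine 1-D convolution, `h_t = M v_{t:t+d-1} + b` (no
   nonlinearity; output length *l − d + 1*),
2. per-dimension max over disjoint blocks of *n* consecutive positions
   (*n*-max-pooling; a partial final block is pooled over its available
   entries rather than dropped, so short tails are not discarded),
3. a bidirectional GRU whose forward/backward states are merged with the
   layer input either by concatenation `[fwd, bwd, v]` (dimension 3·d′) or by
   a residual shortcut `[fwd+v, bwd+v]` (dimension 2·d′; requires the input
   dimension to equal d′).

After the last unit a final convolution (same width *d*) maps back to d′ and
global average pooling over the remaining positions yields the sequence
embedding E(S) ∈ R^{d′}. A protein pair is encoded by running both sequences
through the *same* parameter bundle and multiplying the two embeddings
element-wise, x̄ = E(S₁) ⊙ E(S₂) — which makes the pair representation
exactly symmetric under argument order, for any parameter values.

GRU gates are the standard update/reset form:

    z_t = σ(M_z v_t + N_z h_{t−1} + b_z)
    r_t = σ(M_r v_t + N_r h_{t−1} + b_r)
    h̃_t = tanh(M_s v_t + r_t ⊙ (N_s h_{t−1}) + b_s)
    h_t = z_t ⊙ h̃_t + (1 − z_t) ⊙ h_{t−1}

**Ordinal head.** The score range (cs_min, cs_max) is split uniformly into K
sub-intervals; a pair scores label k when its confidence score falls in the
k-th sub-interval (boundaries belong to the interval on their right; the
first interval is open at cs_min). K−1 binary sub-classifiers — each a
one-hidden-layer MLP with Leaky ReLU (slope 0.01) and a 2-unit softmax
output — answer "is the label greater than k?" on the relabeled training set
D_k⁺ = {y > k}, D_k⁻ = {y ≤ k}. At prediction time the rank is
r̄ = 1 + #{k : f_k positive} (the sum tolerates mutually inconsistent
sub-classifier decisions; no monotonisation is applied, and a tie s₁ = s₂
decides negative). The rank decodes to a score — sub-interval mid-point by
default, or either endpoint — and the PPI call is `score > θ` (strict).

A scalar-output MLP regression head over the same pair encoding serves as
the ablation (squared-error loss); its raw output is passed through a
sigmoid scaled onto (cs_min, cs_max) so predictions stay strictly inside the
score range.

## Training

All K−1 sub-classifiers share one encoder and are optimised jointly: every
mini-batch is encoded once and the *sum* of the K−1 cross-entropies is
minimised. Joint training is the only arrangement consistent with parameter
sharing as a cost reduction; training each sub-classifier with its own
encoder would multiply the encoder cost by K−1.

The optimiser is AMSGrad (bias-corrected moments, running maximum of the
second-moment estimate as divisor, ε = 1e-8). Full-scale defaults: learning
rate 0.001, β₁ = 0.9, β₂ = 0.999, batch 768, kernel width d = 3,
3-max-pooling, d′ = 50, 5 stacked units, padded length 2000, K = 20 over
(0, 1). Epoch count defaults to 30.

The network is implemented on an in-package reverse-mode automatic
differentiation core over NumPy arrays (`orrcnn.autodiff`). The GRU
recurrence is a single fused graph node with hand-derived backpropagation
through time; its forward pass is checked against a literal scalar-loop
oracle and its backward pass against finite differences in the test suite.
Weights initialise uniform in ±1/√fan_in; the initial hidden state is zero;
zero-padding rows are processed like real positions (no masking mechanism is
part of the model). Training is single-threaded and bit-reproducible given
the seed.

## Embeddings

* **one-hot** — 20 standard basis vectors, alphabet order.
* **7-class indicator** ("eh") — the conjoint-triad grouping of residues by
  dipole and side-chain volume: {A,G,V}, {I,L,F,P}, {Y,M,T,S}, {H,N,Q,W},
  {R,K}, {D,E}, {C}. The indicator (rather than continuous dipole/volume
  values) is used; it behaves like a class-level one-hot.
* **skip-gram** — trained on a sequence corpus with negative sampling; each
  protein is one sentence, windows span ±C positions (C = 3 by default)
  skipping the centre, m = 5 negatives per positive drawn uniformly from the
  alphabet, 5 epochs of plain SGD at learning rate 0.025 with linear decay.
  The embedding dimension defaults to 20 for parity with one-hot.

Unknown residues (X, B, Z, U) are tolerated in input and embed to the zero
vector, i.e. they behave like padding.

## Synthetic benchmark

The generator plants a monotone, recoverable relationship between sequence
content and confidence score. Each synthetic protein draws a 7-class residue
composition from a symmetric Dirichlet(α = 0.5) (residues uniform within a
class); pairs are sampled uniformly and scored

    score = clip(cos(c₁, c₂) + N(0, σ), floor, ceiling)

where c_i are the 7-class composition frequency vectors, σ = 0.05, and
floor/ceiling = 0.02/0.98. The Dirichlet spread is essential: sequences with
i.i.d.-uniform residues all have near-identical compositions, the pair
cosine then concentrates in ≈[0.88, 1.0], and the score carries no
recoverable signal. α = 0.5 spreads the cosine over most of (0, 1).
The planted signal deliberately reuses the same 7-class grouping as the
"eh" embedding so that encoder/head learnability can be tested without
depending on skip-gram pre-training.

Desk-scale defaults: 300 sequences of length 50–120, 3000 pairs, K = 5.
The corresponding training recipe is a reduced encoder (2 units, d′ = 16,
padded length 120, head hidden width 32) trained 50 epochs at batch 64,
learning rate 0.003 — sized so the whole recovery experiment (model plus
label-shuffled control) runs in minutes on one CPU. The benchmark criterion
is *parameter recovery*: the trained model's test MAE must be at most half
the MAE of an identically trained model whose training labels were shuffled
(the shuffled control collapses to the marginal label distribution, i.e. a
constant-rank predictor).

The skip-gram test bed plants co-occurrence instead: biased bigram
transitions make one symbol pair (A, G) adjacent far above chance while
another (A, W) never is; trained embeddings must rank cos(A, G) above
cos(A, W).

What these fixtures do **not** emulate: real protein evolution, domain
architecture, interaction biophysics, or the long-tailed length and
class-imbalance structure of STRING exports. Passing the synthetic benchmark
shows the architecture and training loop can extract a planted
composition-level signal at desk scale; it says nothing about accuracy on
real interactomes, which requires full-scale training (length-2000 padding,
5 units, d′ = 50, K = 20, ~10⁵ pairs).

## Numerical and design choices

* Sub-interval boundaries: left-closed (a score of exactly 0.05 with K = 20
  gets label 2); scores equal to cs_min or cs_max are rejected at I/O (the
  interval is open), not clamped.
* Decoding uses the sub-interval mid-point by default; the two endpoint
  decodes are exposed for comparison (`mid` minimises worst-case
  within-interval error and empirically minimises MAE/MSE).
* The convolution is affine as defined; no activation follows it —
  nonlinearity enters through the GRU gates and the heads' Leaky ReLU.
* The conv kernel is a width-d, in_dim-channel, d′-output-channel 1-D
  convolution — the only dimensionally coherent reading of a weight-sharing
  kernel applied to d consecutive embedding vectors.
* After a concatenate-merged unit the next convolution takes in_dim = 3·d′
  back to d′, restoring the width (150 → 50 under full-scale defaults).
* The final convolution reuses the unit kernel width and is followed
  directly by global average pooling (no n-max-pooling stage between them;
  the global average subsumes its reduction role).
* Stratified splitting assigns round(fraction·n) per label to training, with
  half-count ties rounded up into training; labels with fewer than two
  members go wholly to training with a warning.
* Duplicate pairs (same ids, either order) are kept as-is; the pair encoding
  is order-symmetric anyway.
* round-trip text serialisation of embedding tables keeps 9 significant
  digits; model checkpoints are NumPy archives with a format-version field,
  and loading rejects mismatched versions.

## Known limitations

* No masking of padded positions: embeddings of very short sequences are
  dominated by padding statistics. The fixed-length design assumes length
  filtering (50–2000) upstream.
* Pure-NumPy training is CPU-bound; the full-scale recipe is provided as
  configuration but is intended for much longer runs than the desk-scale
  demonstrations in this repository.
* The `--per-k` alternative (one independently trained network per
  sub-classifier) is not implemented; only joint training with a shared
  encoder is provided.
* Skip-gram negatives are drawn uniformly over the 20-symbol alphabet, not
  from a unigram^0.75 distribution; with a 20-symbol vocabulary the
  difference is minor.
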