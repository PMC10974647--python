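# Methods

This note documents the modeling choices, the synthetic data the package is
validated on, and the numerical details a user should know before trusting
or extending the results.

## Data model

A compound record carries a SMILES string, a physicochemical block of
exactly 1 Boolean + 5 integer + 7 float features, and 21 binary ADMET
outcomes. Rule-based drug-likeness filters (Lipinski, Ghose, Veber,
MDDR-like) may appear in input files but are excluded from the model
inputs: they are derived rules, not measurements, and correlate trivially
with the other descriptors. Records missing any input feature or label are
excluded outright rather than imputed — multi-task training with per-label
masking is supported by the loss implementation but not the default path.

Semantically redundant outcome pairs are merged before training:
intestinal absorption with Caco-2 permeability, the two
p-glycoprotein-inhibitor assays, and the two hERG assays. The combiner is
logical OR by default — positive if either source is positive — which is
the conservative choice for safety liabilities such as hERG block; AND and
first-source combiners are available per rule (`MergeRule(op=...)`). The
21 final label names ship as a documented default schema (CYP450
substrate/inhibitor panels, absorption and toxicity endpoints) and are
fully user-overridable; nothing in the code assumes the count 21 beyond
the schema's own length.

Numeric features are z-scored with mean and standard deviation estimated
on the training split only; Boolean features pass through untouched.
A zero-variance feature is a hard error (it cannot be standardized and
signals a degenerate split), detected with a relative tolerance of 1e-10
so that floating-point noise on a constant column still triggers it.

## Tokenizer

The SMILES tokenizer is plain byte-pair encoding over single characters:
merges are learned greedily by descending pair frequency, ties broken
lexicographically so retraining is byte-identical across platforms.
Multi-character atoms (`Cl`) are not special-cased; frequent ones are
learned as merges. Five special tokens (PAD, UNK, CLS, SEP, MASK) occupy
reserved ids 0–4. Encoding applies merges by learned rank, truncates the
tail keeping the SEP terminator, and pads at the tail only; characters
outside the training alphabet map to UNK, so unseen strings never crash.
Defaults (vocabulary 512, maximum length 128) are configuration, not
claims; the synthetic corpora saturate at roughly 150–300 tokens.

## Encoder and MLM pretraining

The encoder is a pre-norm transformer: learned token and position
embeddings, multi-head scaled-dot-product attention with an additive
padding mask, ReLU feed-forward blocks (the classical transformer
activation, chosen over GELU because it is markedly cheaper on CPU), and a
final layer norm. The published scale (4 layers, 8 heads, hidden size
H = 768) is the default configuration; tests and the acceptance script use
a desk-scale encoder (2 layers, 4 heads, H = 64, feed-forward 128, maximum
length 32) so the whole suite runs on one CPU in minutes. H is
configuration everywhere — outputs, checkpoints and fusion widths follow
it.

Pretraining is the RoBERTa masking recipe with the standard rates, which
the training protocol description leaves unstated: each non-special
position is selected independently with probability 0.15; selected
positions become MASK with probability 0.8, a random non-special token
with 0.1, and stay unchanged with 0.1. Cross-entropy is computed at
selected positions only. The molecule embedding is the CLS-position hidden
state by default, with masked mean pooling as an alternative — the choice
is exposed because nothing downstream depends on it structurally.
Checkpoints store the weights together with the encoder configuration and
a hash of the tokenizer vocabulary; loading against a different vocabulary
is a hard error.

Pretraining at desk scale uses learning rate 1e-3 (AdamW); the 5e-5
protocol rate belongs to fine-tuning and is far too small to move a
freshly initialized small model in ≤ 30 epochs.

## Fusion architectures

All six architectures share the output contract: 21 logits, sigmoid, one
probability per label.

- **dnn** — Boolean feature through a 2-row, 10-wide embedding table; the
  five integers and seven floats through separate affine maps to 10-d
  each; concatenation gives the 30-d fused vector; an affine head maps to
  21 logits. Normalized integers enter the affine map as reals (they are
  grouped with the floats, not embedded).
- **encoder** — pooled H-d vector, affine head. At H = 768 the head input
  is 768; the head output is 21.
- **concat** — [fused 30-d ‖ pooled H-d], i.e. 798-d at defaults, affine
  head to 21.
- **pipe** — the pooled vector first predicts the 13-feature physchem
  block (12 numeric regressions + 1 Boolean logit); those *predictions*
  feed the DNN trunk. The Boolean prediction enters the trunk as a soft
  mixture p·emb[1] + (1−p)·emb[0] of the embedding rows, keeping the whole
  pipe differentiable end-to-end. Training sums the stage-2 BCE with the
  stage-1 loss (MSE numeric + BCE Boolean) at weight 1:1, configurable;
  a stage-wise regime falls out of `freeze_encoder` plus the weight.
  The intermediate head size defaults to 13 — the size of the actual
  feature block — and is configurable.
- **dnn_a / pipe_a** — dot-product self-attention over the three 10-d
  group vectors treated as a length-3 sequence, with the group vectors
  themselves as query, key and value (no learned projections, so the
  attention adds no parameters); scores scaled by √d, softmax per query,
  tanh on the weighted sum. Attention weights are exposed on the trunk
  for inspection.

Following the protocol description, heads are plain affine stacks with no
hidden nonlinearity; tanh appears only inside the attention block. A
`head_depth`/`activation="relu"` switch adds capacity for users who want
it (the memorization test uses it). Depth-1 affine heads make dnn a
logistic regression on the fused representation — intentionally so.

The estimators follow scikit-learn conventions (get_params/set_params,
fitted attributes with trailing underscores, predict/predict_proba), so
they compose with sklearn model selection; `build_model(name)` maps the
six architecture names onto the four classes.

## Training protocol

Split 7 : 1.5 : 1.5 with sizes n_train = round(0.7 n),
n_val = floor(0.15 n), remainder to test — 700/150/150 at n = 1000 and
7/1/2 at n = 10. Batches of 32, AdamW (β = 0.9/0.999, weight decay 0.01),
summed per-label binary cross-entropy, early stopping when validation loss
has not strictly improved for 5 consecutive epochs, cap at 30 epochs,
best-validation weights restored after stopping. Replication re-fits with
independent seeds (5 by default) and reports test metrics as "mean (SD)"
strings like `82.3 (0.9)`. Weight initialization is fan-in uniform for
affine maps and small-Gaussian for embeddings, all drawn from
seed-controlled generators; a fixed seed reproduces the loss trace
bit-for-bit. Label imbalance is deliberately not reweighted — plain BCE.

## Evaluation

Metrics come from explicit confusion counts at threshold 0.5
(configurable). Ratios with zero denominators are reported as absent
(None), never as 0 — an all-negative prediction has undefined precision,
not perfect precision. AUROC is computed from average ranks, which equals
the Mann–Whitney concordance probability with ties counted half; the test
suite verifies exact agreement with an O(n²) pair-counting oracle and
with an independent library implementation.

The six-model ensemble binarizes each model at the threshold and takes the
majority; a 3 : 3 tie is resolved by the per-cell mean of the six
probabilities against the threshold. (The alternative reading of the
tie-break — pick the most confident model's call — is noted but not the
default; the per-cell mean is order-invariant and degenerates gracefully
to plain thresholding when all models agree.)

CYP450 substrate aggregation offers three methods: a small trained
synthesis network (one hidden layer of width 8, trained with the same
early-stopping protocol), taking the 3A4 probability directly (3A4 being
the dominant metabolizing enzyme), and abundance-weighted soft voting with
weights 0.12/0.04/0.30 for 2C9/2D6/3A4. The weights sum to 0.46, so the
soft-vote score is normalized by the weight sum to stay in [0, 1]; with
equal weights it reduces to the unweighted mean, and with a single
positive weight to a passthrough of that subtype.

## Synthetic data: what it emulates and what it does not

The generator emits grammar-valid SMILES — atoms C/N/O/S/F/Cl, balanced
branches, matched ring-bond digits, optional aromatic rings — not
chemically valid molecules; validity under the generator's own grammar is
the contract, which suffices to exercise tokenization and sequence models
without a cheminformatics dependency. Feature blocks are derived from
string composition: the five integer features are exact counts
(heteroatoms, ring pairs, branches, halogens, a length decile mapped onto
the schema's integer names), the seven floats are smooth functions of
composition plus Gaussian jitter, and the Boolean thresholds a composite
at its median.

Labels have a controllable signal source. *feature_driven*: each label is
Bernoulli(σ(w·z + b)) with per-label coefficients of norm 5 on the
standardized numeric features — a logistic ground truth whose Bayes AUROC
is ≈ 0.9 under the default 5% label-flip noise, so a correctly implemented
linear model can and should recover it. *structure_driven*: labels equal
the presence of a planted nitro-like motif `N(=O)=O`. The motif is
inserted after the feature-relevant composition is fixed and all features
are computed on the motif-stripped string, making the feature block blind
to it by construction; independence is also verified empirically
(point-biserial |r| < 0.05 over 5000 molecules) rather than assumed.
*mixed* splits the label vector between the two regimes.

Passing tests on this data therefore show that the architectures read the
input view they claim to read and that the training loop optimizes what it
claims to optimize. They do **not** show medicinal-chemistry realism: real
descriptor distributions, label correlation structure, activity cliffs and
assay noise are all absent, and no claim about real-compound performance
follows from the synthetic results.

## Problem sizes and numerics

The discrimination experiment uses 2000 molecules (1400/300/300 after
splitting), label noise 0.05, three replicate seeds, the desk-scale
encoder, learning rate 1e-3 and the protocol's batch size, patience and
epoch cap; MLM checks use a 5000-molecule corpus for 3 epochs. These sizes
were chosen as the smallest at which the planted effects are
unambiguous — the feature-only DNN stays near chance AUROC on
structure-driven labels while encoder and concat exceed 0.9, and the DNN
reaches ≈ 0.89 on feature-driven labels.

All network arithmetic is float32; the autodiff engine preserves float64
when fed float64 (the gradient tests rely on this). Losses are computed in
numerically stable forms (softplus-based BCE, max-shifted softmax), and
sigmoids use the split positive/negative form to avoid overflow. A
non-finite loss aborts training with a diagnostic rather than continuing.
Dropout draws from its own seeded stream and is disabled in evaluation
mode, so embeddings and validation losses are deterministic; checkpoints
round-trip bitwise.

## Known limitations

- The numpy training stack is single-threaded and CPU-bound; the published
  H = 768 scale is configurable and structurally verified but not trained
  in the test suite.
- WordPiece tokenization and replaced-token-detection pretraining are out
  of scope; the encoder interface (ids + attention mask in, hidden states
  out) does not preclude adding them.
- The pipe intermediate head predicts the 13 input features; sources that
  quote a larger intermediate physchem panel can set `pipe_head_size`.
- Per-label missingness masks exist in the loss but the default data path
  excludes incomplete records instead.
- The synthesis-network CYP aggregator requires reference substrate labels
  to train; without them use the abundance-weighted soft vote.
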