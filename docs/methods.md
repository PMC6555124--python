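# Methods

## Problem and model

`venuerec` treats venue recommendation as flat multiclass text
classification: given only an abstract, predict a probability distribution
over the T journals present in the training corpus and present the top N
as the recommendation list. The underlying assumptions are (i) an
abstract's vocabulary and phrasing carry enough signal to identify the
venue's scope, (ii) the journal set is closed at training time — a new
journal requires retraining, and (iii) the label is the catalog identity
of the journal (a LocatorPlus-style unique ID), so a journal's print and
electronic ISSNs are the same class.

The classifier is a three-stage 1-D convolutional network over the
token-vector matrix:

1. **Input.** Tokens are encoded to ids, padded or tail-truncated to
   m tokens, and mapped through a k-dimensional embedding matrix. Row 0 of
   the embedding is pinned to zero and serves both padding and
   out-of-vocabulary tokens; this follows the rule that words outside the
   pretrained vocabulary are initialised to zero vectors. The id space
   makes the two indistinguishable downstream by design — both contribute
   nothing to the convolution.
2. **Convolution stack.** Stage t applies r_t valid (no padding)
   convolutions of window h_t spanning all input channels, then ReLU, then
   max-pooling with window 2 and stride 2. Stage-1 kernels have shape
   k x h_1; stage-2/3 kernels span the previous stage's r channels. A
   trailing unpaired element of an odd-length map is dropped (floor), so
   the default geometry is 350 -> (348, 174) -> (171, 85) -> (81, 40).
3. **Head.** The stage-3 output is flattened (96 x 40 = 3840 features by
   default; a `global_max_pool` flag reduces it to r_3 = 96 — the choice
   between the two conventions is genuinely open and the flattened variant
   is the default because it preserves positional information) and passed
   through two fully connected ReLU layers with dropout, then a T-way
   softmax. The head weights initialise to zero so an untrained model
   predicts the uniform distribution and the initial loss is ln T — a
   useful training diagnostic.
4. **Objective.** Cross-entropy against the one-hot label plus an L2
   penalty `lambda * sum(w^2)` over convolution and dense weights (biases
   and embeddings excluded), minimised by Adam (beta1 0.9, beta2 0.999,
   eps 1e-8). Embeddings are fine-tuned by default
   (`trainable_embeddings=False` freezes them); whether the original
   system froze its pretrained vectors is not documented, and fine-tuning
   is the stronger default when the embedding is randomly initialised.

## Parameters

| parameter | default | notes |
| --- | --- | --- |
| m (sequence length, tokens) | 350 | covers ~95% of biomedical abstracts; longer ones are tail-truncated |
| k (vector dimension) | 200 | matches widely used pretrained biomedical word2vec tables |
| conv stages (count, window) | (256,3), (128,4), (96,5) | phrase-, sentence-, abstract-level features |
| pool window / stride | 2 / 2 | fixed; other values are not supported |
| dropout rate | 0.2 | applied to the two dense hidden layers, training only |
| L2 coefficient | 1e-4 | not pinned by the reference description; surfaced in `ModelConfig` |
| hidden widths | 512, 256 | likewise unspecified upstream; surfaced, not hard-coded |
| Adam learning rate | 1e-3 | conventional default |
| batch size | 64 | |
| skip-gram window / subsample threshold | 5 / 1e-3 | hierarchical-softmax training |
| abstract filter | 200 characters | counted after collapsing whitespace runs to single spaces |
| journal filter | 100 papers | applied once, after the abstract-level filters |
| date window | 2007-01 .. 2017-04 inclusive | month precision; a missing month reads as January |
| size bins | 100-400 / 400-2000 / 2000-10,000 / >10,000 | on training-corpus paper counts |

## Corpus curation semantics

Paper-level filters (abstract length, publication window) run first; the
journal-size filter then runs once on the surviving counts. The
interaction is deliberate: a journal with 105 papers of which 10 have
short abstracts drops to 95 and is removed entirely. No fixpoint iteration
is performed — one pass matches the stated order of operations, and
re-running the filter on its own output is a no-op (idempotence is
tested). Every removal is logged with a machine-readable reason, making
`kept + rejected = input` checkable. Papers whose ISSNs are absent from
the journal list are rejected with reason `no_issn`; how such papers were
originally handled is undocumented, and rejecting keeps the catalog an
exact inverse of the label set.

## Evaluation conventions

At cutoff N every label in the first N ranked positions counts as
predicted. Per class: tp = true members recovered in top-N, fn = true
members missed, fp = foreign samples whose top-N contains the class,
tn = remainder. Macro metrics are unweighted means of the per-class
precision, recall and F1; micro metrics come from the summed counts. With
one label per sample, micro precision = micro recall = micro F1 = accuracy
at N = 1 (each sample contributes exactly one predicted label); at N > 1
micro precision is bounded above by 1/N under this convention — published
tables whose micro precision at N > 1 exceeds that bound use some other,
undocumented fp convention, so no attempt is made to match them. A
precision or recall whose denominator is empty is defined as 0. Stratified
accuracy groups test samples by the TRUE journal's size bin, binned on
training-corpus counts; the bin-weighted mean accuracy must reproduce the
overall correct count exactly (a partition identity, asserted in tests).

Ties in the ranking are broken by ascending journal label — a stable,
documented total order, so recommendation lists are identical across runs.

## Synthetic corpus generator

The generator is the package's study instrument, not a test double. Each
synthetic journal owns a private slice of the vocabulary; a document of
class c draws each word from c's slice with probability `topic_sharpness`
and from a shared pool otherwise. Document lengths are drawn from
word-count bins shaped like a real abstract corpus (probabilities
proportional to 25,499 / 76,614 / 139,420 / 227,993 / 191,156 / 87,597 /
46,275 / 43,328 across the bins 20-50 up to 350-400), so padding and
truncation are both exercised at their real rates. A unigram mixture was
chosen over a topic model because it keeps the Bayes-optimal baseline
analytic: at sharpness 1 the class supports are disjoint and majority
vocabulary membership classifies perfectly, which upper-bounds what the
network should approach. Synthetic ISSNs carry valid mod-11 check digits
and each journal has distinct print/electronic ISSNs, so catalog
unification runs on realistic identifiers.

What the generator does **not** emulate: natural language structure (word
order within a document is exchangeable), topic overlap between related
venues beyond the single shared pool, scope drift over time, and
multi-disciplinary mega-journal heterogeneity. Passing tests therefore
demonstrate that the pipeline's machinery is correct and that the network
can exploit lexical signal at realistic length and imbalance profiles —
not that it reaches any particular accuracy on real submissions.

The imbalanced preset uses six journals with 120 / 300 / 700 / 1500 /
2600 / 10,400 papers — one to two classes per size bin, ~15,600 documents.
Class sizes must genuinely span the bins (tiny needs >= 100, large needs
> 10,000), which sets the preset's scale.

## Numerical choices

- Softmax subtracts the row maximum before exponentiation; the loss clamps
  probabilities at 1e-300 before the log. Probabilities are asserted to
  sum to 1 within 1e-6 even for scores of magnitude 1e300.
- Convolution is im2col + GEMM; the backward pass re-folds window
  gradients with an explicit loop over the (small) window size. Training
  is single-threaded numpy and bit-reproducible for a fixed seed; dropout
  masks and the epoch shuffle come from one generator seeded from
  `config.seed`.
- Training aborts with a diagnostic if the loss becomes non-finite.
- Stage geometry is validated eagerly: a configuration whose convolved
  length is non-positive, or too short to pool (length < 2), is rejected
  naming the offending stage.
- Skip-gram uses a Huffman-coded hierarchical softmax with logits clipped
  to ±16 inside the sigmoid, single-worker and seeded; it is intended for
  the modest corpora used in testing and for small research corpora, with
  large-corpus vectors expected to arrive via the word2vec reader.

## Problem sizes in tests and the acceptance script

Test and acceptance runs scale the *geometry* down (m = 100-128,
k = 24-32, 16-32 kernels per stage, hidden 64-128) while keeping the data
conditions fixed: the separable condition uses 20 journals x 100
abstracts at sharpness 0.9 with an 80/10/10 split; the capacity condition
uses 5 x 40 at sharpness 1.0; the imbalance condition uses the preset
above. Training runs to convergence with an early stop at 99.5% training
accuracy, capped at 20 epochs (200 for the capacity test). The reference
geometry itself is exercised structurally (layer-length plan, 3840-feature
head, 350 x 200 input matrix) rather than trained.

## Known limitations

- The journal set is closed; unseen journals at prediction time are
  unrepresentable rather than poorly ranked.
- No class re-weighting by default — the raw imbalanced corpus is trained
  as-is, matching the reference protocol; `class_weighting =
  "inverse_frequency"` is available as an extension.
- The tokenizer is a deterministic regex segmenter (words keep internal
  hyphens/apostrophes; other punctuation splits off). It is pinned by
  golden tests; swapping in another segmenter changes vocabularies and
  requires retraining.
- The checkpoint format stores weights with full config and a vocabulary
  digest, but no optimizer state: training cannot resume mid-run.
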