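# Methods

## The model

The tagger assigns one label per token with a stack of bidirectional
LSTM layers. The generic recurrent step `h_t = H(U x_t + W h_{t−1} + b)`
is realised by the standard LSTM cell — input/forget/output gates with
logistic activations and a tanh candidate — with `U`, `W`, `b`
interpreted as the gate-stacked parameter blocks `(D, 4H)`, `(H, 4H)`,
`(4H,)`. Initial hidden and cell states are zero in both directions.

Within each sentence-level bidirectional layer the forward and backward
states are combined by **element-wise sum**, which forces equal hidden
sizes in the two directions. Concatenation is the commoner convention
and would double the downstream width; the sum is the formulation this
architecture prescribes, and we keep it everywhere except the character
encoder, where a word is summarised by the **concatenation** of the
final forward and final backward states — the word-vector definition is
explicitly a concatenation of word embedding and character embedding.

Full architecture, per token:

| stage | size (reference / desk) |
| --- | --- |
| word embedding | 100 / 24 |
| character embedding → char BiLSTM | 50 → 150 cells / 12 → 16 |
| transferred layer (BiLSTM) | 300 / 32 |
| shared layer (BiLSTM) | 300 / 32 |
| POS layer and NER layer (BiLSTM each) | 300 / 32 |
| per-task affine projection + softmax | label-set size |

Dropout (rate 0.5, inverted scaling) is applied to every recurrent
layer's output during training only. Embedding dimensions are
conventional choices; the recurrent sizes in the reference column are
the published configuration. The desk column is the reduced
configuration (`medtagger.experiments.desk_model_config`, float32) used
for the seeded experiments so that a full ablation fits in CPU minutes;
variants are always compared under one shared configuration, so the
mechanism comparison does not depend on the absolute sizes.

## Two-phase training

**Phase 1** trains embeddings + one bidirectional layer + a softmax head
on the general-domain corpus (NER labels by default; POS is available —
the source task is configurable because either choice yields a valid
transferable layer). The layer's `U`/`W` blocks, the embedding tables
and the vocabulary are packed into a `TransferPackage`.

**Phase 2** builds the full model on the target vocabulary and sets the
transferred layer's `U`/`W` blocks equal to the package values, both
directions, element-wise. The printed transfer rule covers only `U` and
`W`, so biases keep their random initialisation by default; the package
carries the biases anyway and `transfer_biases=True` copies them too,
which makes the transferred layer reproduce Phase-1 outputs exactly —
that switch is what the transfer-identity test exercises, while the
default path is checked for `U`/`W`-only assignment. Optionally
(`copy_embeddings`, default on) word/character vectors for items shared
with the Phase-1 vocabulary are copied as well; the target vocabulary
itself is built from the target corpus only, so all ablation variants
see identical input encodings.

Fine-tuning strictly alternates minibatches between the POS and NER
objectives — for each batch, a POS update then an NER update — so the
two update counts are equal over any epoch. Each objective is mean
per-token cross-entropy under its own softmax head; the transferred and
shared layers (and embeddings) receive gradients from both. Each task
keeps a separate Adam state (β₁ = 0.9, β₂ = 0.999, ε = 1e-8); the
learning rate starts at 0.01 and is multiplied by 0.9 after every epoch
(the conventional reading of a per-epoch decay of 0.9). The reference
budget is 100 epochs with minibatch 50 (10 for smaller,
progress-note-like workloads); no early stopping by default, though a
validation-patience option exists. Sentences are bucketed by length
before batching; padded positions pass recurrent states through
unchanged and are masked out of losses and metrics.

## Synthetic study conditions

The generator emulates the transfer/multitask setting without any
private data: a **general** corpus of 5,000 sentences and a **target**
corpus of 500, sharing 70 % of their background vocabulary
(~2,000 words over seven POS classes) and of their per-type entity
phrase lexicons (~40 phrases per type). Sentences (5–25 tokens) are
drawn template → slot-fill → tag; POS tags are a deterministic function
of word class, making the auxiliary task learnable; entity mentions span
1–4 tokens with probabilities 0.4/0.3/0.2/0.1, and mention types follow
fixed weights with *disease group* deliberately rare (~2 %), mirroring
the hardest class in real clinical evaluations. Word forms are syllable
strings with class- and type-specific suffixes, so the character channel
carries usable signal. One RNG stream per corpus is derived from the
master seed; identical seeds give identical corpora.

What the generator does **not** emulate: real orthography (Chinese or
otherwise), section structure of medical records, annotation noise and
disagreement, nested or discontinuous mentions, and genuinely ambiguous
POS. Passing tests therefore demonstrate that the machinery — transfer
initialisation, alternating optimisation, span scoring — behaves as
specified and that the expected qualitative orderings emerge under
controlled conditions; they do not predict absolute scores on real EMR
text.

## Evaluation conventions

* Micro P/R/F pool confusion counts over **all** token classes
  including `O`; with one label per token this forces P = R = F (token
  accuracy), which is why comparison tables repeat one value per model.
  An entity-classes-only pooling is available behind a flag. F is
  computed from raw counts (`200·TP / (2TP+FP+FN)`), which keeps the
  identity exact in floating point.
* Span scoring is exact-match on (type, sentence, span); macro values
  are unweighted means over the types present; types with no gold and no
  predicted mentions are excluded.
* Entity accuracy is matched gold mentions ÷ gold mentions (per type and
  overall): a recall-style exact-match rate, by its verbatim definition;
  spurious predictions affect precision but not accuracy. Types with no
  gold mentions report N/A.
* Precision with an empty prediction set is 0, not an error. Rounding is
  half-up to 2 decimals and happens only at rendering time.
* BIO is assumed (the annotation scheme is otherwise unspecified), with
  the conlleval leniency: a dangling `I-t` opens a mention as `B-t`.
  Spans are 0-based, half-open.

## Numerical choices

* Default arithmetic is float64; desk experiments use float32. Analytic
  gradients of every block are tested against central finite differences
  (float64, tolerance 1e-4 relative).
* Glorot-uniform initialisation for weight matrices, zero biases with
  forget-gate bias 1, embeddings uniform at scale √(3/d); all draws from
  one seeded generator, so identical seeds give bit-identical models,
  packages and final metrics.
* Checkpoints and transfer packages serialise every parameter block plus
  configuration and a vocabulary fingerprint into one `.npz` archive and
  round-trip bit-exactly; a fingerprint mismatch on load is an error.

## Experiment sizes

The seeded experiments (`medtagger.experiments`, also driven by
`scripts/acceptance.py` and the heavier tests) use the generator
defaults above with an 80/20 target train/test split, the desk network,
Phase 1 for 3 epochs, fine-tuning for 30 epochs, minibatch 50. The
ablation compares variants on median held-out NER micro-F across seeded
replicates; the learning-rate sweep reuses each seed's Phase-1 package
(trained at lr 0.01) and varies only the fine-tuning rate, isolating the
schedule. Under these conditions transfer + multitask (TMBRNN) clearly
outperforms the single-task baseline, and lr 0.0001 underperforms
lr 0.01 at a fixed 30-epoch budget — the expected qualitative orderings.

## Known limitations

* The softmax output is token-independent; no CRF transition layer, so
  predicted BIO sequences can be locally inconsistent (decoding repairs
  them leniently).
* Joint-loss optimisation of the two tasks is out of scope (the
  procedure alternates two losses by design).
* The alternation granularity ("trained alternately") is interpreted as
  per-minibatch; other granularities (per epoch) are plausible readings.
* Whether the shared layer should also receive Phase-1 weights is left
  open; only the first layer is transferred here.
* Pretrained word2vec tables can be loaded through the textual reader
  hook, but embeddings are trained from scratch by default and are
  always trainable.
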