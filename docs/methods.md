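# Methods

## Problem and approach

`chemner` locates chemical-name mentions in title/abstract records and
returns exact character spans with confidence scores.  It implements two
complementary sequence taggers over the SOBIE (BIOES) tag scheme — Single,
Outside, Begin, Inside, End — plus a span decoder, an ensemble combiner and
transfer-learning schedules:

* **Token-level ("traditional") tagger.**  Text is tokenised with a
  chemistry-aware rule set; each token carries a word-embedding index and an
  engineered feature vector.  The network embeds tokens (300-wide by
  default, initialised from a GloVe-format file where coverage exists and
  zeros elsewhere, trainable), convolves the feature vectors over the token
  axis (width 3, 256 relu filters, dropout 0.5), concatenates the two
  streams (556 wide at the defaults), and applies a bidirectional LSTM
  (64 units per direction, dropout 0.5) and a per-token 5-way softmax.
* **Character-level ("minimalist") tagger.**  No tokeniser and no feature
  engineering: characters are encoded against a fixed 90-character
  inventory plus an unknown index, embedded (64-wide lookup), passed through
  a forward LSTM (128) and a reversed LSTM (128) whose outputs are
  concatenated with dropout 0.5, then two stacked bidirectional LSTMs
  (64/direction, dropout 0.5 each) and a per-character 5-way softmax.
  Because labels are per character, spans may begin or end inside what a
  tokeniser would call one token.

Both are trained with RMSProp (lr 1e-3, rho 0.9) on categorical
cross-entropy, in mini-batches of equal-length sequences (so no padding or
masking exists anywhere), checkpointing each epoch and keeping the epoch
with the best held-out strict F decoded at threshold 0.5.  The token model
trains 20 epochs; the character model 30, with the first 4 epochs visiting
length groups shortest-first (length curriculum).  An optional flag enables
recurrent dropout 0.5 inside the LSTMs, reproducing the slower CPU-era
configuration; the default is off.

### Neural engine

No deep-learning framework is used: `chemner.nn` is a compact NumPy engine
implementing exactly the layers these models need (embedding, same-padded
Conv1D, LSTM with input/recurrent dropout, bidirectional wrapper,
time-distributed dense, global max pooling) with manual backpropagation and
RMSProp.  Analytic gradients of every layer are verified against central
differences (float64) in the test suite.  Dropout uses one mask per
sequence shared across timesteps, the usual recurrent-network convention.
LSTM gates follow the i, f, g, o layout with forget-gate bias 1, Glorot
input kernels and orthogonal recurrent kernels.

## Feature engineering (token model)

Per token the network receives, besides the embedding index:

* a **preclassifier score**: a 100-tree random forest (scikit-learn)
  trained on *token types* that are only ever tagged O or only ever tagged
  S/B/I/E (ambiguous types are excluded), over the 1000 binary features —
  word shapes, boundary-marked character 1–4-grams, regex and lexicon
  tests — with the highest plug-in mutual information against that label.
  Scores for training types come from a 5-fold cross-scoring scheme (each
  fold scored by a forest that never saw it); unseen tokens are scored by
  the forest trained on all types.
* three **character-class counts** (non-lowercase, non-letter, digit);
* one bit per **lexicon** (chemical names, element names, English words)
  and per **regular expression** (formula-like, contains-digit, all-caps,
  internal hyphen, common chemical suffix, CAS-number-like; the list is
  configurable — the feature is representative, not canonical);
* presence bits for the **100 most common** features among 2-/3-character
  suffixes and word shapes, counted over all training token instances.

The vocabulary keeps tokens occurring **more than twice** in the training
corpus; everything else shares one unknown row, initialised to zeros.  On
training data only, tokens are split where a gold entity boundary falls
inside them, so SOBIE tags always align with token boundaries; inference
never uses gold information.

## Decoding, ensembling, overlaps

A span [i, j] scores `S[i]` if single-position, else
`min(B[i], I[i+1..j-1], E[j])`; spans scoring strictly above 0.5 become
entities with that score.  The search prunes with the prefix running
minimum `min(B[i], interior I)`, which never increases as the span extends;
pruning is proven output-equivalent to full enumeration by an oracle test.
(Note the span *score* itself is not monotone under extension — the E term
moves — only the running prefix is.)

For the ensemble, both systems run at a lowered component threshold (0.2 by
default); a span found by both systems scores the average of its two
scores, a span found by one scores half its single score, and a final
threshold of 0.475 applies.  The low final threshold lets a strong
single-system span — e.g. one starting mid-token, invisible to the token
model — survive.  Overlaps are resolved greedily by descending score
(earlier start, then longer span on ties).  All thresholds compare
strictly (">").

## Transfer learning (character model)

Two auxiliary tasks share layer objects with the main network, so every
auxiliary step updates the very parameters main training continues from:

* **Predictive transfer**: a character language model — the forward LSTM
  feeds a 91-way softmax predicting the next character, the reversed LSTM
  one predicting the previous character.  Targets are the input sequence
  shifted by one; boundary positions carry an all-zero padding row excluded
  from the loss.  The corpus (one title/abstract per line) is used once.
* **Dictionary transfer**: whole words from the chemical/element/English
  lists run through the full recurrent stack, max-pool over positions, and
  a 3-way sigmoid head predicts list membership (binary cross-entropy).
  Each word is used once.

Each task runs either entirely before main training ("at start") or
alternating with it one mini-batch at a time ("interleaved", 1:1 ratio)
until its data is exhausted; when both run at start, predictive-first,
dictionary-first and mutually-interleaved orderings are supported — 11
combinations in total.  Interleaving exists because dictionary pre-training
alone can *worsen* the main task (negative transfer); alternating it with
main-task batches, and combining it with predictive transfer, mitigates
that.  Every run records a step log (one entry per mini-batch) so schedules
are auditable and reproducible given a seed.

## Synthetic data

The generator emits every artifact the pipeline consumes: documents with
exact gold offsets, lexicons, a transfer-text corpus and a small embedding
file.  Chemical-like names follow a morpheme grammar
(optional multiplier + stems + suffix, e.g. "dichlorethane") or a
formula-like branch ("C6H12O6"); fillers are common procedural English.
Names are separable from fillers chiefly by suffix statistics, so
desk-scale models converge in minutes.  Defaults: 1.5 entities per abstract
sentence, one sentence per abstract, 30 % of titles carry an entity, 20 %
of names take the formula branch.  A few filler words are planted in the
chemical lexicon and a few names occasionally appear unannotated, so the
preclassifier's ambiguous-type exclusion is exercised.

What the generator does **not** emulate: real patent syntax and length,
nested or discontinuous mentions, annotation noise, OCR artifacts, and the
long-tail morphology of real chemical nomenclature.  Passing tests
therefore demonstrate that the machinery is correct and that the
architecture can learn this class of pattern — not that it reaches any
particular accuracy on real corpora.

## Problem sizes and numerical choices

* Learnability runs train the character model on 2,000 synthetic documents
  (400 held out) for 8 epochs — on this grammar held-out F typically
  saturates near 1.0 by epoch 6–8.  The transfer comparison uses the
  reduced 200-document setting with the model's standard 30-epoch regime.
* Mini-batch size defaults to 32.  Equal-length grouping makes batch
  composition deterministic given the seed.
* All probability rows sum to 1 within 1e-5 (softmax in float32); the
  decoder validates this on construction.
* Ties: best-epoch selection keeps the earliest best; MI ranking breaks
  ties by feature id; max pooling takes the first argmax; overlap removal
  prefers earlier, then longer spans.
* Degenerate inputs: empty fields are skipped; an empty training or
  held-out set, a single-class preclassifier input, and misaligned entity
  boundaries raise errors naming the offending item.
* Character inputs longer than `max_len` (default 2000) are chunked at
  whitespace and the per-chunk probability matrices are concatenated;
  spans crossing a chunk boundary are not recoverable (rare at these
  lengths).

## Design choices where the design was open

* Offsets are 0-based, half-open, in Unicode code points; titles and
  abstracts are separate fields so offsets never span them.
* The tokeniser's rule set (whitespace split, edge punctuation detachment,
  internal hyphens kept, standalone =/+/→ split out) is declared and
  versioned here rather than imported, so tests are stable.
* Embedding lookup tries the exact token then its lowercased form before
  falling back to zeros, maximising pretrained coverage.
* Model selection F is entity-level (decoded at 0.5), matching final
  inference rather than tag accuracy.
* The 90-character inventory and the 64-wide character embedding are
  configurable and serialised with the model so encoding is stable.
* Dictionary transfer makes one pass over the word list; the interleaving
  ratio is 1:1.

## Known limitations

Single entity type; no nested or overlapping output; no CRF/Viterbi
decoding; CPU-only NumPy training (fine at desk scale, not at corpus
scale); the regex feature list and character inventory are representative
stand-ins, configurable per deployment.
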