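# chemner

Chemical named-entity recognition with recurrent neural taggers: find
chemical-name mentions in titles and abstracts and return exact character
spans with confidence scores.  Intended for text-mining practitioners in
cheminformatics who need a trainable span extractor for patent-style or
journal-style text, and for method work on sequence-labelling itself
(span decoding, ensembling, transfer-learning schedules).

## What it implements

Text is labelled with **SOBIE** tags (Single / Outside / Begin / Inside /
End) by one of two systems:

* a **token-level tagger** — chemistry-aware tokenisation; per-token
  features (random-forest preclassifier score, character-class counts,
  lexicon/regex bits, common suffix/shape bits) convolved (width 3, 256
  filters) and concatenated with 300-dimensional word embeddings (556 wide
  in total), into a bidirectional LSTM (64 units/direction) and a per-token
  5-way softmax;
* a **character-level tagger** — no tokeniser, no features: characters from
  a 90+1-symbol inventory feed a forward and a reversed LSTM (128 each,
  concatenated), two stacked BiLSTMs (64/direction) and a per-character
  5-way softmax, so entities may start or end mid-token.

A decoder scores every candidate span [i, j] as

    score(i, j) = S_i                      if i = j
    score(i, j) = min(B_i, I_{i+1..j-1}, E_j)   otherwise

and keeps spans with score > 0.5.  An **ensemble** runs both systems at a
lowered threshold, averages scores for spans found by both, halves scores of
single-system spans, and applies a final threshold of 0.475; overlaps are
resolved by keeping higher-scoring spans.  The character tagger can be
pre-trained or co-trained on two auxiliary tasks — a character language
model ("predictive transfer") and word-list membership ("dictionary
transfer") — under 11 scheduling combinations, including mini-batch
interleaving with the main task, which mitigates negative transfer.

Everything trains with RMSProp on categorical cross-entropy in mini-batches
of equal-length sequences, keeping the epoch with the best held-out strict
span-level F.  The recurrent layers are implemented in NumPy with manual
backpropagation (`chemner.nn`), gradient-checked in the test suite.  A
deterministic synthetic-corpus generator provides documents, gold offsets,
lexicons, transfer text and toy embeddings so the full pipeline runs
without downloads.  See `docs/methods.md` for details.

## Worked example

```python
from chemner import MinimalistConfig, MinimalistTagger, generate_corpus
from chemner.synthetic import GeneratorParams

corpus = generate_corpus(GeneratorParams(n_documents=2400, seed=5))
train, heldout = corpus.documents[:2000], corpus.documents[2000:]

tagger = MinimalistTagger(MinimalistConfig(epochs=8, seed=7))
result = tagger.fit(train, heldout, corpus.entities)
print(f"best epoch {result.best_epoch}, held-out F {result.best_f:.3f}")

pred = tagger.predict(heldout[:2])
for e in pred:
    print(e.doc_id, e.field, e.start, e.end, e.text, round(e.score, 3))
```

prints (about two minutes on one CPU):

```
best epoch 7, held-out F 1.000
SYN02000 A 4 15 pentpentide 0.996
SYN02000 A 34 38 Zn5S 0.998
SYN02001 A 0 11 pentoxaline 0.982
SYN02001 A 25 32 glycide 0.999
SYN02001 A 41 53 dipenthexide 0.998
```

`best epoch` is the checkpoint with the highest strict span-level F on the
400 held-out documents (decoded at threshold 0.5); each prediction line is
a document id, field (T = title, A = abstract), 0-based half-open character
offsets, the matched text and the decoder's min-over-tags span score.
F = 1.0 reflects the deliberately learnable synthetic grammar, not expected
real-corpus accuracy.

The same pipeline is available from the shell:

```sh
chemner synth --outdir corpus --n-documents 400 --seed 3
chemner train --model minimalist --docs corpus/documents.tsv \
    --annotations corpus/annotations.tsv --outdir model --epochs 8
chemner tag  --model-dir model --docs corpus/documents.tsv --out pred.tsv
chemner eval --docs corpus/documents.tsv --gold corpus/annotations.tsv \
    --pred pred.tsv
```

## Data formats

* documents: TSV `doc_id<TAB>title<TAB>abstract` (UTF-8)
* annotations/predictions: TSV
  `doc_id<TAB>field<TAB>start<TAB>end<TAB>text<TAB>score`, `field` ∈ {T, A},
  offsets 0-based half-open in code points
* embeddings: GloVe-style plain text, `word v1 ... vd` per line
* lexicons: one term per line; transfer corpus: one title/abstract per line
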