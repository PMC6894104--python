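# Methods

## Problem and model

`phitag` treats de-identification of clinical notes as BIO sequence
labeling over ten PHI categories (DATE, NAME, AGE, ID, PHONE, WEB,
INSTITUTE, STREET, CITY, ZIP). The tagger is a BiLSTM-CRF:

1. **Character BiLSTM.** Each token's characters are embedded
   (`char_dim`, default 25) and read by a forward and a backward LSTM
   (`char_lstm_out` per direction, default 25); the two final hidden
   states summarize spelling and shape cues that survive out-of-vocabulary
   words (phone layouts, ID patterns, capitalization).
2. **Feature embedding layer.** Categorical per-token feature streams are
   each embedded in a small dense table and concatenated with the word and
   character representations: part of speech and word shape at
   `lexical_feat_dim` (default 15) each, and the gazetteer-lookup result at
   `semantic_feat_dim` (default 20). With the default "composite" wiring
   the lookup triple (category, BIO boundary within the match, exact vs
   partial condition) is one stream, giving a per-token input width of
   300 + 2x25 + 20 + 15 + 15 = 400; the alternative "separate" wiring
   embeds the category and the boundary:condition pair as two streams.
   Disabling both feature groups reduces the model to a plain word+char
   BiLSTM-CRF of width 350 — the ablation tier structure of the model
   comparison.
3. **Word BiLSTM and CRF.** The concatenation (dropout 0.5 on this input
   during training) feeds a word-level BiLSTM (`word_lstm_out` per
   direction, default 100), a linear projection to per-tag emission
   scores, and a linear-chain CRF over the 21-tag BIO inventory.

The CRF layer is exact: log-likelihood by the forward algorithm in log
space, gradients from forward-backward marginals, decoding by Viterbi.
The Viterbi max-score recursion runs from the end of the sentence so the
path can be built front-to-back, taking the smallest tag index among
optimal continuations — under exact ties this yields the
lexicographically smallest optimal path, which makes decoding fully
deterministic and testable against enumeration. Transitions are
unconstrained (no hard BIO mask); rare invalid transitions are repaired
downstream when BIO runs are collapsed to spans (an orphan `I-X` is
promoted to `B-X`).

All neural components are implemented directly on numpy arrays with
hand-derived backward passes (LSTM backpropagation through time, CRF
forward-backward). At the model sizes this package targets, per-sentence
numpy steps are fast enough that no accelerator framework is needed, and
the closed-form gradients are themselves tested against finite
differences.

## Optimization

Pure SGD — one sentence per step — with momentum 0.9, learning rate
0.005, per-sentence elementwise gradient clipping to [-5, 5], and dropout
only at training time. Training runs a fixed number of epochs with no
early stopping: 30 from scratch, 15 for fine-tuning. Weights are
initialized uniformly scaled by fan-in from the run seed; the LSTM forget
gate bias starts at 1. Word embeddings are trainable rows; when a
pretrained vector file is supplied its rows initialize the table
(exact-form lookup, then case-folded, then the UNKNOWN row). Everything
random — initialization, epoch shuffling, dropout masks — derives from
the single `seed` parameter, so identical seeds give bit-identical
checkpoints. Momentum buffers are not carried across `fit`/`fine_tune`
calls; fine-tuning restarts the optimizer on the pretrained weights,
which keeps checkpoints small and is standard practice.

A training step that produces a non-finite loss aborts with a
diagnostic rather than silently continuing.

## Fine-tuning and corpus merging

Two customization regimes for a new institution are built in.
`merge_corpora(a, b)` concatenates corpora (suffixing colliding document
ids) for retraining from scratch; `fine_tune(docs)` continues training an
existing model's weights. Fine-tuning extends the word/character/feature
vocabularies with freshly initialized rows for unseen values; the tag
inventory is always the full 21-tag BIO set over the ten categories, so a
fine-tuning corpus that lacks rare categories is never rejected, while
genuinely alien labels raise an error listing the symmetric difference.

## Preprocessing

The dominant typographic error in clinical text is the run-together word
("prnInsulin"). `correct_typos` inserts a space at each
lowercase-to-uppercase transition whose flanking alphabetic runs both
have length >= 2 and at least one of which is in a configurable known-word
lexicon; the gate keeps genuine camel-case names ("McDonald") intact.
Because the text is edited, every operation carries an `OffsetMap`
(piecewise monotone, total, corrected -> original offsets) and all
annotations remain in original-text coordinates end to end.

Sentence splitting breaks on newlines (clinical notes are line-oriented)
and on sentence-final punctuation followed by whitespace; the tokenizer
is deliberately aggressive — letter runs, digit runs, single punctuation
marks — because PHIs such as phone numbers and IDs are punctuation-laced
and finer tokens give the CRF cleaner boundaries. When a span edge falls
inside a token the whole token is labeled (boundary snapping): a
de-identification system should over-mask, never leak.

The sentence splitter and tokenizer are documented conventions of this
package, not reconstructions of any particular system.

## Knowledge features and fuzzy lookup

Gazetteers (one case-folded entry per line; bundled sets for first/last
names, provider names, cities, institutes, zip codes) are scanned for
longest leftmost matches. EXACT means case-insensitive token equality.
PARTIAL means either (a) per-token optimal-string-alignment
(Damerau-Levenshtein) distance <= 1, applied only to tokens of length
>= 5 so that short forms never fuzzy-match, or (b) an exact strict prefix
covering at least half the words of a multi-word entry. Competing matches
are resolved by dictionary priority rank, then longer match, then exact
before partial. Zip-code dictionaries are exact-only: edit distance on
5-digit strings would manufacture false partials. With no dictionaries
loaded every token gets the NONE feature and the model degrades to its
lexical-only tier.

Knowledge features are computed on the corrected text — the same stream
the tagger reads.

The part-of-speech stream comes from a small deterministic rule-based
tagger (closed-class lexicon plus suffix heuristics over the Penn
Treebank tagset) shipped with the package. As a categorical feature
stream feeding a learned embedding, stability and determinism matter more
than tagging accuracy; the contract (length-preserving, deterministic,
"X" fallback) is what the model relies on.

## Evaluation

Strict matching requires identical (start, end, category); relax
matching requires at least one character of overlap and the same
category. Matching is one-to-one: exactly coincident pairs bind first,
then each remaining gold span (left to right) takes the available
overlapping prediction with the smallest end offset. For disjoint span
lists this earliest-end rule achieves maximum-cardinality matching (the
classic interval exchange argument), so reported counts equal an
exhaustive optimal assignment. Precision, recall and F1 use the 0/0 -> 0
convention (a category with nothing detected scores 0, not NaN); micro
scores pool counts over categories before dividing. Every disagreement is
also assigned to exactly one of four error kinds: boundary mismatch,
wrong category, false positive, false negative.

Relax-mode credit requires the categories to agree; an overlapping span
with the wrong category is not a relax true positive (it surfaces in the
taxonomy as a wrong-category error instead).

## The surrogate-note generator

Real de-identification corpora are access-restricted, so the package
ships a seeded generator of surrogate notes. Each note is a note-type
header (PROGRESS NOTES / RADIOLOGY REPORT / H&P, mixed 0.5/0.3/0.2)
followed by 4-8 single-PHI sentences and 2-4 filler sentences, one per
line. Each PHI sentence draws its category from a fixed weight table
(DATE 4702, NAME 1983, AGE 408, ID 334, PHONE 125, WEB 4, INSTITUTE 319,
STREET 52, CITY 114, ZIP 65 — the heavy-tailed skew of real annotation
counts, with WEB vanishingly rare), picks a sentence template for that
category, and fills the slot with a surrogate value. Because each PHI
sentence carries exactly one category draw, per-category counts are a
clean multinomial, which the tests verify against 3-sigma bands.

Two built-in styles emulate the cross-institute shift: `site_A` and
`site_B` share sentence templates but have disjoint date, phone and ID
surface formats and disjoint name/city/street/institute vocabularies
(overlap constraint <= 20%, actual 0%). Typo injection deletes spaces at
lowercase-word/Capitalized-word boundaries outside annotated spans at a
configurable rate (default 0.02), shifting annotation offsets
consistently — exactly the error class the preprocessing repairs.

What the generator does **not** emulate: clinical narrative prose, PHIs
embedded mid-sentence in unpredictable contexts, ambiguous non-PHI
look-alikes (lab values shaped like dates), OCR noise, or annotation
disagreement. Passing the synthetic end-to-end tests therefore
demonstrates that the pipeline is wired correctly and that the model can
learn and transfer format/vocabulary distinctions — not that it would
reach any particular score on real clinical notes.

`plant_prediction_errors` perturbs gold annotations into synthetic
predictions realizing exact requested counts of the four error kinds
(extend/shrink a boundary by one character, flip a category, delete a
span, or add a span over unannotated text), giving the evaluation module
a closed-loop oracle.

## Scaled-down study sizes

The miniature studies in `phitag.experiments` use reduced dimensions
(word 24, char 8, LSTM 16 per direction, feature embeddings 8/6) and 10
scratch epochs (fine-tuning keeps its standard 15):

* single-site: train on 200 site_A notes, evaluate on 50 held-out site_A
  notes, median strict micro F1 over 3 seeds;
* cross-institute: 120 site_A training notes, 60 site_B training notes,
  40-note test sets; per seed the study trains the source model, measures
  zero-shot transfer, fine-tunes on site_B, retrains on the merged
  corpus, and trains a site_B-only baseline.

These sizes were chosen once as the smallest configuration that still
exercises every pipeline stage and the qualitative ordering of the
customization strategies (zero-shot < fine-tuned, zero-shot < merged,
fine-tuned >= target-only); the ordering, not the absolute F1, is the
reproducible claim at this scale.

## Numerical and degenerate-input choices

* Log-space forward/backward with max-shifted logsumexp throughout the
  CRF; likelihood/decoder agree with exhaustive enumeration within 1e-6
  on small instances.
* Empty documents predict no spans; empty sentences are skipped; an
  empty training corpus is an error.
* `T = 0` CRF inputs give an empty path and zero partition.
* Duplicate words in a vector file keep their first row (warning);
  a missing UNKNOWN row is sampled uniform in [-0.25, 0.25] from a fixed
  seed so repeated loads are identical.
* Unseen words at prediction time fall back exact -> case-folded ->
  UNKNOWN; unseen characters and feature values map to reserved UNK
  indices.
* Checkpoints are an `npz` weights file plus a JSON sidecar
  (vocabularies, hyperparameters, provenance chain of corpora and epoch
  counts); reloading reproduces predictions exactly.

## Known limitations

* The rule-based POS tagger is coarse; swapping in a stronger tagger
  behind the same contract may help on real text.
* Surrogate notes are template-generated; absolute synthetic scores
  overstate what any model achieves on real clinical narrative.
* The typo model covers only run-together words, the dominant class the
  preprocessing targets; other typographic noise passes through.
* Training is single-threaded CPU numpy; it is sized for the bundled
  studies, not for corpus-scale hyperparameter sweeps at the full
  300/100-dimension configuration.
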