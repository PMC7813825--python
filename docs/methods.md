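# Methods

## Problem setting

A localisation statement in a paper ties three entities together: a protein,
a subcellular compartment, and the experimental methodology that established
the observation.  `locrex` decomposes this ternary relation into per-triplet
binary classification: every (protein, methodology, location) mention
combination in a sentence becomes one instance, and the classifier decides
whether that particular combination is asserted by the sentence.  Because
the entity surface forms are replaced by typed tokens, the decision must be
made from the neighbouring context words and from the *positions* of the
focus tokens relative to the blanked competitors — which is exactly what a
recurrent reader can exploit.

## Candidate extraction

Sections are matched with case-insensitive header patterns
(`abstract`, `results?`, `materials? and methods|methods`); figure captions
are folded into the results section since localisation evidence is often
stated there.  Text is NFC-normalized before lexicon matching so typographic
hyphen and Greek variants cannot break protein-name lookup.

Mention matching is dictionary-driven: case-insensitive, word-bounded regex
matches against the three lexicons, with overlaps resolved to the longest
match ("green fluorescent protein" as a methodology beats an embedded
"protein").  A passage is reported wherever some contiguous forty-word
window contains at least one mention of each category.  Words are counted
after stripping edge punctuation (tokens that are pure punctuation do not
count; a flag restores the pre-stripping count, since the original window
definition does not pin this down).  Hit windows are merged when they
overlap; each merged cluster is trimmed to its mention-carrying words and
expanded to enclosing sentence boundaries (sentences split on `[.!?]` +
space + capital with an abbreviation guard: "Fig.", "et al.", "e.g.", …).
Adjacent sentences holding distinct clusters remain distinct passages.
Windows never span section boundaries, and the sliding step is one word —
the exhaustive reading of a sliding window.

## Annotation schema

Standoff annotations use 0-based half-open code-point offsets.  The schema
has eight entity types; four of them (Protein, Tagged_Protein,
Protein_variant, Protein_Locus) can fill the protein slot of a triplet.  The
eleven allowed (entity, entity, relation) rows are enforced by
`validate_schema`; Identifier/Gene_Locus bookkeeping relations are parsed
and validated but excluded from triplet building, since they carry no
localisation signal.  Tagged proteins ("SUVR2a-GFP") fuse protein and
methodology in one surface form; their protein/method sub-spans are
serialized as annotator-note lines (standoff has no native sub-span record)
and the method sub-span acts as a methodology mention for its own protein
only.

## Labelling rule

An instance is positive iff the annotation asserts both
`Located_In(protein, location)` and `Subcellular_methodology(protein,
method)`; `Not_Located_In` on the pair forces the negative label; a tagged
protein's own method sub-span satisfies the methodology requirement
implicitly.  Note a structural limit of the pairwise schema: it cannot
express a direct location↔method pairing.  In "respectively"-structured
sentences, where each compartment was established by its own technique, the
pairing is recoverable only through which `Subcellular_methodology`
relations the annotator asserts; the synthetic generator therefore builds
its "respectively" sentences with two protein mentions so that
cross-pairings are genuinely false under the pairwise rule.

## Instance construction

Focus mentions become `_PROTEIN_` / `_METHOD_` / `_LOCATION_`; competing
mentions become `_BLANKP_` / `_BLANKM_` / `_BLANKL_` (the method blank is
added by symmetry — a blanking scheme with protein and location blanks but
observable method competitors would leak the focus).  Multi-word entities
collapse to a single token by default; a `method_style="tail"` flag instead
replaces only the last word of a multi-word methodology ("using mass
_METHOD_"), as both readings of the replacement scheme are defensible.
Remaining words are lower-cased and stripped of edge punctuation.  Sequences
are tail-padded to a common length — by default the 95th percentile of
content lengths, rounded up; padded positions are masked out of the
recurrent summary, so padding can never change a prediction.

Negatives are generated one-per-positive by permuting the special tokens
over the special-token positions.  Category-preserving focus↔blank swaps are
tried first; when every such arrangement is itself a true state (a sentence
where all enumerable triplets are annotated true), or none exists (a
single-triplet sentence), the generator falls back to cross-category
permutations, which always produce a structurally invalid candidate.  The
result must differ from the source and from every true tokenization of the
sentence, so a permuted negative is lexically identical to its positive and
differs only in structure.

Splits are paper-disjoint: whole papers are assigned to the test side until
it holds the target 20% of instances (achieved fraction within one paper's
worth of the target), preventing near-duplicate sentences from straddling
the split.

## CBOW pretraining

The embedding layer is initialized from CBOW vectors trained on the full
corpus: predict a target word from the mean of its context vectors, with
k = 5 negative samples drawn from the unigram^0.75 distribution.  The
trainer is a deterministic numpy implementation using mini-batches of
(target, context) examples (batch 64, learning rate 0.025 with linear
decay); these values were chosen for stable convergence of the summed-batch
update on small corpora.  Defaults follow word2vec convention where the
pipeline itself does not dictate them: dimension 100, window 5, min_count 2,
10 epochs.  Special tokens receive trained vectors by appending tokenized
instances to the pretraining stream; the PAD row is pinned to zero.
Embeddings are fine-tuned during classifier training (configurable).

## Classifier

Embedding → LSTM (hidden 150 per direction, forget-gate bias 1) read
forward and, when bidirectional, backward → final hidden states concatenated
(so the summary is 150- or 300-dimensional) → dropout 0.5 → dense tanh layer
→ 2-unit output → log-softmax; the prediction is the argmax, with exact ties
resolved to the negative class for determinism.  Training minimizes
cross-entropy with Adam (lr 0.01, weight decay 1e-4 applied as L2 on
non-bias weights).  "Learning-rate decay 500" is implemented as halving the
learning rate every 500 optimizer steps; the schedule is pluggable since the
constant alone does not fix its semantics.  Gradients are clipped to global
norm 5 — a standard stability measure for recurrent networks at this
learning rate, chosen up front.  The backward pass is hand-derived BPTT and
is pinned by a finite-difference gradient check in float64.

Protocol: every epoch cycle reshuffles the training partition into five
folds (validation:training 1:4); each fold is held out once while one pass
is made over the other four, so a cycle comprises five train/validate
experiments and folds never repeat across cycles.  The parameter snapshot
with the best single-fold validation F1 is returned (`model_selection=
"final"` keeps the last weights instead).  Epochs (unstated upstream)
default to at most 30 cycles with early stopping after 3 cycles without
improvement in cycle-mean validation F1; batch size defaults to 32.
`run_experiments` re-seeds initialization and shuffling per run and reports
mean ± sd over runs on the fixed held-out test set; the sd is reported on
the fractional scale (an accuracy sd of 0.028 is 2.8 percentage points).

## Synthetic corpus

The generator emulates the statistical structure of annotated localisation
sentences: invented entity inventories (30 protein-like names, 8
compartment-like names, 4 methodology phrases — deliberately not real gene
symbols or GO terms, to avoid lexicon collisions), sentence templates with
typed slots, planted cue phrases that carry the relation signal ("localized
to … using" for true statements, hedged co-occurrence phrasing with a
`Not_Located_In` annotation for false ones), a 20% rate of multi-triplet
sentences (the all-true shared-method template and the two-protein
"respectively" template in equal shares), random filler-word noise, and a
grouping of 20 sentences per synthetic paper for the disjoint split.  Gold
labels are derived from the template structure, independently of the
annotation-based labelling rule, and the two routes are checked against
each other exhaustively in the tests.

Defaults are the study-scale conditions: 1400 sentences with an even
true/false split, yielding ≈700+ positive candidates, from which the
balanced 700 + 700 dataset is built.

What passing on this corpus shows — and does not.  The corpus is solvable
from context alone by construction, so the learnability check (≥95%
held-out accuracy with the default configuration) validates the *machinery*:
blanking, padding, masking, BPTT, the fold protocol and the metric plumbing.
It does not estimate performance on real prose, whose vocabulary, syntax and
annotation noise are far richer; scores on curated corpora must be measured
on those corpora with the same `run_experiments` protocol (30 runs, mean ±
sd, bidirectional and unidirectional rows).

## Numerical and degenerate-input choices

Metric conventions: precision 0 when TP+FP = 0, recall 0 when TP+FN = 0, F1
0 when precision+recall = 0; all-zero confusion counts are an error.
Single-class training data raises rather than fitting a degenerate model;
fewer than two papers cannot be split paper-disjointly; an empty lexicon or
corpus is an error.  All randomness flows through explicit seeds (Python
`random` for discrete choices, numpy Generators for the numerics); repeated
runs with the same seed are bitwise identical on the same machine and BLAS
configuration.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run the full protocol at the
default study scale (1400 sentences, 700+700 instances, hidden size 150) for
the learnability and experiment-summary checks, with three seeds and three
experiment repetitions respectively — enough to exercise seed-to-seed
variability while keeping a complete run in the minutes range on one CPU.
Unit tests use deliberately tiny models (hidden 4–12) where only contracts,
not capacity, are under test.

## Known limitations

- Sentence-bounded: no cross-sentence relations, coreference, or
  abbreviation expansion beyond lexicon synonyms.
- Dictionary-based mention finding misses names absent from the lexicons.
- The pairwise relation schema cannot directly encode location↔method
  pairings (see the labelling-rule note above).
- The CBOW trainer and LSTM are plain-numpy and single-threaded by design;
  they are sized for corpora of thousands of sentences, not millions.
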