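# locrex

Relation extraction for protein subcellular localisation from full-text
plant-biology literature.

Curated localisation databases are built by experts reading papers and
recording, for each protein, the compartment it was observed in **and** the
technique that established the observation (fluorophore tagging, subcellular
proteomics by mass spectrometry, …).  `locrex` implements a pipeline that
automates the extraction step as a *ternary* relation problem: within a
sentence, does a given (protein, methodology, subcellular location) mention
combination express an experimentally verified localisation?

## Pipeline

1. **Ingest** (`locrex.ingest`) — parse XML or plain-text articles into
   abstract / results / methods sections (figure captions folded into
   results); load entity lexicons (protein names + synonyms, compartment
   names, methodology terms) with case-insensitive lookup.
2. **Highlight** (`locrex.highlight`) — find passages where all three entity
   categories co-occur inside a forty-word sliding window, expanded to
   sentence boundaries; these are the candidate sentences for annotation.
3. **Standoff annotation** (`locrex.brat`) — read/write BRAT `.txt`/`.ann`
   pairs against a schema of eight entity types and five relation types
   (`Located_In`, `Not_Located_In`, `Subcellular_methodology`,
   `Protein_identifier`, `Locus_link`), including protein/method sub-labels
   for tagged proteins such as `SUVR2a-GFP`.
4. **Instance building** (`locrex.instances`) — enumerate every candidate
   triplet of a sentence, replace its mentions by `_PROTEIN_` / `_METHOD_` /
   `_LOCATION_` tokens and every competing mention by `_BLANKP_` / `_BLANKM_`
   / `_BLANKL_`, pad with `PAD`; label an instance 1 iff the annotation
   asserts both `Located_In(protein, location)` and
   `Subcellular_methodology(protein, method)`.  Negatives are generated by
   permuting the special-token positions of positives; train/test splits are
   paper-disjoint (1:4, 20% test).
5. **Pretraining** (`locrex.embeddings`) — CBOW word vectors (negative
   sampling, numpy) trained on the full-text corpus initialize the
   classifier's embedding layer.
6. **Classification** (`locrex.classifier`, `locrex.nn`) — a bidirectional
   LSTM reads the blanked token sequence; the final hidden states of the two
   directions are concatenated, passed through dropout (0.5), a tanh dense
   layer and a 2-way log-softmax:

   y\* = argmax_i log( exp(x_i) / Σ_j exp(x_j) )

   Training uses cross-entropy with Adam (learning rate 0.01, weight decay
   1e-4, hidden size 150, learning rate halved every 500 steps) and a
   shuffled five-fold validation protocol: each epoch cycle reshuffles the
   training partition into five folds and holds each out once, so a cycle is
   five train/validate experiments.  `run_experiments` repeats the whole
   protocol *n* times and reports mean ± sd of precision, recall, accuracy
   and F1 — with a unidirectional toggle for the directionality comparison.
7. **Synthetic fixtures** (`locrex.synthetic`) — a generator of schema-valid
   annotated corpora whose labels are a deterministic function of planted cue
   words, so the full pipeline is testable without external data.

## Worked example

```python
from locrex import enumerate_triplets, label_instance, tokenize_instance
from locrex.synthetic import shared_method_example

sent = shared_method_example()   # "Both Deg1 and Deg9 have been localized to
                                 #  the plastid and nucleus using mass spectrometry"
triplets = enumerate_triplets(sent)
print(len(triplets))             # 4  (2 proteins x 2 locations x 1 method)
inst = tokenize_instance(sent, triplets[0])
print(inst.tokens)
# ['both', '_PROTEIN_', 'and', '_BLANKP_', 'have', 'been', 'localized',
#  'to', 'the', '_LOCATION_', 'and', '_BLANKL_', 'using', '_METHOD_']
print([label_instance(sent, t) for t in triplets])   # [1, 1, 1, 1]
```

One sentence with two proteins, two compartments and one shared method
yields four candidate instances, one per triplet group; each is presented to
the classifier with exactly one focus triplet and all competitors blanked.

End-to-end from a shell:

```bash
locrex synth --out data/ --seed 3 --n-sentences 200
locrex highlight --corpus data/corpus.jsonl --lexicons data/lexicons --out passages.jsonl
locrex tokenize --ann data/brat --out inst.jsonl --seed 1
locrex split --instances inst.jsonl --train-out train.jsonl --test-out test.jsonl --seed 2
locrex pretrain --corpus data/corpus.jsonl --instances inst.jsonl --out emb.vec
locrex train --instances train.jsonl --embeddings emb.vec --out model.npz
locrex evaluate --model model.npz --embeddings emb.vec --instances test.jsonl --report report.json
```

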