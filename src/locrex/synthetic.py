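"""Schema-valid synthetic corpora with known ground truth.

Real annotated localisation corpora are external data, so every pipeline stage
is exercised on generated sentences whose relation labels are a deterministic
function of planted lexical cues: true statements use localisation cue phrases
("localized to … using"), false co-occurrences use hedged phrasing without a
methodology link, and "respectively"-structured sentences pair entities
positionally so that cross-pairings are false.  Entity inventories are
invented names (no real gene symbols, compartments or techniques) to avoid
accidental lexicon collisions.

The generator is not a statistical model of scientific prose — vocabulary is
tiny and syntax templated — but it reproduces the structural features the
classifier must handle: multiple triplet groups per sentence, distractor
entities, blanked competitors, and context words that carry the signal.
"""

from __future__ import annotations

import csv
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .brat import (
    AnnotatedSentence,
    EntityAnnotation,
    RelationAnnotation,
    SubLabel,
    write_standoff,
)
from .ingest import DocumentRecord, Lexicon, write_corpus
from .instances import (
    CandidateTriplet,
    TokenizedInstance,
    build_instances,
    enumerate_triplets,
    generate_negatives,
    pad_instances,
)

_PROTEIN_PREFIXES = ("VXP", "ZQR", "KLP", "DRB", "QTM", "NLF")

DEFAULT_PROTEINS = tuple(f"{p}{i}" for p in _PROTEIN_PREFIXES for i in range(1, 6))
DEFAULT_LOCATIONS = (
    "velosome", "bruntoplast", "kleinosome", "marzelle",
    "orbiplast", "tessosome", "quorosome", "drellium",
)
DEFAULT_METHODS = (
    "glimmer tagging", "mass veltrometry", "fluorotag imaging", "proximity velocimetry",
)
_FILLERS = ("notably", "previously", "moreover", "reportedly", "subsequently", "interestingly")

DEFAULT_CUE_MODEL = {
    "true": ("localized to", "using"),
    "false": ("discussed alongside", "also employed"),
}

DEFAULT_TEMPLATES = ("single_true", "single_false", "shared_method", "respectively_pair")


class GeneratorSpecError(ValueError):
    pass


@dataclass
class GeneratorSpec:
    """Parameters of the synthetic corpus.

    Defaults mirror the scale of the annotation study the pipeline targets:
    1400 candidate sentences drawn from a pool of papers, an even split of
    true and false statements, and a 20% rate of multi-triplet sentences.
    """

    n_sentences: int = 1400
    proteins: tuple[str, ...] = DEFAULT_PROTEINS
    locations: tuple[str, ...] = DEFAULT_LOCATIONS
    methods: tuple[str, ...] = DEFAULT_METHODS
    templates: tuple[str, ...] = DEFAULT_TEMPLATES
    p_true: float = 0.5
    p_multi_triplet: float = 0.2
    cue_model: dict[str, tuple[str, str]] = field(default_factory=lambda: dict(DEFAULT_CUE_MODEL))
    noise: float = 0.3
    sentences_per_paper: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_true, self.p_multi_triplet, self.noise):
            if not 0 <= p <= 1:
                raise GeneratorSpecError("probabilities must lie in [0, 1]")
        if not (self.proteins and self.locations and self.methods):
            raise GeneratorSpecError("entity inventories must be non-empty")
        inventories = [set(map(str.lower, inv)) for inv in (self.proteins, self.locations, self.methods)]
        for i in range(3):
            for j in range(i + 1, 3):
                if inventories[i] & inventories[j]:
                    raise GeneratorSpecError("entity inventories must be disjoint across categories")
        if self.n_sentences < 1 or self.sentences_per_paper < 1:
            raise GeneratorSpecError("n_sentences and sentences_per_paper must be positive")


@dataclass(frozen=True)
class GoldLabel:
    sent_id: str
    triplet: CandidateTriplet
    label: int


@dataclass
class SyntheticCorpus:
    spec: GeneratorSpec
    documents: list[DocumentRecord]
    sentences: list[AnnotatedSentence]
    lexicons: dict[str, Lexicon]
    gold: list[GoldLabel]


class _Builder:
    """Assemble sentence text while tracking entity spans."""

    def __init__(self) -> None:
        self.parts: list[str] = []
        self.length = 0
        self.entities: list[EntityAnnotation] = []
        self.relations: list[RelationAnnotation] = []
        self.sub_labels: dict[str, SubLabel] = {}
        self._t = 0
        self._r = 0

    def add(self, text: str) -> None:
        self.parts.append(text)
        self.length += len(text)

    def entity(self, surface: str, etype: str) -> str:
        self._t += 1
        ann_id = f"T{self._t}"
        self.entities.append(EntityAnnotation(ann_id, etype, self.length, self.length + len(surface), surface))
        self.add(surface)
        return ann_id

    def relation(self, rtype: str, arg1: str, arg2: str) -> None:
        self._r += 1
        self.relations.append(RelationAnnotation(f"R{self._r}", rtype, arg1, arg2))

    def finish(self, sent_id: str, doc_id: str) -> AnnotatedSentence:
        return AnnotatedSentence(
            sent_id=sent_id, text="".join(self.parts), entities=self.entities,
            relations=self.relations, sub_labels=self.sub_labels, doc_id=doc_id,
        )


def _maybe_filler(b: _Builder, rng: random.Random, rate: float) -> None:
    if rng.random() < rate:
        b.add(rng.choice(_FILLERS).capitalize() + ", ")


def _sample_template(spec: GeneratorSpec, rng: random.Random) -> str:
    truth = rng.random() < spec.p_true
    multi = rng.random() < spec.p_multi_triplet
    if truth and multi:
        pool = [t for t in ("shared_method", "respectively_pair") if t in spec.templates]
        if pool:
            return rng.choice(pool)
    return ("single_true" if truth else "single_false")


def _build_sentence(
    template: str, spec: GeneratorSpec, rng: random.Random, sent_id: str, doc_id: str
) -> tuple[AnnotatedSentence, list[tuple[str, str, str]]]:
    """Returns the sentence and its true (protein, method, location) id triples."""
    b = _Builder()
    cue_t = spec.cue_model["true"]
    cue_f = spec.cue_model["false"]
    _maybe_filler(b, rng, spec.noise)
    true_triples: list[tuple[str, str, str]] = []
    if template == "single_true":
        p, loc = rng.choice(spec.proteins), rng.choice(spec.locations)
        meth = rng.choice(spec.methods)
        b.add("The ")
        tp = b.entity(p, "Protein")
        b.add(f" protein was {cue_t[0]} the ")
        tl = b.entity(loc, "Subcellular_Location")
        b.add(f" {cue_t[1]} ")
        tm = b.entity(meth, "Methodology")
        b.add(".")
        b.relation("Located_In", tp, tl)
        b.relation("Subcellular_methodology", tp, tm)
        true_triples.append((tp, tm, tl))
    elif template == "single_false":
        p, loc = rng.choice(spec.proteins), rng.choice(spec.locations)
        meth = rng.choice(spec.methods)
        b.add("The ")
        tp = b.entity(p, "Protein")
        b.add(f" protein was {cue_f[0]} the ")
        tl = b.entity(loc, "Subcellular_Location")
        b.add(f" in work that {cue_f[1]} ")
        b.entity(meth, "Methodology")
        b.add(".")
        b.relation("Not_Located_In", tp, tl)
    elif template == "shared_method":
        p1, p2 = rng.sample(spec.proteins, 2)
        l1, l2 = rng.sample(spec.locations, 2)
        meth = rng.choice(spec.methods)
        b.add("Both ")
        tp1 = b.entity(p1, "Protein")
        b.add(" and ")
        tp2 = b.entity(p2, "Protein")
        b.add(f" have been {cue_t[0]} the ")
        tl1 = b.entity(l1, "Subcellular_Location")
        b.add(" and ")
        tl2 = b.entity(l2, "Subcellular_Location")
        b.add(f" {cue_t[1]} ")
        tm = b.entity(meth, "Methodology")
        b.add(".")
        for tp in (tp1, tp2):
            b.relation("Subcellular_methodology", tp, tm)
            for tl in (tl1, tl2):
                b.relation("Located_In", tp, tl)
                true_triples.append((tp, tm, tl))
    elif template == "respectively_pair":
        p1, p2 = rng.sample(spec.proteins, 2)
        l1, l2 = rng.sample(spec.locations, 2)
        m1, m2 = rng.sample(spec.methods, 2)
        tp1 = b.entity(p1, "Protein")
        b.add(" and ")
        tp2 = b.entity(p2, "Protein")
        b.add(f" were {cue_t[0]} the ")
        tl1 = b.entity(l1, "Subcellular_Location")
        b.add(" and ")
        tl2 = b.entity(l2, "Subcellular_Location")
        b.add(f" {cue_t[1]} ")
        tm1 = b.entity(m1, "Methodology")
        b.add(" and ")
        tm2 = b.entity(m2, "Methodology")
        b.add(", respectively.")
        for tp, tm, tl in ((tp1, tm1, tl1), (tp2, tm2, tl2)):
            b.relation("Located_In", tp, tl)
            b.relation("Subcellular_methodology", tp, tm)
            true_triples.append((tp, tm, tl))
    else:
        raise GeneratorSpecError(f"unknown template {template!r}")
    return b.finish(sent_id, doc_id), true_triples


def expected_positive_stats(spec: GeneratorSpec) -> tuple[float, float]:
    """Per-sentence mean and variance of the positive-candidate count."""
    multi_pool = [t for t in ("shared_method", "respectively_pair") if t in spec.templates]
    per_multi = {"shared_method": 4, "respectively_pair": 2}
    outcomes: list[tuple[float, int]] = [(1 - spec.p_true, 0)]
    pm = spec.p_multi_triplet if multi_pool else 0.0
    outcomes.append((spec.p_true * (1 - pm), 1))
    for t in multi_pool:
        outcomes.append((spec.p_true * pm / len(multi_pool), per_multi[t]))
    mean = sum(p * k for p, k in outcomes)
    var = sum(p * k * k for p, k in outcomes) - mean ** 2
    return mean, var


def generate_corpus(spec: GeneratorSpec) -> SyntheticCorpus:
    """Generate documents, annotated sentences, lexicons and gold labels.

    Deterministic under ``spec.seed``; gold labels are derived from the
    template structure, independently of the annotation-based labelling rule.
    """
    rng = random.Random(spec.seed)
    sentences: list[AnnotatedSentence] = []
    gold: list[GoldLabel] = []
    documents: list[DocumentRecord] = []
    n_docs = (spec.n_sentences + spec.sentences_per_paper - 1) // spec.sentences_per_paper
    idx = 0
    for d in range(n_docs):
        doc_id = f"SYN{d + 1:04d}"
        doc_sents: list[AnnotatedSentence] = []
        for _ in range(min(spec.sentences_per_paper, spec.n_sentences - idx)):
            sent_id = f"{doc_id}-s{idx:05d}"
            template = _sample_template(spec, rng)
            sent, true_triples = _build_sentence(template, spec, rng, sent_id, doc_id)
            true_set = set(true_triples)
            for trip in enumerate_triplets(sent):
                label = int((trip.protein, trip.method, trip.location) in true_set)
                gold.append(GoldLabel(sent_id=sent_id, triplet=trip, label=label))
            doc_sents.append(sent)
            sentences.append(sent)
            idx += 1
        documents.append(
            DocumentRecord(
                doc_id=doc_id,
                sections={
                    "abstract": "A study of subcellular targeting in a model plant.",
                    "results": " ".join(s.text for s in doc_sents),
                    "methods": "Standard growth conditions were used throughout.",
                },
                source_format="txt",
            )
        )
    lexicons = {
        "protein": Lexicon.from_terms("protein", spec.proteins),
        "location": Lexicon.from_terms("location", spec.locations),
        "method": Lexicon.from_terms("method", spec.methods),
    }
    return SyntheticCorpus(spec=spec, documents=documents, sentences=sentences, lexicons=lexicons, gold=gold)


def write_corpus_files(corpus: SyntheticCorpus, out_dir: str | Path) -> None:
    """Materialize the corpus: JSON-lines documents, BRAT pairs, lexicons, gold CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_corpus(corpus.documents, out_dir / "corpus.jsonl")
    brat_dir = out_dir / "brat"
    for sent in corpus.sentences:
        write_standoff(sent, brat_dir)
    lex_dir = out_dir / "lexicons"
    lex_dir.mkdir(exist_ok=True)
    for cat, lex in corpus.lexicons.items():
        terms = sorted(lex.terms)
        (lex_dir / f"{cat}.tsv").write_text("\n".join(terms) + "\n", encoding="utf-8")
    with open(out_dir / "gold.csv", "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sent_id", "protein", "method", "location", "label"])
        for g in corpus.gold:
            writer.writerow([g.sent_id, g.triplet.protein, g.triplet.method, g.triplet.location, g.label])


def make_classifier_dataset(
    corpus: SyntheticCorpus,
    n_pairs: int = 700,
    seed: int = 0,
    method_style: str = "whole",
) -> list[TokenizedInstance]:
    """Balanced instance set: ``n_pairs`` positives + ``n_pairs`` permuted negatives.

    Positive candidates are the label-1 tokenizations of the corpus; when more
    than ``n_pairs`` exist a deterministic subsample is taken.  Each retained
    positive contributes one permutation negative.  All instances are padded to
    the longest content length so the set shares one sequence length.
    """
    insts = build_instances(corpus.sentences, method_style=method_style)
    all_positives = [i for i in insts if i.label == 1]
    if len(all_positives) < n_pairs:
        raise GeneratorSpecError(
            f"corpus yields only {len(all_positives)} positives; need {n_pairs} (increase n_sentences)"
        )
    # negatives are drawn against the FULL positive set so a permutation can
    # never coincide with a true tokenization that the subsample dropped
    all_negatives = generate_negatives(all_positives, seed=seed + 1)
    if len(all_negatives) != len(all_positives):  # pragma: no cover - template sentences always permute
        raise GeneratorSpecError("some positives yielded no permutation negative")
    rng = random.Random(seed)
    keep = sorted(rng.sample(range(len(all_negatives)), n_pairs))
    positives = [all_positives[i] for i in keep]
    negatives = [all_negatives[i] for i in keep]
    combined = pad_instances(positives + negatives, percentile=100.0)
    rng.shuffle(combined)
    return combined


def shared_method_example() -> AnnotatedSentence:
    """Worked example: two proteins localized to two compartments by one method.

    Enumerates to four candidate triplets, all annotated true — the canonical
    multi-triplet case where one tokenized variant is produced per group.
    """
    b = _Builder()
    b.add("Both ")
    tp1 = b.entity("Deg1", "Protein")
    b.add(" and ")
    tp2 = b.entity("Deg9", "Protein")
    b.add(" have been localized to the ")
    tl1 = b.entity("plastid", "Subcellular_Location")
    b.add(" and ")
    tl2 = b.entity("nucleus", "Subcellular_Location")
    b.add(" using ")
    tm = b.entity("mass spectrometry", "Methodology")
    for tp in (tp1, tp2):
        b.relation("Subcellular_methodology", tp, tm)
        for tl in (tl1, tl2):
            b.relation("Located_In", tp, tl)
    return b.finish("example-shared-method", "EXAMPLE")


def easy_example() -> AnnotatedSentence:
    """One protein, one shared method, two compartments — the easy regime."""
    b = _Builder()
    tp = b.entity("GPR1", "Protein")
    b.add(" was localized to the ")
    tl1 = b.entity("nucleus", "Subcellular_Location")
    b.add(" and ")
    tl2 = b.entity("cytoplasm", "Subcellular_Location")
    b.add(" using ")
    tm = b.entity("GFP", "Methodology")
    b.add(".")
    b.relation("Subcellular_methodology", tp, tm)
    for tl in (tl1, tl2):
        b.relation("Located_In", tp, tl)
    return b.finish("example-easy", "EXAMPLE")


def hard_example() -> AnnotatedSentence:
    """'Respectively'-structured sentence: two locations paired with two methods.

    Each location was established by its own technique, so cross-pairings are
    false; the annotation asserts the methodology link only for the technique
    named first, making the pairing recoverable from pairwise relations.
    """
    b = _Builder()
    tp = b.entity("Deg7", "Protein")
    b.add(" is located in the ")
    tl1 = b.entity("plastid", "Subcellular_Location")
    b.add(" and ")
    tl2 = b.entity("cytosol", "Subcellular_Location")
    b.add(" using ")
    tm1 = b.entity("GFP", "Methodology")
    b.add(" and ")
    b.entity("mass spectrometry", "Methodology")
    b.add(", respectively.")
    b.relation("Located_In", tp, tl1)
    b.relation("Located_In", tp, tl2)
    b.relation("Subcellular_methodology", tp, tm1)
    return b.finish("example-hard", "EXAMPLE")


def tagged_protein_example() -> AnnotatedSentence:
    """A fluorophore-tagged protein whose surface form fuses protein and method."""
    b = _Builder()
    tid_start = b.length
    tid = b.entity("SUVR2a-GFP", "Tagged_Protein")
    b.add(" fluorescence was observed in the ")
    tl = b.entity("nucleolus", "Subcellular_Location")
    b.add(".")
    b.sub_labels[tid] = SubLabel(
        protein_span=(tid_start, tid_start + 6), method_span=(tid_start + 7, tid_start + 10)
    )
    b.relation("Located_In", tid, tl)
    return b.finish("example-tagged", "EXAMPLE")
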