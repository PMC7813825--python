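"""Candidate-triplet enumeration, entity-blanked tokenization and data splits.

Each annotated sentence is turned into one binary-classification instance per
(protein, methodology, location) mention combination.  The focus combination's
mentions become ``_PROTEIN_`` / ``_METHOD_`` / ``_LOCATION_`` tokens and every
other candidate mention is blanked (``_BLANKP_`` / ``_BLANKM_`` / ``_BLANKL_``),
so an instance encodes exactly one candidate relation and the classifier must
rely on the neighbouring context words.  An instance is positive when the
annotation asserts both ``Located_In`` (protein, location) and
``Subcellular_methodology`` (protein, method); a ``Not_Located_In`` assertion
forces the negative label.  Negatives for training are generated by permuting
the special-token positions of positive instances, and train/test splitting is
paper-disjoint so near-duplicate sentences never straddle the split.
"""

from __future__ import annotations

import json
import logging
import math
import random
import re
from dataclasses import dataclass, field, replace
from itertools import permutations
from pathlib import Path
from typing import Iterable, Sequence

from .brat import PROTEIN_GROUP, AnnotatedSentence, EntityAnnotation

logger = logging.getLogger(__name__)

PAD = "PAD"
UNK = "UNK"
FOCUS_TOKENS = {"protein": "_PROTEIN_", "method": "_METHOD_", "location": "_LOCATION_"}
BLANK_TOKENS = {"protein": "_BLANKP_", "method": "_BLANKM_", "location": "_BLANKL_"}
SPECIAL_TOKENS = (PAD, UNK, "_PROTEIN_", "_METHOD_", "_LOCATION_", "_BLANKP_", "_BLANKL_", "_BLANKM_")

_WORD_CLEAN_RE = re.compile(r"^\W+|\W+$")

#: sentinel suffix marking the method sub-span of a tagged protein
_TAG_METHOD_SUFFIX = ":method"


class InstanceError(ValueError):
    """Inconsistent triplet/sentence combination or malformed instance data."""


class SplitError(ValueError):
    """Raised when a paper-disjoint split is impossible."""


@dataclass(frozen=True)
class CandidateTriplet:
    """One (protein, methodology, location) mention combination of a sentence.

    ``method`` is the ann_id of a Methodology entity, or ``"<Tid>:method"``
    for the method sub-span of the focus Tagged_Protein itself.
    """

    protein: str
    method: str
    location: str
    sent_id: str

    @property
    def method_is_sublabel(self) -> bool:
        return self.method.endswith(_TAG_METHOD_SUFFIX)

    @property
    def method_entity(self) -> str:
        return self.method.split(":")[0]


@dataclass
class TokenizedInstance:
    """Fixed-length token sequence with a binary relation label."""

    tokens: list[str]
    label: int
    doc_id: str
    sent_id: str
    triplet: CandidateTriplet | None = None

    def content_length(self) -> int:
        return sum(1 for t in self.tokens if t != PAD)

    def check(self) -> None:
        for tok in ("_PROTEIN_", "_METHOD_", "_LOCATION_"):
            if self.tokens.count(tok) != 1:
                raise InstanceError(f"instance must contain exactly one {tok}")
        tail = self.tokens[self.content_length():]
        if any(t != PAD for t in tail) or PAD in self.tokens[: self.content_length()]:
            raise InstanceError("PAD tokens must form a contiguous tail")

    def to_json(self) -> str:
        d = {"tokens": self.tokens, "label": self.label, "doc_id": self.doc_id, "sent_id": self.sent_id}
        if self.triplet is not None:
            d["triplet"] = [self.triplet.protein, self.triplet.method, self.triplet.location]
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, line: str) -> "TokenizedInstance":
        d = json.loads(line)
        trip = None
        if "triplet" in d:
            p, m, loc = d["triplet"]
            trip = CandidateTriplet(p, m, loc, d["sent_id"])
        return cls(tokens=d["tokens"], label=int(d["label"]), doc_id=d["doc_id"], sent_id=d["sent_id"], triplet=trip)


def _protein_mentions(sentence: AnnotatedSentence) -> list[EntityAnnotation]:
    return sentence.entities_of(*PROTEIN_GROUP)


def enumerate_triplets(sentence: AnnotatedSentence) -> list[CandidateTriplet]:
    """Full cross product of protein-group × methodology × location mentions.

    A tagged protein's own method sub-span counts as a methodology mention for
    that protein only (the tag names the technique applied to that protein).
    Order is deterministic: protein-major, then method, then location offsets.
    """
    proteins = _protein_mentions(sentence)
    methods = sentence.entities_of("Methodology")
    locations = sentence.entities_of("Subcellular_Location")
    out: list[CandidateTriplet] = []
    for p in proteins:
        p_methods: list[tuple[int, str]] = [(m.start, m.ann_id) for m in methods]
        if p.etype == "Tagged_Protein" and p.ann_id in sentence.sub_labels:
            sub = sentence.sub_labels[p.ann_id]
            p_methods.append((sub.method_span[0], p.ann_id + _TAG_METHOD_SUFFIX))
        p_methods.sort()
        for _, m_id in p_methods:
            for loc in locations:
                out.append(CandidateTriplet(p.ann_id, m_id, loc.ann_id, sentence.sent_id))
    return out


def label_instance(sentence: AnnotatedSentence, focus: CandidateTriplet) -> int:
    """1 iff Located_In(protein, location) AND Subcellular_methodology(protein, method).

    A tagged protein's own sub-span method satisfies the methodology condition
    implicitly.  ``Not_Located_In`` on the (protein, location) pair forces 0.
    """
    located = False
    methodology = focus.method_is_sublabel and focus.method_entity == focus.protein
    for r in sentence.relations:
        if r.arg1 == focus.protein and r.arg2 == focus.location:
            if r.rtype == "Not_Located_In":
                return 0
            if r.rtype == "Located_In":
                located = True
        if r.rtype == "Subcellular_methodology" and r.arg1 == focus.protein and r.arg2 == focus.method_entity and not focus.method_is_sublabel:
            methodology = True
    return int(located and methodology)


def _clean_word(word: str) -> str:
    return _WORD_CLEAN_RE.sub("", word).lower()


def _words_of(fragment: str) -> list[str]:
    return [w for w in (_clean_word(t) for t in fragment.split()) if w]


def tokenize_instance(
    sentence: AnnotatedSentence,
    focus: CandidateTriplet,
    method_style: str = "whole",
) -> TokenizedInstance:
    """Entity-blanked token sequence for one candidate triplet (unpadded, unlabeled).

    Every candidate mention collapses to a single special token; ordinary words
    are lower-cased and stripped of edge punctuation.  ``method_style="tail"``
    replaces only the final word of a multi-word methodology mention, keeping
    the leading words as context (both readings of the replacement scheme are
    supported; whole-entity replacement is the default).
    """
    if method_style not in ("whole", "tail"):
        raise ValueError(f"unknown method_style {method_style!r}")
    if focus not in enumerate_triplets(sentence):
        raise InstanceError(f"{focus} is not a candidate triplet of sentence {sentence.sent_id}")

    # (start, end, token(s)) replacement segments
    segments: list[tuple[int, int, list[str]]] = []

    def method_tokens(surface_span: tuple[int, int], token: str) -> list[str]:
        if method_style == "tail":
            a, b = surface_span
            words = sentence.text[a:b].split()
            return _words_of(" ".join(words[:-1])) + [token] if len(words) > 1 else [token]
        return [token]

    for ent in _protein_mentions(sentence):
        sub = sentence.sub_labels.get(ent.ann_id)
        if ent.ann_id == focus.protein:
            if sub is not None:
                p_tok = ("_PROTEIN_", sub.protein_span)
                m_token = "_METHOD_" if focus.method_is_sublabel else "_BLANKM_"
                m_tok = (m_token, sub.method_span)
                for tok, (a, b) in sorted((p_tok, m_tok), key=lambda x: x[1]):
                    segments.append((a, b, [tok]))
                continue
            segments.append((ent.start, ent.end, ["_PROTEIN_"]))
        else:
            segments.append((ent.start, ent.end, ["_BLANKP_"]))
    for ent in sentence.entities_of("Methodology"):
        token = "_METHOD_" if ent.ann_id == focus.method else "_BLANKM_"
        segments.append((ent.start, ent.end, method_tokens((ent.start, ent.end), token)))
    for ent in sentence.entities_of("Subcellular_Location"):
        token = "_LOCATION_" if ent.ann_id == focus.location else "_BLANKL_"
        segments.append((ent.start, ent.end, [token]))

    segments.sort()
    tokens: list[str] = []
    cursor = 0
    for a, b, toks in segments:
        tokens.extend(_words_of(sentence.text[cursor:a]))
        tokens.extend(toks)
        cursor = b
    tokens.extend(_words_of(sentence.text[cursor:]))
    return TokenizedInstance(tokens=tokens, label=0, doc_id=sentence.doc_id, sent_id=sentence.sent_id, triplet=focus)


def build_instances(
    sentences: Iterable[AnnotatedSentence],
    method_style: str = "whole",
) -> list[TokenizedInstance]:
    """Enumerate, tokenize and label every candidate triplet of every sentence."""
    out = []
    for sent in sentences:
        for trip in enumerate_triplets(sent):
            inst = tokenize_instance(sent, trip, method_style=method_style)
            inst.label = label_instance(sent, trip)
            out.append(inst)
    return out


def max_sequence_length(instances: Sequence[TokenizedInstance], percentile: float = 95.0) -> int:
    """Padding length: the given percentile of content lengths, rounded up."""
    if not instances:
        raise ValueError("no instances")
    lengths = sorted(i.content_length() for i in instances)
    rank = max(0, math.ceil(percentile / 100.0 * len(lengths)) - 1)
    return lengths[rank]


def pad_instances(
    instances: Sequence[TokenizedInstance], max_len: int | None = None, percentile: float = 95.0
) -> list[TokenizedInstance]:
    """Tail-pad every instance to a common length.

    Instances longer than the padding length are truncated at the tail; if
    truncation would drop a focus token the instance is skipped with a warning.
    """
    if max_len is None:
        max_len = max_sequence_length(instances, percentile)
    out = []
    for inst in instances:
        toks = list(inst.tokens[: inst.content_length()])
        if len(toks) > max_len:
            toks = toks[:max_len]
            if any(toks.count(t) != 1 for t in FOCUS_TOKENS.values()):
                logger.warning("skipping %s/%s: truncation would drop a focus token", inst.doc_id, inst.sent_id)
                continue
        padded = replace(inst, tokens=toks + [PAD] * (max_len - len(toks)))
        padded.check()
        out.append(padded)
    return out


def _special_positions(tokens: Sequence[str]) -> list[int]:
    specials = set(FOCUS_TOKENS.values()) | set(BLANK_TOKENS.values())
    return [i for i, t in enumerate(tokens) if t in specials]


def _category_preserving_arrangements(tokens: Sequence[str], positions: Sequence[int]) -> list[tuple[str, ...]]:
    """Arrangements that only swap a focus token with blanks of its own category."""
    by_cat: dict[str, list[int]] = {"protein": [], "method": [], "location": []}
    cat_of = {**{v: k for k, v in FOCUS_TOKENS.items()}, **{v: k for k, v in BLANK_TOKENS.items()}}
    for idx, pos in enumerate(positions):
        by_cat[cat_of[tokens[pos]]].append(idx)
    choices = []
    for cat, idxs in by_cat.items():
        choices.append([i for i in idxs])  # index (into positions) that receives the focus token
    arrangements = []
    for pi in choices[0]:
        for mi in choices[1]:
            for li in choices[2]:
                arr = []
                for idx, pos in enumerate(positions):
                    cat = cat_of[tokens[pos]]
                    focus_idx = {"protein": pi, "method": mi, "location": li}[cat]
                    arr.append(FOCUS_TOKENS[cat] if idx == focus_idx else BLANK_TOKENS[cat])
                arrangements.append(tuple(arr))
    return arrangements


def generate_negatives(
    positives: Sequence[TokenizedInstance], seed: int
) -> list[TokenizedInstance]:
    """One permuted label-0 instance per positive.

    The special tokens of a positive are permuted over the special-token
    positions so that the result differs from the source and from every
    label-1 tokenization of the same sentence.  Category-preserving focus/blank
    swaps are tried first; when every such arrangement is itself a true state
    (or none exists), the fall-back permutes tokens across categories, which
    always yields a structurally invalid — hence false — candidate.
    """
    if any(p.label != 1 for p in positives):
        raise InstanceError("generate_negatives expects label-1 instances only")
    forbidden: dict[str, set[tuple[str, ...]]] = {}
    for p in positives:
        forbidden.setdefault(p.sent_id, set()).add(tuple(p.tokens))
    rng = random.Random(seed)
    out: list[TokenizedInstance] = []
    for p in positives:
        inst_rng = random.Random(rng.randrange(2**31))
        positions = _special_positions(p.tokens)
        original = tuple(p.tokens[i] for i in positions)
        candidates = _category_preserving_arrangements(p.tokens, positions)
        inst_rng.shuffle(candidates)
        if len(positions) <= 7:
            general = sorted(set(permutations(original)))
            inst_rng.shuffle(general)
        else:  # factorial blow-up guard: sample shuffles instead of enumerating
            general = []
            pool = list(original)
            for _ in range(1000):
                inst_rng.shuffle(pool)
                general.append(tuple(pool))
        chosen: tuple[str, ...] | None = None
        for arr in candidates + general:
            if arr == original:
                continue
            toks = list(p.tokens)
            for pos, tok in zip(positions, arr):
                toks[pos] = tok
            if tuple(toks) in forbidden.get(p.sent_id, set()):
                continue
            chosen = arr
            break
        if chosen is None:
            logger.warning("no permutable negative for %s/%s; skipped", p.doc_id, p.sent_id)
            continue
        toks = list(p.tokens)
        for pos, tok in zip(positions, chosen):
            toks[pos] = tok
        neg = replace(p, tokens=toks, label=0)
        neg.check()
        out.append(neg)
    return out


def split_dataset(
    instances: Sequence[TokenizedInstance], test_fraction: float = 0.2, seed: int = 0
) -> tuple[list[TokenizedInstance], list[TokenizedInstance]]:
    """Paper-disjoint train/test split.

    Whole papers are assigned to the test side until it holds ``test_fraction``
    of the instances; the achieved fraction is within one paper's worth of the
    target and no doc_id straddles the split.
    """
    if not 0 <= test_fraction < 1:
        raise ValueError("test_fraction must be in [0, 1)")
    if test_fraction == 0:
        return list(instances), []
    by_doc: dict[str, list[TokenizedInstance]] = {}
    for inst in instances:
        by_doc.setdefault(inst.doc_id, []).append(inst)
    if len(by_doc) < 2:
        raise SplitError("paper-disjoint split requires at least 2 papers")
    docs = sorted(by_doc)
    random.Random(seed).shuffle(docs)
    target = test_fraction * len(instances)
    test_docs: set[str] = set()
    count = 0
    for doc in docs:
        if count >= target:
            break
        test_docs.add(doc)
        count += len(by_doc[doc])
    train = [i for i in instances if i.doc_id not in test_docs]
    test = [i for i in instances if i.doc_id in test_docs]
    return train, test


def write_instances(instances: Iterable[TokenizedInstance], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for inst in instances:
            fh.write(inst.to_json() + "\n")


def read_instances(path: str | Path) -> list[TokenizedInstance]:
    with open(path, encoding="utf-8") as fh:
        return [TokenizedInstance.from_json(line) for line in fh if line.strip()]
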