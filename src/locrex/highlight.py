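"""Dictionary-driven mention finding and sliding-window passage extraction.

A candidate passage is any stretch of text where a protein name, an
experimental-methodology term and a subcellular-compartment name co-occur
within a forty-word sliding window; overlapping hit windows are merged and the
result is expanded to enclosing sentence boundaries, since annotation and
classification operate on sentences.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .ingest import CATEGORIES, DocumentRecord, Lexicon

DEFAULT_WINDOW_WORDS = 40

#: tokens that end with '.' but do not end a sentence
_ABBREVIATIONS = {
    "fig.", "figs.", "al.", "e.g.", "i.e.", "vs.", "cf.", "ca.", "no.",
    "sp.", "spp.", "approx.", "etc.", "dr.", "st.",
}

_PUNCT_STRIP = ".,;:!?()[]{}\"'“”‘’"


@dataclass(frozen=True)
class Mention:
    """One lexicon match in a piece of text (offsets 0-based, half-open)."""

    category: str
    surface: str
    start: int
    end: int
    canonical: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid span [{self.start}, {self.end})")


@dataclass
class Passage:
    """A sentence-aligned span containing at least one full triplet group."""

    doc_id: str
    section: str
    text: str
    mentions: list[Mention]

    def __post_init__(self) -> None:
        cats = {m.category for m in self.mentions}
        if cats != set(CATEGORIES):
            raise ValueError(f"passage lacks categories: {set(CATEGORIES) - cats}")
        for m in self.mentions:
            if m.end > len(self.text) or self.text[m.start:m.end] != m.surface:
                raise ValueError(f"mention span does not match passage text: {m}")


def find_mentions(text: str, lexicons: Sequence[Lexicon]) -> list[Mention]:
    """All lexicon matches in ``text``, longest-match resolved, sorted by offset.

    Matching is case-insensitive and word-bounded; when two matches overlap the
    longer one wins (ties: the earlier, then the lexicographically smaller
    category — deterministic either way).
    """
    raw: list[Mention] = []
    for lex in lexicons:
        for surface in lex.surfaces():
            pat = re.compile(r"(?<!\w)" + re.escape(surface) + r"(?!\w)", re.IGNORECASE)
            for m in pat.finditer(text):
                matched = text[m.start():m.end()]
                raw.append(
                    Mention(
                        category=lex.category,
                        surface=matched,
                        start=m.start(),
                        end=m.end(),
                        canonical=lex.lookup(matched) or matched,
                    )
                )
    # longest-match overlap resolution
    raw.sort(key=lambda m: (-(m.end - m.start), m.start, m.category))
    kept: list[Mention] = []
    for cand in raw:
        if all(cand.end <= k.start or cand.start >= k.end for k in kept):
            kept.append(cand)
    kept.sort(key=lambda m: (m.start, m.end))
    return kept


def word_spans(text: str, count_punct_tokens: bool = False) -> list[tuple[int, int]]:
    """Character spans of the whitespace-delimited words used for window counting.

    A token that is empty after stripping edge punctuation does not count as a
    word unless ``count_punct_tokens`` is set.
    """
    spans = []
    for m in re.finditer(r"\S+", text):
        if not count_punct_tokens and not m.group().strip(_PUNCT_STRIP):
            continue
        spans.append((m.start(), m.end()))
    return spans


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Sentence spans split on [.!?] + space + capital, with an abbreviation guard."""
    bounds = [0]
    for m in re.finditer(r"[.!?]+\s+(?=[A-Z0-9])", text):
        prev = text[:m.start() + 1].rsplit(None, 1)
        last_tok = prev[-1].lower() if prev else ""
        if last_tok in _ABBREVIATIONS:
            continue
        bounds.append(m.end())
    bounds.append(len(text))
    out = []
    for a, b in zip(bounds, bounds[1:]):
        if text[a:b].strip():
            out.append((a, b))
    return out


def _hit_windows(
    word_cats: list[set[str]], window_words: int
) -> list[tuple[int, int]]:
    """Word-index ranges [i, j) of windows containing all three categories."""
    n = len(word_cats)
    w = min(window_words, n)
    if n == 0 or w == 0:
        return []
    counts = {c: 0 for c in CATEGORIES}
    hits = []
    for i in range(n - w + 1):
        if i == 0:
            for k in range(w):
                for c in word_cats[k]:
                    counts[c] += 1
        else:
            for c in word_cats[i - 1]:
                counts[c] -= 1
            for c in word_cats[i + w - 1]:
                counts[c] += 1
        if all(counts[c] > 0 for c in CATEGORIES):
            hits.append((i, i + w))
    return hits


def _merge_ranges(ranges: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge strictly overlapping ranges; touching ranges stay separate
    (adjacent sentences holding distinct clusters are distinct passages)."""
    merged: list[list[int]] = []
    for a, b in sorted(ranges):
        if merged and a < merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def extract_section_passages(
    text: str,
    lexicons: Sequence[Lexicon],
    window_words: int = DEFAULT_WINDOW_WORDS,
    doc_id: str = "",
    section: str = "results",
    count_punct_tokens: bool = False,
) -> list[Passage]:
    """Passages of one section where all three categories co-occur in a window."""
    if window_words < 1:
        raise ValueError("window_words must be >= 1")
    mentions = find_mentions(text, lexicons)
    if not mentions:
        return []
    spans = word_spans(text, count_punct_tokens)
    # per-word category presence (a word is covered if it overlaps a mention)
    word_cats: list[set[str]] = [set() for _ in spans]
    for men in mentions:
        for wi, (a, b) in enumerate(spans):
            if a < men.end and men.start < b:
                word_cats[wi].add(men.category)
    clusters = _merge_ranges(_hit_windows(word_cats, window_words))
    sentences = split_sentences(text)
    char_ranges = []
    for wi, wj in clusters:
        # trim cluster to the words that actually carry mentions
        carrying = [k for k in range(wi, wj) if word_cats[k]]
        lo, hi = spans[carrying[0]][0], spans[carrying[-1]][1]
        s_lo = min((a for a, b in sentences if b > lo), default=lo)
        s_hi = max((b for a, b in sentences if a < hi), default=hi)
        char_ranges.append((s_lo, s_hi))
    passages = []
    for a, b in _merge_ranges(char_ranges):
        sub = text[a:b]
        rebased = [replace(m, start=m.start - a, end=m.end - a) for m in mentions if a <= m.start and m.end <= b]
        cats = {m.category for m in rebased}
        if cats == set(CATEGORIES):
            passages.append(Passage(doc_id=doc_id, section=section, text=sub, mentions=rebased))
    return passages


def extract_passages(
    doc: DocumentRecord,
    lexicons: Sequence[Lexicon],
    window_words: int = DEFAULT_WINDOW_WORDS,
    count_punct_tokens: bool = False,
) -> list[Passage]:
    """All candidate passages of a document; windows never span section boundaries."""
    out = []
    for section in ("abstract", "results", "methods"):
        if section not in doc.sections:
            continue
        out.extend(
            extract_section_passages(
                doc.sections[section],
                lexicons,
                window_words=window_words,
                doc_id=doc.doc_id,
                section=section,
                count_punct_tokens=count_punct_tokens,
            )
        )
    return out
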