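"""Mention matching and sliding-window passage extraction.

The windowing logic is dual-routed: every result is compared against a literal
scan of each contiguous forty-word window (the brute-force oracle used here
and in the acceptance suite).
"""

import random
import re

import pytest

from locrex.highlight import (
    Mention,
    extract_passages,
    extract_section_passages,
    find_mentions,
    split_sentences,
    word_spans,
)
from locrex.ingest import DocumentRecord, Lexicon

PROT = Lexicon.from_terms("protein", ["GPR1", "VXP2"])
LOC = Lexicon.from_terms("location", ["nucleus", "velosome"])
METH = Lexicon.from_terms("method", ["GFP", "green fluorescent protein", "mass spectrometry"])
LEXICONS = [PROT, LOC, METH]


def brute_force_passages(text, lexicons, window_words):
    """Independent reference: scan every contiguous window directly."""
    mentions = find_mentions(text, lexicons)
    spans = word_spans(text)
    cats = []
    for a, b in spans:
        cover = {m.category for m in mentions if a < m.end and m.start < b}
        cats.append(cover)
    n = len(spans)
    w = min(window_words, n)
    hit_words = set()
    for i in range(max(0, n - w + 1) if n else 0):
        window = cats[i:i + w]
        union = set().union(*window) if window else set()
        if {"protein", "location", "method"} <= union:
            hit_words.update(range(i, i + w))
    # merge hit words into contiguous clusters
    clusters = []
    for idx in sorted(hit_words):
        if clusters and idx == clusters[-1][-1] + 1:
            clusters[-1].append(idx)
        else:
            clusters.append([idx])
    sentences = split_sentences(text)
    ranges = []
    for cl in clusters:
        carrying = [k for k in cl if cats[k]]
        lo, hi = spans[carrying[0]][0], spans[carrying[-1]][1]
        s_lo = min((a for a, b in sentences if b > lo), default=lo)
        s_hi = max((b for a, b in sentences if a < hi), default=hi)
        ranges.append((s_lo, s_hi))
    merged = []
    for a, b in sorted(ranges):
        if merged and a < merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    out = []
    for a, b in merged:
        covered = {m.category for m in mentions if a <= m.start and m.end <= b}
        if covered == {"protein", "location", "method"}:
            out.append(text[a:b])
    return out


def random_text(rng, n_words):
    filler = ["the", "plant", "cells", "were", "analysed", "and", "showed", "signal",
              "expression", "of", "localised", "in", "study", "samples."]
    terms = ["GPR1", "VXP2", "nucleus", "velosome", "GFP", "mass spectrometry"]
    words = []
    while len(words) < n_words:
        if rng.random() < 0.12:
            words.extend(rng.choice(terms).split())
        else:
            words.append(rng.choice(filler))
    return " ".join(words[:n_words]).capitalize()


class TestFindMentions:
    def test_three_categories_found(self):
        text = "GPR1 localised to the nucleus using GFP"
        mentions = find_mentions(text, LEXICONS)
        assert [m.category for m in mentions] == ["protein", "location", "method"]
        for m in mentions:
            assert text[m.start:m.end] == m.surface

    def test_no_lexicon_term_gives_empty_list(self):
        assert find_mentions("nothing relevant here", LEXICONS) == []

    def test_longest_match_wins(self):
        # "protein" itself is also a protein-lexicon term here: the full method
        # phrase must absorb it
        lexs = [Lexicon.from_terms("protein", ["protein"]), LOC,
                Lexicon.from_terms("method", ["green fluorescent protein"])]
        mentions = find_mentions("tagged with green fluorescent protein today", lexs)
        assert len(mentions) == 1
        assert mentions[0].category == "method"
        assert mentions[0].surface == "green fluorescent protein"

    def test_word_boundaries_respected(self):
        assert find_mentions("GPR12 is not GPR1", [PROT])[0].start == len("GPR12 is not ")

    def test_case_insensitive_canonicalization(self):
        m = find_mentions("the NUCLEUS was stained", [LOC])[0]
        assert m.canonical == "nucleus"
        assert m.surface == "NUCLEUS"

    def test_mentions_sorted_by_offset(self):
        text = "GFP marked GPR1 inside the nucleus"
        starts = [m.start for m in find_mentions(text, LEXICONS)]
        assert starts == sorted(starts)


class TestExtractPassages:
    def test_close_cooccurrence_yields_one_passage(self):
        text = "GPR1 localised to the nucleus using GFP in all samples."
        passages = extract_section_passages(text, LEXICONS, window_words=40)
        assert len(passages) == 1
        assert {m.category for m in passages[0].mentions} == {"protein", "location", "method"}

    def test_entities_beyond_window_yield_nothing(self):
        filler = " ".join(["word"] * 58)
        text = f"GPR1 nucleus {filler} GFP"
        assert extract_section_passages(text, LEXICONS, window_words=40) == []
        assert brute_force_passages(text, LEXICONS, 40) == []

    def test_two_disjoint_clusters_give_two_passages(self):
        gap = " ".join(["filler"] * 80)
        text = ("GPR1 sits in the nucleus per GFP data. " + gap +
                ". VXP2 moved to the velosome by mass spectrometry evidence.")
        passages = extract_section_passages(text, LEXICONS, window_words=40)
        assert len(passages) == 2
        assert [p.text for p in passages] == brute_force_passages(text, LEXICONS, 40)

    def test_passage_mentions_reproduce_via_find_mentions(self):
        text = "Imaging showed GPR1 localised to the nucleus using GFP. Unrelated tail sentence."
        for p in extract_section_passages(text, LEXICONS, window_words=40):
            again = find_mentions(p.text, LEXICONS)
            assert [(m.category, m.start, m.end) for m in again] == \
                [(m.category, m.start, m.end) for m in p.mentions]

    def test_window_must_be_positive(self):
        with pytest.raises(ValueError):
            extract_section_passages("GPR1 nucleus GFP", LEXICONS, window_words=0)

    def test_windows_do_not_span_sections(self):
        doc = DocumentRecord(
            doc_id="d", sections={"abstract": "GPR1 and the nucleus.", "results": "Only GFP here."}
        )
        assert extract_passages(doc, LEXICONS) == []

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_on_random_texts(self, seed):
        rng = random.Random(seed)
        text = random_text(rng, rng.randint(30, 500))
        got = [p.text for p in extract_section_passages(text, LEXICONS, window_words=40)]
        assert got == brute_force_passages(text, LEXICONS, 40)

    @pytest.mark.parametrize("seed", range(6))
    def test_mention_coverage_monotone_in_window_size(self, seed):
        rng = random.Random(100 + seed)
        text = random_text(rng, 300)

        def covered(window):
            out = set()
            for p in extract_section_passages(text, LEXICONS, window_words=window):
                out.update((m.category, m.canonical) for m in p.mentions)
            return out

        prev = set()
        for window in (5, 10, 20, 40, 80):
            cur = covered(window)
            assert prev <= cur
            prev = cur


class TestSentenceSplit:
    def test_abbreviations_do_not_split(self):
        text = "See Fig. 2 for details. The protein moved."
        spans = split_sentences(text)
        assert len(spans) == 2
        assert text[spans[0][0]:spans[0][1]].strip() == "See Fig. 2 for details."

    def test_word_spans_skip_bare_punctuation(self):
        assert len(word_spans("one , two .")) == 2
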