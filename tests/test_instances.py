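import collections
import re

import pytest

from locrex.brat import AnnotatedSentence, EntityAnnotation, RelationAnnotation
from locrex.instances import (
    FOCUS_TOKENS,
    PAD,
    CandidateTriplet,
    InstanceError,
    SplitError,
    build_instances,
    enumerate_triplets,
    generate_negatives,
    label_instance,
    max_sequence_length,
    pad_instances,
    split_dataset,
    tokenize_instance,
    _words_of,
)
from locrex.synthetic import (
    GeneratorSpec,
    easy_example,
    generate_corpus,
    hard_example,
    shared_method_example,
    tagged_protein_example,
)


def _simple_sentence(n_prot=1, n_meth=1, n_loc=1, relate_first=True):
    """Sentence with the requested mention counts, first triplet optionally true."""
    parts, entities, relations = [], [], []
    cursor = 0
    t = 0

    def ent(surface, etype):
        nonlocal cursor, t
        t += 1
        entities.append(EntityAnnotation(f"T{t}", etype, cursor, cursor + len(surface), surface))
        parts.append(surface)
        cursor += len(surface)
        return f"T{t}"

    def lit(s):
        nonlocal cursor
        parts.append(s)
        cursor += len(s)

    p_ids = []
    for i in range(n_prot):
        p_ids.append(ent(f"PROT{i}", "Protein"))
        lit(" and ")
    lit("went to ")
    l_ids = []
    for i in range(n_loc):
        l_ids.append(ent(f"loci{i}", "Subcellular_Location"))
        lit(" or ")
    lit("seen by ")
    m_ids = []
    for i in range(n_meth):
        m_ids.append(ent(f"metho{i}", "Methodology"))
        lit(" plus ")
    if relate_first:
        relations.append(RelationAnnotation("R1", "Located_In", p_ids[0], l_ids[0]))
        relations.append(RelationAnnotation("R2", "Subcellular_methodology", p_ids[0], m_ids[0]))
    return AnnotatedSentence(sent_id="s1", text="".join(parts), entities=entities, relations=relations)


class TestEnumerateTriplets:
    def test_worked_example_yields_four(self):
        assert len(enumerate_triplets(shared_method_example())) == 4

    def test_single_combination(self):
        assert len(enumerate_triplets(_simple_sentence())) == 1

    @pytest.mark.parametrize("np_,nm,nl", [(3, 2, 2), (2, 1, 3), (1, 4, 1)])
    def test_cross_product_count(self, np_, nm, nl):
        sent = _simple_sentence(np_, nm, nl)
        assert len(enumerate_triplets(sent)) == np_ * nm * nl

    def test_missing_category_gives_empty(self):
        sent = _simple_sentence(n_meth=0, relate_first=False)
        assert enumerate_triplets(sent) == []

    def test_order_is_protein_major_and_deterministic(self):
        sent = _simple_sentence(2, 2, 2)
        trips = enumerate_triplets(sent)
        assert trips == enumerate_triplets(sent)
        protein_order = [t.protein for t in trips]
        assert protein_order == sorted(protein_order, key=lambda a: int(a[1:]))


class TestTokenizeInstance:
    def test_printed_blanking_pattern(self):
        sent = shared_method_example()
        first = enumerate_triplets(sent)[0]
        inst = tokenize_instance(sent, first)
        assert inst.tokens == [
            "both", "_PROTEIN_", "and", "_BLANKP_", "have", "been", "localized",
            "to", "the", "_LOCATION_", "and", "_BLANKL_", "using", "_METHOD_",
        ]

    def test_single_triplet_has_no_blanks(self):
        sent = _simple_sentence()
        inst = tokenize_instance(sent, enumerate_triplets(sent)[0])
        assert not any(t.startswith("_BLANK") for t in inst.tokens)

    def test_tagged_protein_sub_spans_become_adjacent_tokens(self):
        sent = tagged_protein_example()
        trips = enumerate_triplets(sent)
        assert len(trips) == 1 and trips[0].method_is_sublabel
        inst = tokenize_instance(sent, trips[0])
        i = inst.tokens.index("_PROTEIN_")
        assert inst.tokens[i + 1] == "_METHOD_"

    def test_tail_method_style_keeps_leading_words(self):
        sent = shared_method_example()
        inst = tokenize_instance(sent, enumerate_triplets(sent)[0], method_style="tail")
        assert inst.tokens[-2:] == ["mass", "_METHOD_"]

    def test_foreign_triplet_rejected(self):
        sent = _simple_sentence()
        alien = CandidateTriplet("T9", "T8", "T7", "s1")
        with pytest.raises(InstanceError):
            tokenize_instance(sent, alien)

    def test_token_multiset_preserved(self, small_corpus):
        # mapping each special token back to its entity's surface words must
        # recover the sentence word multiset exactly (no loss or duplication)
        for sent in small_corpus.sentences[:40]:
            for trip in enumerate_triplets(sent):
                inst = tokenize_instance(sent, trip)
                specials = iter(sorted(sent.entities, key=lambda e: e.start))
                expanded = []
                for tok in inst.tokens:
                    if tok in FOCUS_TOKENS.values() or tok.startswith("_BLANK"):
                        expanded.extend(_words_of(next(specials).surface))
                    else:
                        expanded.append(tok)
                assert collections.Counter(expanded) == collections.Counter(_words_of(sent.text))


class TestLabelInstance:
    def test_easy_example_all_true(self):
        sent = easy_example()
        labels = [label_instance(sent, t) for t in enumerate_triplets(sent)]
        assert labels == [1, 1]

    def test_cross_pairing_without_methodology_relation_is_false(self):
        sent = hard_example()
        by_key = {
            (t.method, t.location): label_instance(sent, t) for t in enumerate_triplets(sent)
        }
        # GFP (T4) is the annotated methodology; mass spectrometry (T5) is not linked
        assert by_key[("T4", "T2")] == 1   # (GFP, plastid): annotated pairing
        assert by_key[("T5", "T2")] == 0   # (mass spectrometry, plastid): cross pairing
        assert by_key[("T5", "T3")] == 0   # no methodology relation for T5 at all

    def test_no_relations_means_false(self):
        sent = _simple_sentence(relate_first=False)
        assert label_instance(sent, enumerate_triplets(sent)[0]) == 0

    def test_not_located_in_forces_false(self):
        sent = _simple_sentence()
        sent.relations.append(RelationAnnotation("R3", "Not_Located_In", "T1", "T2"))
        assert label_instance(sent, enumerate_triplets(sent)[0]) == 0

    def test_label_sum_equals_related_pairs(self, small_corpus):
        for sent in small_corpus.sentences:
            located = {(r.arg1, r.arg2) for r in sent.relations if r.rtype == "Located_In"}
            blocked = {(r.arg1, r.arg2) for r in sent.relations if r.rtype == "Not_Located_In"}
            methodol = {(r.arg1, r.arg2) for r in sent.relations if r.rtype == "Subcellular_methodology"}
            expected = sum(
                1
                for (p, loc) in located - blocked
                for (p2, m) in methodol
                if p2 == p
            )
            got = sum(label_instance(sent, t) for t in enumerate_triplets(sent))
            assert got == expected


class TestGenerateNegatives:
    def _positives(self, corpus, n):
        pos = [i for i in build_instances(corpus.sentences) if i.label == 1]
        return pos[:n]

    def test_one_negative_per_positive_all_distinct(self, small_corpus):
        pos = self._positives(small_corpus, 60)
        negs = generate_negatives(pos, seed=3)
        assert len(negs) == len(pos)
        assert all(n.label == 0 for n in negs)
        for p, n in zip(pos, negs):
            assert n.tokens != p.tokens
            assert sorted(n.tokens) == sorted(p.tokens)
            n.check()

    def test_negative_never_equals_any_true_tokenization(self, small_corpus):
        pos = [i for i in build_instances(small_corpus.sentences) if i.label == 1]
        true_by_sent = collections.defaultdict(set)
        for p in pos:
            true_by_sent[p.sent_id].add(tuple(p.tokens))
        for n in generate_negatives(pos, seed=9):
            assert tuple(n.tokens) not in true_by_sent[n.sent_id]

    def test_empty_input_empty_output(self):
        assert generate_negatives([], seed=0) == []

    def test_deterministic_under_seed(self, small_corpus):
        pos = self._positives(small_corpus, 30)
        a = generate_negatives(pos, seed=42)
        b = generate_negatives(pos, seed=42)
        assert [x.tokens for x in a] == [y.tokens for y in b]

    def test_label_one_required(self, small_corpus):
        neg = [i for i in build_instances(small_corpus.sentences) if i.label == 0][:1]
        with pytest.raises(InstanceError):
            generate_negatives(neg, seed=0)


class TestPadding:
    def test_pad_to_common_length_with_tail_padding(self, small_corpus):
        insts = build_instances(small_corpus.sentences)[:50]
        padded = pad_instances(insts, percentile=100.0)
        length = len(padded[0].tokens)
        for inst in padded:
            assert len(inst.tokens) == length
            inst.check()

    def test_percentile_length_is_order_statistic(self, small_corpus):
        insts = build_instances(small_corpus.sentences)[:50]
        lengths = sorted(i.content_length() for i in insts)
        assert max_sequence_length(insts, percentile=100.0) == lengths[-1]
        assert max_sequence_length(insts, percentile=50.0) <= lengths[-1]


class TestSplitDataset:
    def test_twenty_equal_papers_give_four_test_papers(self, small_corpus):
        corpus = generate_corpus(GeneratorSpec(n_sentences=100, sentences_per_paper=5, seed=2))
        insts = pad_instances(build_instances(corpus.sentences), percentile=100.0)
        train, test = split_dataset(insts, test_fraction=0.2, seed=0)
        train_docs = {i.doc_id for i in train}
        test_docs = {i.doc_id for i in test}
        assert not train_docs & test_docs
        assert len(test_docs) >= 4  # 20 papers, uneven instance counts per paper

    def test_single_paper_rejected(self):
        sent = shared_method_example()
        insts = pad_instances(build_instances([sent]), percentile=100.0)
        with pytest.raises(SplitError):
            split_dataset(insts, test_fraction=0.2, seed=0)

    def test_zero_fraction_puts_everything_in_train(self, small_dataset):
        train, test = split_dataset(small_dataset, test_fraction=0.0, seed=1)
        assert test == [] and len(train) == len(small_dataset)

    def test_disjoint_and_near_target_over_many_seeds(self, small_dataset):
        total = len(small_dataset)
        largest_paper = max(
            collections.Counter(i.doc_id for i in small_dataset).values()
        )
        for seed in range(200):
            train, test = split_dataset(small_dataset, test_fraction=0.2, seed=seed)
            assert not {i.doc_id for i in train} & {i.doc_id for i in test}
            assert abs(len(test) - 0.2 * total) <= largest_paper


class TestSerialization:
    def test_instance_jsonl_round_trip(self, tmp_path, small_dataset):
        from locrex.instances import read_instances, write_instances

        path = tmp_path / "inst.jsonl"
        write_instances(small_dataset, path)
        again = read_instances(path)
        assert [i.tokens for i in again] == [i.tokens for i in small_dataset]
        assert [i.label for i in again] == [i.label for i in small_dataset]
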