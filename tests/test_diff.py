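"""Sentence alignment (against an exhaustive LCS oracle) and highlighting."""

import itertools
import random

import pytest

from labeldiff import diff


def exhaustive_lcs_length(a, b):
    """Independent oracle: longest common subsequence by enumerating all
    subsequences of the shorter list (lists are kept at length <= 8)."""
    short, other = (a, b) if len(a) <= len(b) else (b, a)
    best = 0
    for r in range(len(short), 0, -1):
        if r <= best:
            break
        for combo in itertools.combinations(short, r):
            it = iter(other)
            if all(item in it for item in combo):
                best = r
                break
    return best


def check_alignment_valid(old, new, alignment):
    olds = [p.old_index for p in alignment.pairs if p.old_index is not None]
    news = [p.new_index for p in alignment.pairs if p.new_index is not None]
    assert sorted(olds) == list(range(len(old)))
    assert sorted(news) == list(range(len(new)))
    equal_pairs = [(p.old_index, p.new_index) for p in alignment.pairs if p.op == "equal"]
    # equal pairs form a strictly increasing common subsequence of equal text
    assert equal_pairs == sorted(equal_pairs)
    for oi, ni in equal_pairs:
        assert diff.normalize_sentence(old[oi]) == diff.normalize_sentence(new[ni])


class TestAlignment:
    def test_identity(self):
        sentences = ["One here.", "Two here.", "Three here."]
        alignment = diff.align_sentences(sentences, sentences)
        assert all(p.op == "equal" for p in alignment.pairs)
        assert alignment.equal_count == 3

    def test_append_is_insert(self):
        old = ["A stays.", "B stays."]
        new = old + ["C added."]
        ops = [p.op for p in diff.align_sentences(old, new).pairs]
        assert ops == ["equal", "equal", "insert"]

    def test_reword_is_replace(self):
        old = ["A stays.", "B original.", "C stays."]
        new = ["A stays.", "B reworded.", "C stays."]
        pairs = diff.align_sentences(old, new).pairs
        assert [p.op for p in pairs] == ["equal", "replace", "equal"]
        replaced = pairs[1]
        assert (replaced.old_index, replaced.new_index) == (1, 1)

    def test_case_and_whitespace_insensitive_equality(self):
        alignment = diff.align_sentences(["Nausea  was seen."], ["NAUSEA WAS SEEN."])
        assert alignment.pairs[0].op == "equal"

    def test_empty_lists(self):
        assert diff.align_sentences([], []).pairs == []
        assert [p.op for p in diff.align_sentences(["x"], []).pairs] == ["delete"]
        assert [p.op for p in diff.align_sentences([], ["x"]).pairs] == ["insert"]

    def test_matches_exhaustive_lcs_oracle_on_random_lists(self):
        rng = random.Random(42)
        alphabet = [f"s{i}" for i in range(5)]
        for _ in range(200):
            old = [rng.choice(alphabet) for _ in range(rng.randint(0, 8))]
            new = [rng.choice(alphabet) for _ in range(rng.randint(0, 8))]
            alignment = diff.align_sentences(old, new)
            check_alignment_valid(old, new, alignment)
            assert alignment.equal_count == exhaustive_lcs_length(old, new)

    def test_equal_count_symmetric_on_random_lists(self):
        # with repeated sentences several maximum alignments exist, but the
        # number of matched pairs (the LCS length) is direction-independent
        rng = random.Random(7)
        alphabet = [f"s{i}" for i in range(4)]
        for _ in range(100):
            old = [rng.choice(alphabet) for _ in range(rng.randint(0, 8))]
            new = [rng.choice(alphabet) for _ in range(rng.randint(0, 8))]
            forward = diff.align_sentences(old, new)
            backward = diff.align_sentences(new, old)
            assert forward.equal_count == backward.equal_count

    def test_swap_mirrors_edit_scenarios(self):
        # documents have (near-)unique sentences; for old->new edit
        # derivations the alignment is unique and swapping old/new mirrors
        # every pair, exchanging insert and delete
        rng = random.Random(13)
        for round_number in range(50):
            old = [f"sentence {round_number}-{i}." for i in range(rng.randint(1, 8))]
            new = list(old)
            for index in range(len(new) - 1, -1, -1):
                action = rng.random()
                if action < 0.2:
                    del new[index]
                elif action < 0.4:
                    new[index] = f"rewritten {round_number}-{index}."
            for _ in range(rng.randint(0, 2)):
                new.insert(rng.randint(0, len(new)), f"fresh {rng.random():.6f}.")
            forward = diff.align_sentences(old, new)
            backward = diff.align_sentences(new, old)
            mirror = {"insert": "delete", "delete": "insert"}
            mirrored = [
                (mirror.get(p.op, p.op), p.new_index, p.old_index)
                for p in backward.pairs
            ]
            assert sorted(mirrored) == sorted(
                (p.op, p.old_index, p.new_index) for p in forward.pairs
            )


class TestHighlighting:
    def test_identical_sentences_no_spans(self):
        assert diff.highlight_pair("Same text here.", "Same text here.") == []

    def test_single_word_substitution_gives_token_spans(self):
        old = "In studies of twenty adult patients the most common finding overall was mild transient headache during the first week of treatment period"
        new = old.replace("headache", "dizziness")
        spans = diff.highlight_pair(old, new, ratio_threshold=0.5)
        assert {s.granularity for s in spans} == {"token"}
        by_side = {s.side: s for s in spans}
        assert old[slice(*by_side["old"].char_span)] == "headache"
        assert new[slice(*by_side["new"].char_span)] == "dizziness"

    def test_rewritten_sentence_gives_whole_sentence_spans(self):
        old = "The old wording covered one specific topic."
        new = "Completely different text replaces everything now entirely."
        spans = diff.highlight_pair(old, new, ratio_threshold=0.5)
        assert {s.granularity for s in spans} == {"whole_sentence"}
        assert {s.side for s in spans} == {"old", "new"}
        for span in spans:
            text = old if span.side == "old" else new
            assert span.char_span == (0, len(text))

    def test_punctuation_only_change_counts_as_changed(self):
        spans = diff.highlight_pair("A result: five.", "A result, five.")
        assert spans, "punctuation edit must produce highlight spans"

    def test_threshold_is_configurable(self):
        old = "alpha beta gamma delta"
        new = "alpha beta gamma omega"
        token = diff.highlight_pair(old, new, ratio_threshold=0.5)
        whole = diff.highlight_pair(old, new, ratio_threshold=0.1)
        assert {s.granularity for s in token} == {"token"}
        assert {s.granularity for s in whole} == {"whole_sentence"}

    def test_self_diff_of_document_sentences_yields_nothing(self, simple_pair):
        from labeldiff import report

        doc = report.load_label(simple_pair.old_pdf)
        for section in doc.ae_sections:
            for sub in section.subsections:
                sentences = [s.text for s in sub.sentences]
                alignment = diff.align_sentences(sentences, sentences)
                assert all(p.op == "equal" for p in alignment.pairs)
                for sentence in sentences:
                    assert diff.highlight_pair(sentence, sentence) == []
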