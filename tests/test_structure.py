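"""Component segmentation, AE-section extraction, subsection and sentence
splitting."""

import pytest

from labeldiff import structure
from labeldiff.ingest import TextBlock


def block(text, y0=100.0, page=0):
    return TextBlock(page_index=page, bbox=(36.0, y0, 300.0, y0 + 12.0), text=text)


FULL_TEXT = """WARNING: SERIOUS RISKS
Severe events may occur in some patients.
1 INDICATIONS AND USAGE
The product is indicated for the described condition.
4 CONTRAINDICATIONS
Do not use in patients with prior reactions.
5 WARNINGS AND PRECAUTIONS
Lead text for warnings.
5.1 Hepatic Effects
Liver findings were seen. Rates were 5.2% (e.g., in adults).
5.2 Use With Central Depressants
Avoid concurrent use when possible.
6 ADVERSE REACTIONS
Overall reaction summary text.
6.1 Clinical Trials Experience
Nausea occurred. Vomiting occurred.
6.2 Postmarketing Experience
Reports were received after approval.
7 DRUG INTERACTIONS
Interaction studies were performed.
8 USE IN SPECIFIC POPULATIONS
Use caution in older patients."""


class TestComponents:
    def test_three_components(self):
        blocks = [
            block("HIGHLIGHTS OF PRESCRIBING INFORMATION", 40),
            block("highlight text", 60),
            block("FULL PRESCRIBING INFORMATION: CONTENTS", 100),
            block("6 ADVERSE REACTIONS", 120),
            block("FULL PRESCRIBING INFORMATION", 160, page=1),
            block("body text", 180, page=1),
        ]
        components = structure.segment_components(blocks)
        assert components["highlights"].splitlines() == [
            "HIGHLIGHTS OF PRESCRIBING INFORMATION",
            "highlight text",
        ]
        assert "6 ADVERSE REACTIONS" in components["contents"]
        assert components["full_text"].endswith("body text")

    def test_no_headings_falls_back_to_full_text(self):
        blocks = [block("just some document"), block("with two blocks", 130)]
        components = structure.segment_components(blocks)
        assert components["full_text"] == "just some document\nwith two blocks"
        assert components["highlights"] == "" and components["contents"] == ""

    def test_prelude_attaches_to_first_component(self):
        blocks = [
            block("PRODUCT banner line", 20),
            block("HIGHLIGHTS OF PRESCRIBING INFORMATION", 40),
        ]
        components = structure.segment_components(blocks)
        assert components["highlights"].startswith("PRODUCT banner line")


class TestSections:
    def test_all_five_kinds_found(self):
        sections = structure.extract_ae_sections(FULL_TEXT)
        assert [s.kind for s in sections] == list(structure.SECTION_KINDS)
        by_kind = {s.kind: s for s in sections}
        assert "Do not use" in by_kind[structure.CONTRAINDICATIONS].body
        # body stops at the next top-level title, AE-related or not
        assert "8 USE" not in by_kind[structure.DRUG_INTERACTIONS].body
        assert "older patients" not in by_kind[structure.DRUG_INTERACTIONS].body

    @pytest.mark.parametrize(
        "title_line", ["6 ADVERSE REACTIONS", "6. ADVERSE REACTIONS", "  ADVERSE REACTIONS"]
    )
    def test_gradient_title_matching(self, title_line):
        text = f"{title_line}\nNausea occurred.\n7 DRUG INTERACTIONS\nNone known."
        sections = structure.extract_ae_sections(text)
        kinds = [s.kind for s in sections]
        assert structure.ADVERSE_REACTIONS in kinds
        section = sections[kinds.index(structure.ADVERSE_REACTIONS)]
        assert section.body.strip() == "Nausea occurred."

    def test_lowercase_title_not_matched(self):
        text = "6 Adverse Reactions\nNausea occurred."
        assert structure.extract_ae_sections(text) == []

    def test_absent_section_simply_omitted(self):
        text = "6 ADVERSE REACTIONS\nNausea occurred."
        sections = structure.extract_ae_sections(text)
        assert [s.kind for s in sections] == [structure.ADVERSE_REACTIONS]

    def test_duplicate_title_keeps_first(self):
        text = (
            "6 ADVERSE REACTIONS\nfirst body.\n"
            "7 DRUG INTERACTIONS\nmiddle.\n"
            "6 ADVERSE REACTIONS\nsecond body."
        )
        sections = structure.extract_ae_sections(text)
        section = [s for s in sections if s.kind == structure.ADVERSE_REACTIONS][0]
        assert "first body" in section.body

    def test_boxed_warning_via_unnumbered_banner(self):
        sections = structure.extract_ae_sections(FULL_TEXT)
        boxed = sections[0]
        assert boxed.kind == structure.BOXED_WARNING
        assert boxed.title_text == "WARNING: SERIOUS RISKS"
        assert "Severe events" in boxed.body
        assert "INDICATIONS" not in boxed.body


class TestSubsections:
    def setup_method(self):
        sections = structure.extract_ae_sections(FULL_TEXT)
        self.by_kind = {s.kind: structure.split_subsections(s) for s in sections}

    def test_numbered_subsections_split(self):
        section = self.by_kind[structure.ADVERSE_REACTIONS]
        numbers = [sub.number for sub in section.subsections]
        assert numbers == ["", "6.1", "6.2"]
        assert section.subsections[1].title == "Clinical Trials Experience"

    def test_decimal_percent_does_not_split(self):
        # "5.2% (e.g., ...)" sits inside 5.1's prose and must not create a
        # phantom subsection; the real 5.2 sub-title still does
        section = self.by_kind[structure.WARNINGS_PRECAUTIONS]
        numbers = [sub.number for sub in section.subsections]
        assert numbers == ["", "5.1", "5.2"]
        assert "5.2%" in section.subsections[1].text

    def test_unnumbered_section_gets_implicit_subsection(self):
        boxed = self.by_kind[structure.BOXED_WARNING]
        assert len(boxed.subsections) == 1
        assert boxed.subsections[0].number == ""
        assert boxed.subsections[0].text == boxed.body

    def test_subsection_concatenation_reproduces_body(self):
        for section in self.by_kind.values():
            joined = "".join(sub.text for sub in section.subsections)
            assert " ".join(joined.split()) == " ".join(section.body.split())


class TestSentences:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("Nausea occurred. Vomiting occurred.", 2),
            ("Rates were 5.2% (e.g., in adults).", 1),
            ("See Dr. Smith for details. Then stop.", 2),
            ("Value was 3.5 mg. Next dose differs.", 2),
            ("One sentence without terminal punctuation", 1),
            ("", 0),
        ],
    )
    def test_sentence_counts(self, text, expected):
        assert len(structure.split_sentence_spans(text)) == expected

    def test_spans_map_back_to_text(self):
        text = "First item here. Second item (e.g., a case). Third one."
        sub = structure.Subsection("", "", text, 0, len(text))
        structure.split_sentences(sub)
        assert [s.text for s in sub.sentences] == [
            "First item here.",
            "Second item (e.g., a case).",
            "Third one.",
        ]
        for sentence in sub.sentences:
            assert text[sentence.start : sentence.end] == sentence.text

    def test_concatenation_invariant(self):
        text = "A first one. Then a second! And a third? Yes."
        spans = structure.split_sentence_spans(text)
        joined = " ".join(text[a:b] for a, b in spans)
        assert " ".join(joined.split()) == " ".join(text.split())


def test_build_document_deterministic(simple_pair):
    from labeldiff import report

    doc1 = report.load_label(simple_pair.old_pdf)
    doc2 = report.load_label(simple_pair.old_pdf)
    assert doc1 == doc2
    kinds = [s.kind for s in doc1.ae_sections]
    assert kinds == list(structure.SECTION_KINDS)
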