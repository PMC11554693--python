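"""Labeling document structure.

Partitions reading-ordered text into the three major components of a
prescribing-information document (Highlights, Contents, Full Prescribing
Information) and builds the tree of the five AE-related sections — Boxed
Warning; Contraindications (4); Warnings and Precautions (5); Adverse
Reactions (6); Drug Interactions (7) — their numbered subsections, and
sentences with character spans.

Section titles are located with a gradient strategy: the numbered line-start
form (``6 ADVERSE REACTIONS`` / ``6. ADVERSE REACTIONS``) first, falling back
to the bare all-caps title when a label omits the number.  Subsection titles
are found by the dotted-number pattern (``.1`` followed by a space and a
capital letter) guarded by the enclosing section's own number, so percentages
like ``5.2%`` in prose never split a section.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .ingest import TextBlock, match_component_heading

logger = logging.getLogger(__name__)

__all__ = [
    "SECTION_KINDS",
    "SECTION_DEFS",
    "Sentence",
    "Subsection",
    "Section",
    "LabelDocument",
    "segment_components",
    "extract_ae_sections",
    "split_subsections",
    "split_sentences",
    "build_document",
]

BOXED_WARNING = "boxed_warning"
CONTRAINDICATIONS = "contraindications_4"
WARNINGS_PRECAUTIONS = "warnings_precautions_5"
ADVERSE_REACTIONS = "adverse_reactions_6"
DRUG_INTERACTIONS = "drug_interactions_7"

SECTION_KINDS = (
    BOXED_WARNING,
    CONTRAINDICATIONS,
    WARNINGS_PRECAUTIONS,
    ADVERSE_REACTIONS,
    DRUG_INTERACTIONS,
)

# kind -> (section number or None, canonical all-caps title variants).
# Titles are configurable because real labels vary ("BOXED WARNING" vs the
# "WARNING: <risk>" banner); matching is case-sensitive on these strings.
SECTION_DEFS: dict[str, tuple[str | None, tuple[str, ...]]] = {
    BOXED_WARNING: (None, ("BOXED WARNING", "WARNING")),
    CONTRAINDICATIONS: ("4", ("CONTRAINDICATIONS",)),
    WARNINGS_PRECAUTIONS: ("5", ("WARNINGS AND PRECAUTIONS",)),
    ADVERSE_REACTIONS: ("6", ("ADVERSE REACTIONS",)),
    DRUG_INTERACTIONS: ("7", ("DRUG INTERACTIONS",)),
}


@dataclass
class Sentence:
    text: str
    start: int  # offsets into the owning subsection's text
    end: int


@dataclass
class Subsection:
    number: str  # "6.1", or "" for the implicit leading subsection
    title: str
    text: str
    start: int = 0  # offsets into the owning section's body
    end: int = 0
    sentences: list[Sentence] = field(default_factory=list)


@dataclass
class Section:
    kind: str
    number: str | None
    title_text: str
    body: str
    start: int = 0  # offsets into full_text
    end: int = 0
    subsections: list[Subsection] = field(default_factory=list)


@dataclass
class LabelDocument:
    source_name: str
    components: dict[str, str]
    ae_sections: list[Section] = field(default_factory=list)

    def section(self, kind: str) -> Section | None:
        for section in self.ae_sections:
            if section.kind == kind:
                return section
        return None


# ---------------------------------------------------------------------------
# components


def segment_components(ordered_blocks: Sequence[TextBlock]) -> dict[str, str]:
    """Partition ordered body text into highlights / contents / full_text.

    Text preceding the first heading is attached to the first component that
    follows (labels open with a product banner above the Highlights heading).
    With no component heading anywhere, everything becomes full_text and a
    warning is logged.
    """
    parts: dict[str, list[str]] = {"highlights": [], "contents": [], "full_text": []}
    current: str | None = None
    prelude: list[str] = []
    for block in ordered_blocks:
        name = match_component_heading(block.text)
        if name is not None:
            current = name
            if prelude:
                parts[current] = prelude + parts[current]
                prelude = []
        if current is None:
            prelude.append(block.text)
        else:
            parts[current].append(block.text)
    if current is None:
        logger.warning(
            "no component heading found; treating the whole document as full text"
        )
        parts["full_text"] = prelude
    return {name: "\n".join(chunks) for name, chunks in parts.items()}


# ---------------------------------------------------------------------------
# AE sections


_TOP_LEVEL_TITLE = re.compile(r"(?m)^[ \t]*(\d{1,2})\.?[ \t]+[A-Z][A-Z0-9 ,&/\-]*[ \t]*$")


def _numbered_pattern(number: str, title: str) -> re.Pattern[str]:
    return re.compile(
        rf"(?m)^[ \t]*{re.escape(number)}\.?[ \t]+{re.escape(title)}\b[^\n]*"
    )


def _unnumbered_pattern(title: str) -> re.Pattern[str]:
    return re.compile(rf"(?m)^[ \t]*{re.escape(title)}\b[^\n]*")


def extract_ae_sections(
    full_text: str,
    section_defs: Mapping[str, tuple[str | None, tuple[str, ...]]] | None = None,
) -> list[Section]:
    """Locate the five AE-related sections in the full-text component.

    Each section body runs from the end of its title line to the start of the
    next top-level section title (of any section, AE-related or not) or the
    end of the document.  Sections a label does not contain are omitted.
    Duplicate matches keep the first occurrence and log a warning.
    """
    defs = dict(section_defs or SECTION_DEFS)

    boundaries: set[int] = set()
    for match in _TOP_LEVEL_TITLE.finditer(full_text):
        boundaries.add(match.start())

    found: list[Section] = []
    for kind, (number, titles) in defs.items():
        match = None
        if number is not None:
            for title in titles:
                candidates = list(_numbered_pattern(number, title).finditer(full_text))
                if candidates:
                    match = candidates[0]
                    if len(candidates) > 1:
                        logger.warning(
                            "duplicate title for %s; keeping the first match", kind
                        )
                    break
        if match is None:
            for title in titles:
                candidates = list(_unnumbered_pattern(title).finditer(full_text))
                if candidates:
                    match = candidates[0]
                    if len(candidates) > 1:
                        logger.warning(
                            "duplicate title for %s; keeping the first match", kind
                        )
                    break
        if match is None:
            continue
        found.append(
            Section(
                kind=kind,
                number=number,
                title_text=match.group(0).strip(),
                body="",
                start=match.start(),
                end=match.end(),
            )
        )
        boundaries.add(match.start())

    found.sort(key=lambda s: s.start)
    ordered_bounds = sorted(boundaries)
    for section in found:
        body_start = section.end
        next_bounds = [b for b in ordered_bounds if b > section.start]
        body_end = next_bounds[0] if next_bounds else len(full_text)
        section.body = full_text[body_start:body_end].strip("\n")
        section.end = body_end
    return found


# ---------------------------------------------------------------------------
# subsections


def _subsection_pattern(section_number: str) -> re.Pattern[str]:
    # The dotted-number pattern with the enclosing section number as prefix
    # guard: "6.1 Clinical" splits section 6, "5.2% of patients" never does
    # (no capital after the space requirement fails on "% ...").
    return re.compile(
        rf"(?<![\d.]){re.escape(section_number)}\.(\d+)(?=\s[A-Z])"
    )


def split_subsections(section: Section) -> Section:
    """Populate ``section.subsections`` from dotted sub-titles.

    Text before the first sub-title — and the whole body when there are no
    sub-titles (Boxed Warning, unnumbered sections) — becomes an implicit
    untitled subsection, so every section has at least one.
    """
    body = section.body
    matches = (
        list(_subsection_pattern(section.number).finditer(body))
        if section.number
        else []
    )
    subsections: list[Subsection] = []
    if not matches:
        subsections.append(Subsection("", "", body, 0, len(body)))
    else:
        first = matches[0]
        if body[: first.start()].strip():
            subsections.append(Subsection("", "", body[: first.start()], 0, first.start()))
        for i, match in enumerate(matches):
            end = matches[i + 1].start() if i + 1 < len(matches) else len(body)
            number = f"{section.number}.{match.group(1)}"
            line_end = body.find("\n", match.end())
            if line_end < 0 or line_end > end:
                line_end = end
            title = body[match.end():line_end].strip()
            subsections.append(
                Subsection(number, title, body[match.start():end], match.start(), end)
            )
    section.subsections = subsections
    return section


# ---------------------------------------------------------------------------
# sentences


# Dots in these tokens never terminate a sentence.  Checked case-insensitively
# against the text ending at a candidate boundary.
PROTECTED_ABBREVIATIONS = (
    "e.g.",
    "i.e.",
    "vs.",
    "etc.",
    "et al.",
    "approx.",
    "dr.",
    "mr.",
    "mrs.",
    "ms.",
    "fig.",
    "no.",
    "inc.",
    "ca.",
    "cf.",
    "spp.",
)

_BOUNDARY = re.compile(r"[.!?](?=[)\"']?\s+[A-Z0-9(\"'])")


def split_sentence_spans(text: str) -> list[tuple[int, int]]:
    """0-based half-open character spans of sentences in ``text``.

    A boundary is sentence-final punctuation followed by whitespace and an
    upper-case/numeral/open-paren start; abbreviations from the protection
    list and decimal numbers (whose dot has no following whitespace) do not
    split.
    """
    lowered = text.casefold()
    cuts: list[int] = []
    for match in _BOUNDARY.finditer(text):
        end = match.end()
        prefix = lowered[:end]
        protected = False
        for abbr in PROTECTED_ABBREVIATIONS:
            if prefix.endswith(abbr):
                head = len(prefix) - len(abbr)
                if head == 0 or not prefix[head - 1].isalnum():
                    protected = True
                    break
        if protected:
            continue
        while end < len(text) and text[end] in ")\"'":
            end += 1
        cuts.append(end)
    spans: list[tuple[int, int]] = []
    start = 0
    for cut in cuts + [len(text)]:
        chunk = text[start:cut]
        lead = len(chunk) - len(chunk.lstrip())
        trail = len(chunk) - len(chunk.rstrip())
        if chunk.strip():
            spans.append((start + lead, cut - trail))
        start = cut
    return spans


def split_sentences(subsection: Subsection) -> Subsection:
    """Populate ``subsection.sentences`` (each with its source span).

    The sub-title line is kept out of the sentence stream: sentences cover
    the running text after the title.
    """
    text = subsection.text
    offset = 0
    if subsection.number:
        line_end = text.find("\n")
        offset = line_end + 1 if line_end >= 0 else len(text)
    spans = split_sentence_spans(text[offset:])
    subsection.sentences = [
        Sentence(text[offset + a : offset + b], offset + a, offset + b)
        for a, b in spans
    ]
    return subsection


# ---------------------------------------------------------------------------
# document assembly


def build_document(
    ordered_blocks: Sequence[TextBlock],
    source_name: str = "",
    section_defs: Mapping[str, tuple[str | None, tuple[str, ...]]] | None = None,
) -> LabelDocument:
    """Assemble the full structure tree from reading-ordered blocks."""
    components = segment_components(ordered_blocks)
    sections = extract_ae_sections(components["full_text"], section_defs)
    for section in sections:
        split_subsections(section)
        for subsection in section.subsections:
            split_sentences(subsection)
    return LabelDocument(
        source_name=source_name, components=components, ae_sections=sections
    )
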