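"""Synthetic labeling-PDF pairs with ground truth.

Real prescribing-information PDFs cannot ship with the package, so every
pipeline stage is exercised against generated pairs: two versions of a
labeling document rendered as real multi-page PDFs, with a manifest that
records exactly which AE-term changes were injected where.  The generator
emulates the layout variants the pipeline must survive — two-column
Highlights/Contents front matter (optionally sharing a page), a
single-column full text with numbered sections and subsections, and the
four footer/header dialects (``Page x of y`` + ``Reference ID:``, a bare
page number at the bottom, no page number, a page number in the header).

Rendering is intentionally plain (fixed Helvetica, explicit line placement,
uncompressed content streams) so extraction round-trips exactly and the same
seed reproduces byte-identical files.
"""

from __future__ import annotations

import json
import random
import re
import textwrap
from dataclasses import asdict, dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

from . import structure
from .classify import NEWLY_ADDED, PRE_EXISTING, REMOVED, _term_identity
from .detect import TermDictionary, load_dictionary, normalize_term
from .evaluate import ReviewRecord

__all__ = [
    "FixtureSpecError",
    "InjectedChange",
    "PairSpec",
    "LabelPairManifest",
    "GeneratedPair",
    "demo_dictionary_paths",
    "load_demo_dictionary",
    "generate_pair",
    "generate_annotations",
    "random_pair_spec",
    "sample_pair_specs",
    "FOOTER_STYLES",
]

FOOTER_STYLES = ("page_x_of_y", "bare_number", "none", "header_number")

PAGE_WIDTH = 612.0
PAGE_HEIGHT = 792.0


class FixtureSpecError(ValueError):
    """The pair specification is internally inconsistent."""


# ---------------------------------------------------------------------------
# minimal PDF writer


def _escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace("(", "\\(").replace(")", "\\)")


class PdfWriter:
    """Writes single-font, uncompressed-stream PDFs with absolute text
    placement (top-left-origin y, like the extractor's output)."""

    def __init__(self, width: float = PAGE_WIDTH, height: float = PAGE_HEIGHT):
        self.width = width
        self.height = height
        self.pages: list[list[tuple[float, float, float, str]]] = []

    def add_page(self) -> int:
        self.pages.append([])
        return len(self.pages) - 1

    def draw_text(
        self, page: int, x: float, y_top: float, text: str, size: float = 10.0
    ) -> None:
        if text:
            self.pages[page].append((x, y_top, size, text))

    def tobytes(self) -> bytes:
        n_pages = max(1, len(self.pages))
        pages = self.pages or [[]]
        body: dict[int, bytes] = {}
        kids = b" ".join(b"%d 0 R" % (4 + 2 * i) for i in range(n_pages))
        body[1] = b"<< /Type /Catalog /Pages 2 0 R >>"
        body[2] = (
            b"<< /Type /Pages /Kids [" + kids + b"] /Count %d "
            b"/MediaBox [0 0 %d %d] >>" % (n_pages, int(self.width), int(self.height))
        )
        body[3] = b"<< /Type /Font /Subtype /Type1 /BaseFont /Helvetica >>"
        for i, lines in enumerate(pages):
            page_num, content_num = 4 + 2 * i, 5 + 2 * i
            body[page_num] = (
                b"<< /Type /Page /Parent 2 0 R /Contents %d 0 R "
                b"/Resources << /Font << /F1 3 0 R >> >> >>" % content_num
            )
            ops = [
                "BT /F1 %g Tf %g %g Td (%s) Tj ET"
                % (size, x, self.height - y_top, _escape(text))
                for (x, y_top, size, text) in lines
            ]
            stream = "\n".join(ops).encode("cp1252")
            body[content_num] = (
                b"<< /Length %d >>\nstream\n" % len(stream)
                + stream
                + b"\nendstream"
            )
        data = b"%PDF-1.4\n"
        offsets: dict[int, int] = {}
        for num in sorted(body):
            offsets[num] = len(data)
            data += b"%d 0 obj\n" % num + body[num] + b"\nendobj\n"
        xref_offset = len(data)
        max_num = max(body)
        data += b"xref\n0 %d\n" % (max_num + 1)
        data += b"0000000000 65535 f \n"
        for num in range(1, max_num + 1):
            data += b"%010d 00000 n \n" % offsets.get(num, 0)
        data += (
            b"trailer\n<< /Size %d /Root 1 0 R >>\nstartxref\n%d\n%%%%EOF\n"
            % (max_num + 1, xref_offset)
        )
        return data


# ---------------------------------------------------------------------------
# demo dictionary and vocabulary


def demo_dictionary_paths() -> tuple[Path, Path]:
    """Paths of the bundled demo term list and stoplist."""
    data = resources.files("labeldiff") / "data"
    return Path(str(data / "demo_terms.txt")), Path(str(data / "demo_stoplist.txt"))


def load_demo_dictionary() -> TermDictionary:
    terms, stop = demo_dictionary_paths()
    return load_dictionary(terms, stop)


# Filler prose deliberately free of demo-dictionary terms (as substrings), so
# planted terms are the only detectable AEs; a unit test enforces this.
_FILLER_SENTENCES = (
    "The recommended starting dose is one tablet taken once daily with food.",
    "Monitor liver enzyme values before treatment and monthly thereafter.",
    "No dose adjustment is needed for patients with mild renal impairment.",
    "Advise patients to swallow the tablet whole with a glass of water.",
    "Exposure increased in proportion to dose across the studied range.",
    "Median time to peak plasma concentration was two hours after dosing.",
    "Treatment should be discontinued if severe reactions develop.",
    "The safety profile was consistent across the studied age groups.",
    "Store the product at room temperature away from direct light.",
    "Counsel patients about the importance of adherence to therapy.",
    "Efficacy was established in two randomized controlled studies.",
    "Plasma protein binding is approximately ninety percent in vitro.",
)

_AE_SENTENCE_TEMPLATES = (
    "Cases of {term} were reported in patients receiving the product.",
    "In controlled studies, {term} occurred more often than with placebo.",
    "Postmarketing reports include {term} in a small number of patients.",
    "The most common reaction leading to discontinuation was {term}.",
)

_HIGHLIGHTS_LEFT = (
    "These highlights do not include the complete information needed to "
    "use the product safely and effectively.",
    "See the complete prescribing information below.",
)
_HIGHLIGHTS_RIGHT = (
    "Initial U.S. approval followed the standard review process.",
    "Report suspected reactions to the national reporting program.",
)

_CONTENTS_LEFT = (
    "1 INDICATIONS AND USAGE",
    "2 DOSAGE AND ADMINISTRATION",
    "4 CONTRAINDICATIONS",
    "5 WARNINGS AND PRECAUTIONS",
)
_CONTENTS_RIGHT = (
    "6 ADVERSE REACTIONS",
    "7 DRUG INTERACTIONS",
    "8 USE IN SPECIFIC POPULATIONS",
)

# section kind -> subsection slots the generator can place sentences in
# ("" is the implicit text before the first numbered sub-title)
_SECTION_SLOTS: dict[str, tuple[str, ...]] = {
    structure.BOXED_WARNING: ("",),
    structure.CONTRAINDICATIONS: ("",),
    structure.WARNINGS_PRECAUTIONS: ("", "5.1", "5.2"),
    structure.ADVERSE_REACTIONS: ("", "6.1", "6.2"),
    structure.DRUG_INTERACTIONS: ("",),
}

_SUBSECTION_TITLES = {
    "5.1": "Hepatic Effects",
    "5.2": "Use With Central Depressants",
    "6.1": "Clinical Trials Experience",
    "6.2": "Postmarketing Experience",
}

_SECTION_TITLES = {
    structure.BOXED_WARNING: "WARNING: SERIOUS RISKS",
    structure.CONTRAINDICATIONS: "4 CONTRAINDICATIONS",
    structure.WARNINGS_PRECAUTIONS: "5 WARNINGS AND PRECAUTIONS",
    structure.ADVERSE_REACTIONS: "6 ADVERSE REACTIONS",
    structure.DRUG_INTERACTIONS: "7 DRUG INTERACTIONS",
}


# ---------------------------------------------------------------------------
# specification and manifest


@dataclass(frozen=True)
class InjectedChange:
    term: str
    section_kind: str
    subsection: str  # "", "6.1", ...
    change_type: str  # newly_added | removed | pre_existing
    also_elsewhere_in_major_section: bool = False


@dataclass(frozen=True)
class PairSpec:
    pair_id: str = "pair"
    footer_style: str = "page_x_of_y"
    two_column_front: bool = True
    shared_page_components: bool = True
    include_boxed_warning: bool = True
    changes: tuple[InjectedChange, ...] = ()

    def validate(self) -> None:
        if self.footer_style not in FOOTER_STYLES:
            raise FixtureSpecError(f"unknown footer style {self.footer_style!r}")
        for change in self.changes:
            if change.section_kind not in _SECTION_SLOTS:
                raise FixtureSpecError(
                    f"unknown section {change.section_kind!r}"
                )
            if (
                change.section_kind == structure.BOXED_WARNING
                and not self.include_boxed_warning
            ):
                raise FixtureSpecError(
                    "change targets the boxed warning but the spec omits it"
                )
            if change.subsection not in _SECTION_SLOTS[change.section_kind]:
                raise FixtureSpecError(
                    f"section {change.section_kind} has no subsection "
                    f"{change.subsection!r}"
                )
            if change.change_type not in (NEWLY_ADDED, REMOVED, PRE_EXISTING):
                raise FixtureSpecError(
                    f"unknown change type {change.change_type!r}"
                )


@dataclass
class LabelPairManifest:
    pair_id: str
    seed: int
    footer_style: str
    two_column_front: bool
    shared_page_components: bool
    include_boxed_warning: bool
    changes: list[InjectedChange]
    old_text: str  # reading-ordered source text of each version
    new_text: str
    old_sections: dict[str, str]  # section kind -> body text
    new_sections: dict[str, str]

    def planted_newly_added(self) -> set[tuple[str, str]]:
        """(term identity, section kind) pairs the classifier must report."""
        return {
            (_term_identity(normalize_term(c.term)), c.section_kind)
            for c in self.changes
            if c.change_type == NEWLY_ADDED and not c.also_elsewhere_in_major_section
        }

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "LabelPairManifest":
        raw = json.loads(text)
        raw["changes"] = [InjectedChange(**c) for c in raw["changes"]]
        return cls(**raw)


@dataclass
class GeneratedPair:
    old_pdf: bytes
    new_pdf: bytes
    manifest: LabelPairManifest


# ---------------------------------------------------------------------------
# document content assembly


def _base_content(
    rng: random.Random, spec: PairSpec, pool: list[str]
) -> dict[str, dict[str, list[str]]]:
    """Shared (old==new) section content before change injection."""
    content: dict[str, dict[str, list[str]]] = {}
    for kind, slots in _SECTION_SLOTS.items():
        if kind == structure.BOXED_WARNING and not spec.include_boxed_warning:
            continue
        content[kind] = {}
        for slot in slots:
            sentences = [rng.choice(_FILLER_SENTENCES)]
            if rng.random() < 0.7 and pool:
                term = pool.pop()
                sentences.append(
                    rng.choice(_AE_SENTENCE_TEMPLATES).format(term=term)
                )
            sentences.append(rng.choice(_FILLER_SENTENCES))
            content[kind][slot] = sentences
    return content


def _ae_sentence(rng: random.Random, term: str) -> str:
    return rng.choice(_AE_SENTENCE_TEMPLATES).format(term=term)


def _apply_changes(
    rng: random.Random,
    base: dict[str, dict[str, list[str]]],
    changes: Sequence[InjectedChange],
) -> tuple[dict[str, dict[str, list[str]]], dict[str, dict[str, list[str]]]]:
    old = {k: {s: list(v) for s, v in slots.items()} for k, slots in base.items()}
    new = {k: {s: list(v) for s, v in slots.items()} for k, slots in base.items()}
    for change in changes:
        sentence = _ae_sentence(rng, change.term)
        section, slot = change.section_kind, change.subsection
        if change.change_type == NEWLY_ADDED:
            new[section][slot].append(sentence)
            if change.also_elsewhere_in_major_section:
                slots = _SECTION_SLOTS[section]
                other = next((s for s in slots if s != slot), slot)
                old[section][other].append(_ae_sentence(rng, change.term))
        elif change.change_type == REMOVED:
            old[section][slot].append(sentence)
        else:  # pre-existing: present in both versions
            old[section][slot].append(sentence)
            new[section][slot].append(sentence)
    return old, new


# ---------------------------------------------------------------------------
# layout / rendering


_BODY_X = 36.0
_RIGHT_X = 320.0
_BODY_SIZE = 10.0
_HEAD_SIZE = 11.0
_LEADING = 12.0
_HEAD_GAP = 24.0
_TOP_Y = 48.0
_MAX_Y = 716.0
_FULL_WRAP = 88
_COL_WRAP = 44


def _wrap(text: str, width: int) -> list[str]:
    return textwrap.wrap(text, width=width, break_on_hyphens=False) or [text]


class _Layout:
    """Greedy top-down page layout with footer decoration."""

    def __init__(self, writer: PdfWriter, footer_style: str):
        self.writer = writer
        self.footer_style = footer_style
        self.page = writer.add_page()
        self.y = _TOP_Y

    def _ensure(self, needed: float) -> None:
        if self.y + needed > _MAX_Y:
            self.page = self.writer.add_page()
            self.y = _TOP_Y

    def heading(self, text: str) -> None:
        self._ensure(_HEAD_GAP + _LEADING)
        self.y += _HEAD_GAP
        self.writer.draw_text(self.page, _BODY_X, self.y, text, _HEAD_SIZE)
        self.y += _HEAD_GAP

    def paragraph(self, text: str) -> None:
        lines = _wrap(text, _FULL_WRAP)
        self._ensure(len(lines) * _LEADING + _HEAD_GAP)
        self.y += _HEAD_GAP
        for line in lines:
            self.writer.draw_text(self.page, _BODY_X, self.y, line, _BODY_SIZE)
            self.y += _LEADING
        self.y -= _LEADING

    def columns(self, left: Sequence[str], right: Sequence[str]) -> None:
        left_lines = [l for text in left for l in _wrap(text, _COL_WRAP)]
        right_lines = [l for text in right for l in _wrap(text, _COL_WRAP)]
        rows = max(len(left_lines), len(right_lines))
        self._ensure(rows * _LEADING + _HEAD_GAP)
        self.y += _HEAD_GAP
        for i, line in enumerate(left_lines):
            self.writer.draw_text(
                self.page, _BODY_X, self.y + i * _LEADING, line, _BODY_SIZE
            )
        for i, line in enumerate(right_lines):
            self.writer.draw_text(
                self.page, _RIGHT_X, self.y + i * _LEADING, line, _BODY_SIZE
            )
        self.y += (rows - 1) * _LEADING

    def page_break(self) -> None:
        self.page = self.writer.add_page()
        self.y = _TOP_Y

    def decorate(self) -> None:
        total = len(self.writer.pages)
        for index in range(total):
            number = index + 1
            if self.footer_style == "page_x_of_y":
                self.writer.draw_text(
                    index, 270.0, 756.0, f"Page {number} of {total}", _BODY_SIZE
                )
                self.writer.draw_text(
                    index, 36.0, 770.0, "Reference ID: 4731209", _BODY_SIZE
                )
            elif self.footer_style == "bare_number":
                self.writer.draw_text(index, 300.0, 760.0, str(number), _BODY_SIZE)
            elif self.footer_style == "header_number":
                self.writer.draw_text(index, 300.0, 24.0, str(number), _BODY_SIZE)


def _render_version(
    spec: PairSpec, content: dict[str, dict[str, list[str]]]
) -> tuple[bytes, str, dict[str, str]]:
    """Render one version; returns (pdf bytes, reading-order text, section bodies)."""
    writer = PdfWriter()
    layout = _Layout(writer, spec.footer_style)
    source: list[str] = []

    def emit_front(heading: str, left: Sequence[str], right: Sequence[str]) -> None:
        layout.heading(heading)
        source.append(heading)
        if spec.two_column_front:
            layout.columns(left, right)
        else:
            for text in list(left) + list(right):
                layout.paragraph(text)
        source.extend(_wrap_block(left) + _wrap_block(right))

    def _wrap_block(entries: Sequence[str]) -> list[str]:
        return [entry for entry in entries]

    emit_front(
        "HIGHLIGHTS OF PRESCRIBING INFORMATION", _HIGHLIGHTS_LEFT, _HIGHLIGHTS_RIGHT
    )
    if not spec.shared_page_components:
        layout.page_break()
    emit_front(
        "FULL PRESCRIBING INFORMATION: CONTENTS", _CONTENTS_LEFT, _CONTENTS_RIGHT
    )

    layout.page_break()
    layout.heading("FULL PRESCRIBING INFORMATION")
    source.append("FULL PRESCRIBING INFORMATION")

    section_bodies: dict[str, str] = {}

    def emit_section(kind: str | None, title: str, slots: dict[str, list[str]] | None) -> None:
        layout.heading(title)
        source.append(title)
        collected: list[str] = []
        if slots is None:
            return
        for slot, sentences in slots.items():
            if slot:
                sub_title = f"{slot} {_SUBSECTION_TITLES[slot]}"
                layout.heading(sub_title)
                source.append(sub_title)
                collected.append(sub_title)
            paragraph = " ".join(sentences)
            layout.paragraph(paragraph)
            source.append(paragraph)
            collected.append(paragraph)
        if kind is not None:
            section_bodies[kind] = "\n".join(collected)

    if spec.include_boxed_warning and structure.BOXED_WARNING in content:
        emit_section(
            structure.BOXED_WARNING,
            _SECTION_TITLES[structure.BOXED_WARNING],
            content[structure.BOXED_WARNING],
        )
    emit_section(None, "1 INDICATIONS AND USAGE", {"": [_FILLER_SENTENCES[0]]})
    emit_section(None, "2 DOSAGE AND ADMINISTRATION", {"": [_FILLER_SENTENCES[1]]})
    for kind in (
        structure.CONTRAINDICATIONS,
        structure.WARNINGS_PRECAUTIONS,
        structure.ADVERSE_REACTIONS,
        structure.DRUG_INTERACTIONS,
    ):
        emit_section(kind, _SECTION_TITLES[kind], content[kind])
    emit_section(None, "8 USE IN SPECIFIC POPULATIONS", {"": [_FILLER_SENTENCES[2]]})

    layout.decorate()
    return writer.tobytes(), "\n".join(source), section_bodies


# ---------------------------------------------------------------------------
# public generator API


def generate_pair(spec: PairSpec, seed: int) -> GeneratedPair:
    """Render both versions of a labeling pair plus its ground-truth manifest.

    Deterministic: the same (spec, seed) yields byte-identical PDFs and an
    identical manifest.
    """
    spec.validate()
    rng = random.Random(seed)
    dictionary = load_demo_dictionary()
    change_terms = {normalize_term(c.term) for c in spec.changes}
    pool = sorted(dictionary.terms - change_terms)
    rng.shuffle(pool)
    base = _base_content(rng, spec, pool)
    old_content, new_content = _apply_changes(rng, base, spec.changes)
    old_pdf, old_text, old_sections = _render_version(spec, old_content)
    new_pdf, new_text, new_sections = _render_version(spec, new_content)
    manifest = LabelPairManifest(
        pair_id=spec.pair_id,
        seed=seed,
        footer_style=spec.footer_style,
        two_column_front=spec.two_column_front,
        shared_page_components=spec.shared_page_components,
        include_boxed_warning=spec.include_boxed_warning,
        changes=list(spec.changes),
        old_text=old_text,
        new_text=new_text,
        old_sections=old_sections,
        new_sections=new_sections,
    )
    return GeneratedPair(old_pdf=old_pdf, new_pdf=new_pdf, manifest=manifest)


# ---------------------------------------------------------------------------
# automatic reviewer annotations


def _is_word_subphrase(short: str, long: str) -> bool:
    return short != long and f" {short} " in f" {long} "


def _in_text(term: str, text: str) -> bool:
    words = [re.escape(w) for w in term.split()]
    pattern = r"(?<!\w)" + r"\s+".join(words) + r"(?!\w)"
    return re.search(pattern, text, re.IGNORECASE) is not None


def generate_annotations(
    manifest: LabelPairManifest,
    newly_added: Sequence,
    pair_id: str | None = None,
) -> list[ReviewRecord]:
    """Play the reviewer: categorize tool findings against the manifest.

    ``newly_added`` is the tool's list of newly-added :class:`AEChange`
    findings (or any objects with ``term_normalized`` and ``section_kind``).
    Findings matching a planted change are category 2; proper sub-terms of a
    planted term category 4 (inaccurate); terms present in the old version's
    same major section category 3 (not new); anything else category 5
    (irrelevant).  Planted changes the tool missed become category 6 rows,
    and a genuinely changeless pair with no findings yields one category-1
    record.
    """
    if pair_id is not None and pair_id != manifest.pair_id:
        raise FixtureSpecError(
            f"pair_id mismatch: {pair_id!r} vs manifest {manifest.pair_id!r}"
        )
    planted = manifest.planted_newly_added()
    records: list[ReviewRecord] = []
    confirmed: set[tuple[str, str]] = set()
    for finding in newly_added:
        term = _term_identity(finding.term_normalized)
        section = finding.section_kind
        key = (term, section)
        if key in planted:
            category, comment = 2, "confirmed new AE"
            confirmed.add(key)
        elif any(
            section == p_section and _is_word_subphrase(term, p_term)
            for p_term, p_section in planted
        ):
            category, comment = 4, "picked up partial term"
        elif _in_text(term, manifest.old_sections.get(section, "")):
            category, comment = 3, "already in previous labeling"
        else:
            category, comment = 5, "not an adverse event change"
        records.append(
            ReviewRecord(
                pair_id=manifest.pair_id, term=term, category=category, comment=comment
            )
        )
    for term, section in sorted(planted - confirmed):
        records.append(
            ReviewRecord(
                pair_id=manifest.pair_id,
                term=term,
                category=6,
                comment=f"missed in {section}",
            )
        )
    if not records and not manifest.changes:
        records.append(
            ReviewRecord(
                pair_id=manifest.pair_id,
                term=None,
                category=1,
                comment="no AE change in this pair",
            )
        )
    return records


# ---------------------------------------------------------------------------
# random specs for batch runs


def random_pair_spec(
    pair_id: str,
    rng: random.Random,
    n_changes: int | None = None,
    footer_style: str | None = None,
    nested_plant: bool = False,
) -> PairSpec:
    """Draw a random pair specification from the study conditions.

    Footer dialects cycle through all four variants across a batch; each pair
    carries 0-5 injected changes.  ``nested_plant=True`` forces one planted
    ``blood pressure`` addition so nested matching has a contained sub-term
    to (inaccurately) pick up.
    """
    dictionary = load_demo_dictionary()
    footer = footer_style or rng.choice(FOOTER_STYLES)
    include_boxed = rng.random() < 0.7
    if n_changes is None:
        n_changes = rng.randint(0, 5)
    kinds = [k for k in _SECTION_SLOTS if include_boxed or k != structure.BOXED_WARNING]
    pool = sorted(dictionary.terms - {"blood pressure", "pressure"})
    rng.shuffle(pool)
    changes: list[InjectedChange] = []
    if nested_plant:
        changes.append(
            InjectedChange("blood pressure", structure.ADVERSE_REACTIONS, "6.1", NEWLY_ADDED)
        )
    while len(changes) < n_changes and pool:
        kind = rng.choice(kinds)
        slot = rng.choice(_SECTION_SLOTS[kind])
        change_type = rng.choice((NEWLY_ADDED, NEWLY_ADDED, REMOVED, PRE_EXISTING))
        changes.append(InjectedChange(pool.pop(), kind, slot, change_type))
    return PairSpec(
        pair_id=pair_id,
        footer_style=footer,
        two_column_front=rng.random() < 0.8,
        shared_page_components=rng.random() < 0.6,
        include_boxed_warning=include_boxed,
        changes=tuple(changes),
    )


def sample_pair_specs(
    count: int, seed: int, nested_plants: bool = False
) -> list[PairSpec]:
    """A batch of pair specs cycling through the four footer dialects."""
    rng = random.Random(seed)
    specs = []
    for index in range(count):
        specs.append(
            random_pair_spec(
                pair_id=f"pair{index:03d}",
                rng=rng,
                footer_style=FOOTER_STYLES[index % len(FOOTER_STYLES)],
                nested_plant=nested_plants and index % 2 == 0,
            )
        )
    return specs
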