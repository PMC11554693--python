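"""Comparison pipeline orchestration and report writers.

``run_compare`` drives the full pipeline — ingest both PDFs, build the
section trees, align and highlight sentences subsection by subsection,
detect AE terms, classify changes — and the writers serialize the result as
a CSV summary table and a standalone two-column HTML page (old | new), with
change styling for edited text and highlight styling for detected AE terms.
Everything is deterministic: the same inputs produce byte-identical reports.
"""

from __future__ import annotations

import csv
import html
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import __version__ as _version
from . import diff, structure
from .classify import NEWLY_ADDED, PRE_EXISTING, REMOVED, AEChange, classify_changes
from .detect import (
    AEMatch,
    NerAdapter,
    TermDictionary,
    combine_matches,
    match_terms,
    ner_detect,
)
from .ingest import ingest_pdf
from .structure import LabelDocument, Section, Subsection

logger = logging.getLogger(__name__)

__all__ = [
    "CompareConfig",
    "SubsectionComparison",
    "ComparisonReport",
    "load_label",
    "run_compare",
    "write_report_csv",
    "write_report_html",
]


@dataclass
class CompareConfig:
    dictionary: TermDictionary
    nested: bool = False
    ratio_threshold: float = diff.DEFAULT_RATIO_THRESHOLD
    sections: tuple[str, ...] = structure.SECTION_KINDS
    ner_adapter: NerAdapter | None = None


@dataclass
class SubsectionComparison:
    section_kind: str
    number: str
    title: str
    old_sentences: list[str]
    new_sentences: list[str]
    pairs: list[diff.AlignedPair]
    highlights: list[diff.HighlightSpan]
    ae_old: dict[int, list[tuple[int, int]]] = field(default_factory=dict)
    ae_new: dict[int, list[tuple[int, int]]] = field(default_factory=dict)


@dataclass
class ComparisonReport:
    pair_id: str
    subsections: list[SubsectionComparison]
    changes: list[AEChange]
    metadata: dict[str, str]
    warnings: list[str] = field(default_factory=list)

    def changes_of(self, change_type: str) -> list[AEChange]:
        return [c for c in self.changes if c.change_type == change_type]

    @property
    def newly_added(self) -> list[AEChange]:
        return self.changes_of(NEWLY_ADDED)

    @property
    def removed(self) -> list[AEChange]:
        return self.changes_of(REMOVED)

    @property
    def pre_existing(self) -> list[AEChange]:
        return self.changes_of(PRE_EXISTING)


def load_label(pdf_source, source_name: str = "") -> LabelDocument:
    """Ingest one PDF into a structured label document."""
    ordered, _layouts = ingest_pdf(pdf_source)
    return structure.build_document(ordered, source_name=source_name)


# ---------------------------------------------------------------------------
# subsection pairing across versions


def _match_subsections(
    old: Section | None, new: Section | None
) -> list[tuple[Subsection | None, Subsection | None]]:
    """Pair subsections by number, then normalized title, then position."""
    old_subs = list(old.subsections) if old else []
    new_subs = list(new.subsections) if new else []
    pairs: list[tuple[Subsection | None, Subsection | None]] = []
    used_old: set[int] = set()
    used_new: set[int] = set()

    def norm_title(sub: Subsection) -> str:
        return " ".join(sub.title.casefold().split())

    for key_fn in (lambda s: s.number or None, lambda s: norm_title(s) or None):
        new_by_key: dict[str, int] = {}
        for j, sub in enumerate(new_subs):
            key = key_fn(sub)
            if j not in used_new and key is not None and key not in new_by_key:
                new_by_key[key] = j
        for i, sub in enumerate(old_subs):
            key = key_fn(sub)
            if i in used_old or key is None:
                continue
            j = new_by_key.get(key)
            if j is not None and j not in used_new:
                pairs.append((old_subs[i], new_subs[j]))
                used_old.add(i)
                used_new.add(j)
    remaining_old = [i for i in range(len(old_subs)) if i not in used_old]
    remaining_new = [j for j in range(len(new_subs)) if j not in used_new]
    for i, j in zip(remaining_old, remaining_new):
        pairs.append((old_subs[i], new_subs[j]))
    for i in remaining_old[len(remaining_new):]:
        pairs.append((old_subs[i], None))
    for j in remaining_new[len(remaining_old):]:
        pairs.append((None, new_subs[j]))
    pairs.sort(
        key=lambda p: (
            (p[1] or p[0]).number,
            (p[1] or p[0]).start,
        )
    )
    return pairs


# ---------------------------------------------------------------------------
# detection over a document


def _detect_document(
    document: LabelDocument, config: CompareConfig
) -> list[AEMatch]:
    matches: list[AEMatch] = []
    for section in document.ae_sections:
        if section.kind not in config.sections:
            continue
        for subsection in section.subsections:
            for index, sentence in enumerate(subsection.sentences):
                from_dict = match_terms(
                    sentence.text,
                    config.dictionary,
                    nested=config.nested,
                    section_kind=section.kind,
                    subsection=subsection.number,
                    sentence_index=index,
                )
                from_ner = ner_detect(
                    sentence.text,
                    config.ner_adapter,
                    section_kind=section.kind,
                    subsection=subsection.number,
                    sentence_index=index,
                )
                matches.extend(combine_matches(from_dict, from_ner))
    return matches


# ---------------------------------------------------------------------------
# comparison


def run_compare(
    old_pdf, new_pdf, config: CompareConfig, pair_id: str = "pair"
) -> ComparisonReport:
    """Compare two labeling PDFs end to end."""
    from .pdfio import PdfError

    docs: dict[str, LabelDocument] = {}
    for name, source in (("old", old_pdf), ("new", new_pdf)):
        label = str(source) if isinstance(source, (str, Path)) else name
        try:
            docs[name] = load_label(source, source_name=label)
        except PdfError as exc:
            raise type(exc)(f"{label}: {exc}") from exc
    old_doc, new_doc = docs["old"], docs["new"]

    subsections: list[SubsectionComparison] = []
    for kind in structure.SECTION_KINDS:
        if kind not in config.sections:
            continue
        old_section = old_doc.section(kind)
        new_section = new_doc.section(kind)
        if old_section is None and new_section is None:
            continue
        for old_sub, new_sub in _match_subsections(old_section, new_section):
            old_sentences = [s.text for s in old_sub.sentences] if old_sub else []
            new_sentences = [s.text for s in new_sub.sentences] if new_sub else []
            alignment = diff.align_sentences(old_sentences, new_sentences)
            highlights: list[diff.HighlightSpan] = []
            for pair in alignment.pairs:
                if pair.op == diff.REPLACE:
                    highlights.extend(
                        diff.highlight_pair(
                            old_sentences[pair.old_index],
                            new_sentences[pair.new_index],
                            config.ratio_threshold,
                            old_index=pair.old_index,
                            new_index=pair.new_index,
                        )
                    )
            reference = new_sub or old_sub
            comparison = SubsectionComparison(
                section_kind=kind,
                number=reference.number,
                title=reference.title,
                old_sentences=old_sentences,
                new_sentences=new_sentences,
                pairs=alignment.pairs,
                highlights=highlights,
            )
            for side, sentences, store in (
                ("old", old_sentences, comparison.ae_old),
                ("new", new_sentences, comparison.ae_new),
            ):
                for index, text in enumerate(sentences):
                    spans = [
                        m.location.span
                        for m in match_terms(text, config.dictionary, config.nested)
                    ]
                    if spans:
                        store[index] = spans
            subsections.append(comparison)

    old_matches = _detect_document(old_doc, config)
    new_matches = _detect_document(new_doc, config)
    changes = classify_changes(old_matches, new_matches)

    metadata = {
        "tool_version": _version,
        "pair_id": pair_id,
        "dictionary": config.dictionary.source_name,
        "nested_matches": str(config.nested).lower(),
        "ratio_threshold": f"{config.ratio_threshold:g}",
        "sections": ",".join(config.sections),
    }
    return ComparisonReport(
        pair_id=pair_id,
        subsections=subsections,
        changes=changes,
        metadata=metadata,
    )


# ---------------------------------------------------------------------------
# writers


def write_report_csv(report: ComparisonReport, path: str | Path) -> None:
    """Summary table: one row per non-equal sentence pair plus one per AE
    change (newly added / removed / pre-existing)."""
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(
            [
                "row_type",
                "section",
                "subsection",
                "detail",
                "term",
                "old_index",
                "new_index",
                "old_text",
                "new_text",
            ]
        )
        for comparison in report.subsections:
            for pair in comparison.pairs:
                if pair.op == diff.EQUAL:
                    continue
                old_text = (
                    comparison.old_sentences[pair.old_index]
                    if pair.old_index is not None
                    else ""
                )
                new_text = (
                    comparison.new_sentences[pair.new_index]
                    if pair.new_index is not None
                    else ""
                )
                writer.writerow(
                    [
                        "diff",
                        comparison.section_kind,
                        comparison.number,
                        pair.op,
                        "",
                        "" if pair.old_index is None else pair.old_index,
                        "" if pair.new_index is None else pair.new_index,
                        old_text,
                        new_text,
                    ]
                )
        for change in report.changes:
            location = change.new_location or change.old_location
            writer.writerow(
                [
                    "change",
                    change.section_kind,
                    location.subsection if location else "",
                    change.change_type,
                    change.term_normalized,
                    "",
                    "",
                    "",
                    "",
                ]
            )


_CSS = """
body { font-family: sans-serif; margin: 2em; }
table.compare { border-collapse: collapse; width: 100%; margin-bottom: 2em; }
table.compare td { border: 1px solid #ccc; vertical-align: top;
                   width: 50%; padding: 4px 8px; }
.chg { color: #1040c0; font-weight: bold; }
.whole { background: #e8efff; }
.ae { background: #ffe870; }
h3 { margin-bottom: 4px; }
ul.changes li { margin: 2px 0; }
.added { color: #1040c0; }
"""


def _render_text(
    text: str, spans: Sequence[tuple[int, int, str]]
) -> str:
    """HTML for ``text`` with possibly-overlapping classed spans."""
    if not spans:
        return html.escape(text)
    cuts = {0, len(text)}
    for start, end, _cls in spans:
        cuts.add(max(0, start))
        cuts.add(min(len(text), end))
    ordered = sorted(cuts)
    out: list[str] = []
    for a, b in zip(ordered, ordered[1:]):
        classes = sorted(
            {cls for start, end, cls in spans if start <= a and b <= end}
        )
        chunk = html.escape(text[a:b])
        if classes:
            out.append(f'<span class="{" ".join(classes)}">{chunk}</span>')
        else:
            out.append(chunk)
    return "".join(out)


def _sentence_html(
    comparison: SubsectionComparison, side: str, index: int | None
) -> str:
    if index is None:
        return ""
    sentences = (
        comparison.old_sentences if side == "old" else comparison.new_sentences
    )
    text = sentences[index]
    spans: list[tuple[int, int, str]] = []
    for span in comparison.highlights:
        if span.side == side and span.sentence_index == index:
            cls = "whole" if span.granularity == diff.WHOLE_SENTENCE else "chg"
            spans.append((span.char_span[0], span.char_span[1], cls))
    ae_spans = (comparison.ae_old if side == "old" else comparison.ae_new).get(
        index, []
    )
    spans.extend((a, b, "ae") for a, b in ae_spans)
    return _render_text(text, spans)


def write_report_html(report: ComparisonReport, path: str | Path) -> None:
    """Static side-by-side comparison page (old | new) per subsection."""
    parts: list[str] = [
        "<!DOCTYPE html>",
        "<html><head><meta charset='utf-8'>",
        f"<title>Label comparison {html.escape(report.pair_id)}</title>",
        f"<style>{_CSS}</style></head><body>",
        f"<h1>Label comparison: {html.escape(report.pair_id)}</h1>",
    ]
    parts.append("<h2>AE term changes</h2><ul class='changes'>")
    for title, changes in (
        ("Newly added", report.newly_added),
        ("Removed", report.removed),
        ("Pre-existing", report.pre_existing),
    ):
        parts.append(
            f"<li><b>{title} ({len(changes)}):</b> "
            + html.escape(
                ", ".join(f"{c.term_normalized} [{c.section_kind}]" for c in changes)
                or "none"
            )
            + "</li>"
        )
    parts.append("</ul>")
    if report.warnings:
        parts.append("<h2>Warnings</h2><ul>")
        parts.extend(f"<li>{html.escape(w)}</li>" for w in report.warnings)
        parts.append("</ul>")
    for comparison in report.subsections:
        label = f"{comparison.section_kind} {comparison.number}".strip()
        if comparison.title:
            label += f" — {comparison.title}"
        parts.append(f"<h3>{html.escape(label)}</h3>")
        parts.append(
            "<table class='compare'><tr><th>old</th><th>new</th></tr>"
        )
        for pair in comparison.pairs:
            row_class = "" if pair.op == diff.EQUAL else f" class='{pair.op}'"
            parts.append(
                f"<tr{row_class}>"
                f"<td>{_sentence_html(comparison, 'old', pair.old_index)}</td>"
                f"<td>{_sentence_html(comparison, 'new', pair.new_index)}</td>"
                "</tr>"
            )
        parts.append("</table>")
    meta = ", ".join(f"{k}={v}" for k, v in sorted(report.metadata.items()))
    parts.append(f"<p><small>{html.escape(meta)}</small></p>")
    parts.append("</body></html>")
    Path(path).write_text("\n".join(parts), encoding="utf-8")
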