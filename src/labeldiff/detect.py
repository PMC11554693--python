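"""Adverse-event term detection.

Terms are found by case-insensitive dictionary matching at word boundaries
(MedDRA-LLT-style term lists; the licensed MedDRA vocabulary itself is
user-supplied) and, optionally, by a pluggable named-entity-recognition
adapter.  The default result is the union of both sources.

Dictionary matching is greedy-maximal by default: of overlapping candidates
the leftmost-then-longest wins, so ``blood pressure`` suppresses the
contained ``pressure``.  ``nested=True`` reports contained matches as well —
useful to study the inaccurate sub-term findings that pure pattern matching
produces.  A stoplist removes terms that are valid LLTs but almost always
ordinary words in running text ('all', 'high', ...).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Protocol, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "DictionaryError",
    "Location",
    "AEMatch",
    "TermDictionary",
    "NerAdapter",
    "load_dictionary",
    "match_terms",
    "ner_detect",
    "combine_matches",
    "normalize_term",
]

DICTIONARY = "dictionary"
NER = "ner"
BOTH = "both"


class DictionaryError(ValueError):
    """The term dictionary is unusable (empty or unreadable)."""


def normalize_term(text: str) -> str:
    """Case-fold and collapse whitespace; the identity used for matching."""
    return " ".join(text.casefold().split())


@dataclass(frozen=True, order=True)
class Location:
    section_kind: str
    subsection: str
    sentence_index: int
    span: tuple[int, int]  # char offsets within the sentence, half-open


@dataclass(frozen=True)
class AEMatch:
    term_surface: str
    term_normalized: str
    source: str  # dictionary | ner | both
    location: Location


class NerAdapter(Protocol):
    """Contract for a pluggable NER backend.

    Called with a text string; returns ``(char_span, label)`` tuples with
    non-overlapping spans inside the text.  Only label ``"AE"`` is used.
    No model ships with this package.
    """

    def __call__(self, text: str) -> list[tuple[tuple[int, int], str]]: ...


@dataclass(frozen=True)
class TermDictionary:
    terms: frozenset[str]  # normalized, stoplist already removed
    stoplist: frozenset[str]
    source_name: str = ""

    def __post_init__(self) -> None:
        if not self.terms:
            raise DictionaryError("effective term dictionary is empty")
        if self.terms & self.stoplist:
            raise DictionaryError("stoplisted terms present in effective terms")


def _read_terms(path: Path) -> Iterable[str]:
    """One term per line, or TSV ``code<TAB>term``; ``#`` lines ignored."""
    for lineno, raw in enumerate(path.read_text("utf-8").splitlines(), 1):
        if not raw.strip() or raw.lstrip().startswith("#"):
            continue
        if "\t" in raw:
            fields = raw.split("\t")
            if len(fields) != 2 or not fields[1].strip():
                logger.warning("%s:%d: malformed line skipped", path, lineno)
                continue
            yield fields[1].strip()
        else:
            yield raw.strip()


def load_dictionary(
    term_file: str | Path, stoplist_file: str | Path | None = None
) -> TermDictionary:
    """Load and normalize a term list, removing stoplisted entries.

    Raises :class:`DictionaryError` when no effective terms remain.
    """
    term_path = Path(term_file)
    try:
        terms = {normalize_term(t) for t in _read_terms(term_path)}
    except OSError as exc:
        raise DictionaryError(f"cannot read term file {term_path}: {exc}") from exc
    terms.discard("")
    stoplist: set[str] = set()
    if stoplist_file is not None:
        stop_path = Path(stoplist_file)
        try:
            stoplist = {normalize_term(t) for t in _read_terms(stop_path)}
        except OSError as exc:
            raise DictionaryError(
                f"cannot read stoplist {stop_path}: {exc}"
            ) from exc
        stoplist.discard("")
    effective = terms - stoplist
    logger.info(
        "dictionary %s: %d terms, %d stoplisted, %d effective",
        term_path.name,
        len(terms),
        len(terms) - len(effective),
        len(effective),
    )
    if not effective:
        raise DictionaryError(
            f"no effective terms in {term_path} after applying the stoplist"
        )
    return TermDictionary(
        terms=frozenset(effective),
        stoplist=frozenset(stoplist),
        source_name=term_path.name,
    )


# ---------------------------------------------------------------------------
# matching


_PATTERN_CACHE: dict[str, re.Pattern[str]] = {}


def _term_pattern(term: str) -> re.Pattern[str]:
    pattern = _PATTERN_CACHE.get(term)
    if pattern is None:
        words = [re.escape(w) for w in term.split()]
        # word boundaries on both ends; whitespace (incl. a line break)
        # between the words of a multi-word term
        pattern = re.compile(
            r"(?<!\w)" + r"\s+".join(words) + r"(?!\w)", re.IGNORECASE
        )
        _PATTERN_CACHE[term] = pattern
    return pattern


def match_terms(
    text: str,
    dictionary: TermDictionary,
    nested: bool = False,
    *,
    section_kind: str = "",
    subsection: str = "",
    sentence_index: int = 0,
) -> list[AEMatch]:
    """Case-insensitive word-boundary dictionary matches in ``text``.

    ``nested=False`` keeps only maximal matches (leftmost, then longest);
    its output spans never overlap.  ``nested=True`` additionally reports
    matches contained in longer ones.
    """
    candidates: list[tuple[int, int, str]] = []
    for term in dictionary.terms:
        for found in _term_pattern(term).finditer(text):
            candidates.append((found.start(), found.end(), term))
    candidates.sort(key=lambda c: (c[0], -c[1], c[2]))
    if not nested:
        kept: list[tuple[int, int, str]] = []
        cursor = -1
        for start, end, term in candidates:
            if start >= cursor:
                kept.append((start, end, term))
                cursor = end
        candidates = kept
    return [
        AEMatch(
            term_surface=text[start:end],
            term_normalized=term,
            source=DICTIONARY,
            location=Location(section_kind, subsection, sentence_index, (start, end)),
        )
        for start, end, term in candidates
    ]


def ner_detect(
    text: str,
    adapter: NerAdapter | None,
    *,
    section_kind: str = "",
    subsection: str = "",
    sentence_index: int = 0,
) -> list[AEMatch]:
    """Run the NER adapter over ``text``; absent adapter means no matches."""
    if adapter is None:
        logger.debug("no NER adapter configured; dictionary matching only")
        return []
    try:
        raw = adapter(text)
    except Exception as exc:
        raise RuntimeError(
            f"NER adapter failed in section {section_kind!r}, subsection "
            f"{subsection!r}, sentence {sentence_index}: {exc}"
        ) from exc
    matches: list[AEMatch] = []
    for (start, end), label in raw:
        if label != "AE":
            continue
        start = max(0, min(start, len(text)))
        end = max(start, min(end, len(text)))
        if end == start:
            continue
        surface = text[start:end]
        matches.append(
            AEMatch(
                term_surface=surface,
                term_normalized=normalize_term(surface),
                source=NER,
                location=Location(section_kind, subsection, sentence_index, (start, end)),
            )
        )
    return matches


def combine_matches(
    dict_matches: Sequence[AEMatch], ner_matches: Sequence[AEMatch]
) -> list[AEMatch]:
    """Union of the two sources, keyed by (normalized term, location).

    A term both sources found at the same spot is reported once with
    ``source="both"``.  Commutative and idempotent.
    """
    merged: dict[tuple[str, Location], AEMatch] = {}
    for match in list(dict_matches) + list(ner_matches):
        key = (match.term_normalized, match.location)
        existing = merged.get(key)
        if existing is None:
            merged[key] = match
        elif existing.source != match.source:
            merged[key] = replace(existing, source=BOTH)
    return sorted(merged.values(), key=lambda m: (m.location, m.term_normalized))
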