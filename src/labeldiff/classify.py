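"""Change classification for detected AE terms.

A term found in the new document is *newly added* only when its normalized
form appears nowhere in the **same major section** of the old document — a
term in new subsection 6.1 that already occurs anywhere in old section 6
(any subsection) is pre-existing.  The symmetric rule yields *removed* terms.
Each (term, major section, change type) is reported once however often the
term repeats, and a term that moved across major sections counts as newly
added in its new section and removed from its old one.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from typing import Sequence

from .detect import AEMatch, Location
from .structure import SECTION_KINDS

__all__ = ["AEChange", "classify_changes", "NEWLY_ADDED", "REMOVED", "PRE_EXISTING"]

NEWLY_ADDED = "newly_added"
REMOVED = "removed"
PRE_EXISTING = "pre_existing"

_SECTION_ORDER = {kind: i for i, kind in enumerate(SECTION_KINDS)}


@dataclass(frozen=True)
class AEChange:
    term_normalized: str
    change_type: str  # newly_added | removed | pre_existing
    section_kind: str
    new_location: Location | None
    old_location: Location | None


def _term_identity(normalized: str) -> str:
    # trailing punctuation (a period picked up at sentence end, a stray
    # comma) must not make the same term look novel
    return normalized.strip(string.punctuation + " ")


def _terms_by_section(
    matches: Sequence[AEMatch],
) -> dict[str, dict[str, Location]]:
    """section kind -> term identity -> first location (document order)."""
    table: dict[str, dict[str, Location]] = {}
    ordered = sorted(matches, key=lambda m: (m.location, m.term_normalized))
    for match in ordered:
        term = _term_identity(match.term_normalized)
        if not term:
            continue
        table.setdefault(match.location.section_kind, {}).setdefault(
            term, match.location
        )
    return table


def classify_changes(
    old_matches: Sequence[AEMatch], new_matches: Sequence[AEMatch]
) -> list[AEChange]:
    """Partition detected terms into newly added / removed / pre-existing.

    Within each major section, the distinct new-document terms split exactly
    into newly added and pre-existing, and the distinct old-document terms
    into removed and pre-existing.
    """
    old_by_section = _terms_by_section(old_matches)
    new_by_section = _terms_by_section(new_matches)
    changes: list[AEChange] = []
    for section in set(old_by_section) | set(new_by_section):
        old_terms = old_by_section.get(section, {})
        new_terms = new_by_section.get(section, {})
        for term, location in new_terms.items():
            if term in old_terms:
                changes.append(
                    AEChange(term, PRE_EXISTING, section, location, old_terms[term])
                )
            else:
                changes.append(AEChange(term, NEWLY_ADDED, section, location, None))
        for term, location in old_terms.items():
            if term not in new_terms:
                changes.append(AEChange(term, REMOVED, section, None, location))
    changes.sort(
        key=lambda c: (
            _SECTION_ORDER.get(c.section_kind, len(_SECTION_ORDER)),
            c.change_type,
            c.term_normalized,
        )
    )
    return changes
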