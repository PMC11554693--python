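"""Sentence alignment and change highlighting.

Old and new versions of a subsection are aligned sentence-by-sentence with a
longest-common-subsequence (LCS) dynamic program on normalized text
(case-folded, whitespace-collapsed).  Unmatched runs are paired positionally
as replacements; leftovers become insertions or deletions.  For a replaced
pair, a token-level diff decides the display granularity: a sentence with
mostly-changed tokens is flagged whole, a lightly edited one gets precise
token spans — reviewers prefer seeing the countable changes when there are
few, and a single block highlight when the sentence was rewritten.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "AlignedPair",
    "SentenceAlignment",
    "HighlightSpan",
    "align_sentences",
    "highlight_pair",
    "tokenize",
    "lcs_pairs",
    "DEFAULT_RATIO_THRESHOLD",
]

EQUAL = "equal"
REPLACE = "replace"
INSERT = "insert"
DELETE = "delete"

OLD = "old"
NEW = "new"

TOKEN = "token"
WHOLE_SENTENCE = "whole_sentence"

# Fraction of changed tokens above which the whole sentence is highlighted.
DEFAULT_RATIO_THRESHOLD = 0.5


@dataclass(frozen=True)
class AlignedPair:
    op: str
    old_index: int | None
    new_index: int | None


@dataclass
class SentenceAlignment:
    pairs: list[AlignedPair]

    @property
    def equal_count(self) -> int:
        return sum(1 for p in self.pairs if p.op == EQUAL)


@dataclass(frozen=True)
class HighlightSpan:
    side: str  # old | new
    sentence_index: int
    char_span: tuple[int, int]  # 0-based, half-open
    granularity: str  # token | whole_sentence


def normalize_sentence(text: str) -> str:
    return " ".join(text.casefold().split())


def lcs_pairs(a: Sequence[str], b: Sequence[str]) -> list[tuple[int, int]]:
    """Matched (i, j) index pairs of one longest common subsequence.

    Classic O(nm) dynamic program; ties during backtracking prefer consuming
    the old side first, which makes the result deterministic.
    """
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        return []
    table = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n - 1, -1, -1):
        row, nxt = table[i], table[i + 1]
        for j in range(m - 1, -1, -1):
            if a[i] == b[j]:
                row[j] = nxt[j + 1] + 1
            else:
                row[j] = nxt[j] if nxt[j] >= row[j + 1] else row[j + 1]
    pairs: list[tuple[int, int]] = []
    i = j = 0
    while i < n and j < m:
        if a[i] == b[j]:
            pairs.append((i, j))
            i += 1
            j += 1
        elif table[i + 1][j] >= table[i][j + 1]:
            i += 1
        else:
            j += 1
    return pairs


def align_sentences(
    old_sentences: Sequence[str], new_sentences: Sequence[str]
) -> SentenceAlignment:
    """Align two sentence lists; every index appears in exactly one pair."""
    norm_old = [normalize_sentence(s) for s in old_sentences]
    norm_new = [normalize_sentence(s) for s in new_sentences]
    matches = lcs_pairs(norm_old, norm_new)

    pairs: list[AlignedPair] = []

    def fill_gap(o0: int, o1: int, n0: int, n1: int) -> None:
        olds = list(range(o0, o1))
        news = list(range(n0, n1))
        for oi, ni in zip(olds, news):
            pairs.append(AlignedPair(REPLACE, oi, ni))
        for oi in olds[len(news):]:
            pairs.append(AlignedPair(DELETE, oi, None))
        for ni in news[len(olds):]:
            pairs.append(AlignedPair(INSERT, None, ni))

    prev_o = prev_n = 0
    for oi, ni in matches:
        fill_gap(prev_o, oi, prev_n, ni)
        pairs.append(AlignedPair(EQUAL, oi, ni))
        prev_o, prev_n = oi + 1, ni + 1
    fill_gap(prev_o, len(old_sentences), prev_n, len(new_sentences))
    return SentenceAlignment(pairs)


# ---------------------------------------------------------------------------
# token-level highlighting


_TOKEN = re.compile(r"\w+|[^\w\s]+")


def tokenize(text: str) -> list[tuple[str, int, int]]:
    """Maximal word-character runs and punctuation runs, with char spans.

    Punctuation runs are tokens in their own right: punctuation-only edits
    still count as changes.
    """
    return [(m.group(0), m.start(), m.end()) for m in _TOKEN.finditer(text)]


def _changed_runs(
    tokens: list[tuple[str, int, int]], matched: set[int]
) -> list[tuple[int, int]]:
    runs: list[tuple[int, int]] = []
    current: tuple[int, int] | None = None
    for idx, (_, start, end) in enumerate(tokens):
        if idx in matched:
            if current:
                runs.append(current)
                current = None
        else:
            current = (current[0], end) if current else (start, end)
    if current:
        runs.append(current)
    return runs


def highlight_pair(
    old_sentence: str,
    new_sentence: str,
    ratio_threshold: float = DEFAULT_RATIO_THRESHOLD,
    *,
    old_index: int = 0,
    new_index: int = 0,
) -> list[HighlightSpan]:
    """Highlight spans for a replaced sentence pair.

    The changed-token ratio is ``max(changed_old, changed_new) / max(token
    counts)``; above ``ratio_threshold`` one whole-sentence span per side is
    emitted, otherwise one token-granularity span per changed run.
    Identical sentences yield no spans.
    """
    old_tokens = tokenize(old_sentence)
    new_tokens = tokenize(new_sentence)
    matches = lcs_pairs(
        [t[0] for t in old_tokens], [t[0] for t in new_tokens]
    )
    matched_old = {i for i, _ in matches}
    matched_new = {j for _, j in matches}
    changed_old = len(old_tokens) - len(matched_old)
    changed_new = len(new_tokens) - len(matched_new)
    if changed_old == 0 and changed_new == 0:
        return []
    denom = max(len(old_tokens), len(new_tokens))
    ratio = max(changed_old, changed_new) / denom if denom else 0.0
    if ratio > ratio_threshold:
        return [
            HighlightSpan(OLD, old_index, (0, len(old_sentence)), WHOLE_SENTENCE),
            HighlightSpan(NEW, new_index, (0, len(new_sentence)), WHOLE_SENTENCE),
        ]
    spans = [
        HighlightSpan(OLD, old_index, run, TOKEN)
        for run in _changed_runs(old_tokens, matched_old)
    ]
    spans.extend(
        HighlightSpan(NEW, new_index, run, TOKEN)
        for run in _changed_runs(new_tokens, matched_new)
    )
    return spans
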