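"""Tiered evaluation of tool findings against reviewer annotations.

Reviewers place every tool finding (or miss) into one of six categories:

1. *No AE updated* — the pair had no AE change and the tool reported none
   (correct, but excluded from the confusion matrix);
2. *True new AE* — correctly identified;
3. *Not new AE* — the term was already in the previous labeling;
4. *Inaccurate* — partially or incompletely identified (e.g. a sub-term);
5. *Irrelevant* — the picked-up term is not an AE;
6. *Missed* — an AE the tool failed to report.

Because categories 3 and 4 sit between true and false positive, three
scoring tiers re-map them: Tier 1 (most tolerant) counts both as TP, Tier 2
counts 4 as FP, Tier 3 (strictest) counts both as FP.  Category 5 is always
FP and category 6 always FN.  Precision = TP/(TP+FP), recall = TP/(TP+FN),
F1 the harmonic mean; a zero denominator makes the metric undefined (``None``,
never silently zero).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "AnnotationError",
    "ReviewRecord",
    "TierConfusion",
    "TierMetrics",
    "CATEGORIES",
    "TIERS",
    "tally_categories",
    "tier_confusion",
    "compute_metrics",
    "evaluate_annotations",
    "read_annotations",
    "write_annotations",
    "write_metrics_csv",
    "round3",
]

CATEGORIES = (1, 2, 3, 4, 5, 6)
TIERS = (1, 2, 3)

# tier -> categories counted as TP; FP is the complement within {3,4,5}+{5}
_TIER_TP: dict[int, tuple[int, ...]] = {1: (2, 3, 4), 2: (2, 3), 3: (2,)}
_TIER_FP: dict[int, tuple[int, ...]] = {1: (5,), 2: (4, 5), 3: (3, 4, 5)}


class AnnotationError(ValueError):
    """An annotation record violates the schema."""


@dataclass(frozen=True)
class ReviewRecord:
    pair_id: str
    term: str | None
    category: int
    comment: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise AnnotationError(
                f"category must be 1-6, got {self.category!r} (pair {self.pair_id})"
            )


@dataclass(frozen=True)
class TierConfusion:
    tier: int
    TP: int
    FP: int
    FN: int


@dataclass(frozen=True)
class TierMetrics:
    precision: float | None
    recall: float | None
    f1: float | None

    @property
    def undefined(self) -> tuple[str, ...]:
        return tuple(
            name
            for name, value in (
                ("precision", self.precision),
                ("recall", self.recall),
                ("f1", self.f1),
            )
            if value is None
        )


def round3(value: float | None) -> float | None:
    """Half-up rounding to 3 decimals, for display alongside raw fractions."""
    if value is None:
        return None
    return float(Decimal(repr(value)).quantize(Decimal("0.001"), ROUND_HALF_UP))


def tally_categories(records: Iterable[ReviewRecord]) -> dict[int, int]:
    """Exact multiset counts per category; the sum equals the record count."""
    counts = {c: 0 for c in CATEGORIES}
    for record in records:
        counts[record.category] += 1
    return counts


def tier_confusion(counts: Mapping[int, int], tier: int) -> TierConfusion:
    """Map category counts to TP/FP/FN for one tier.

    Category 1 is never counted; category 6 is the FN count in every tier.
    """
    if tier not in TIERS:
        raise ValueError(f"tier must be 1, 2 or 3, got {tier!r}")
    tp = sum(counts.get(c, 0) for c in _TIER_TP[tier])
    fp = sum(counts.get(c, 0) for c in _TIER_FP[tier])
    fn = counts.get(6, 0)
    return TierConfusion(tier=tier, TP=tp, FP=fp, FN=fn)


def compute_metrics(confusion: TierConfusion) -> TierMetrics:
    """Precision, recall and F1 as raw fractions (``None`` when undefined)."""
    tp, fp, fn = confusion.TP, confusion.FP, confusion.FN
    if min(tp, fp, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    precision = tp / (tp + fp) if tp + fp else None
    recall = tp / (tp + fn) if tp + fn else None
    if precision is None or recall is None:
        f1 = None
    elif precision + recall == 0:
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return TierMetrics(precision=precision, recall=recall, f1=f1)


def evaluate_annotations(
    records: Sequence[ReviewRecord],
) -> dict[int, tuple[TierConfusion, TierMetrics]]:
    """Tally, map to tiers, and score in one step."""
    counts = tally_categories(records)
    out: dict[int, tuple[TierConfusion, TierMetrics]] = {}
    for tier in TIERS:
        confusion = tier_confusion(counts, tier)
        out[tier] = (confusion, compute_metrics(confusion))
    return out


# ---------------------------------------------------------------------------
# CSV interfaces


_REQUIRED_COLUMNS = ("pair_id", "term", "category")


def read_annotations(path: str | Path) -> list[ReviewRecord]:
    """Read the annotation CSV (header: pair_id, term, category, comment)."""
    records: list[ReviewRecord] = []
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        header = reader.fieldnames or []
        missing = [c for c in _REQUIRED_COLUMNS if c not in header]
        if missing:
            raise AnnotationError(f"{path}: missing columns {missing}")
        for row_number, row in enumerate(reader, start=2):
            raw_category = (row.get("category") or "").strip()
            try:
                category = int(raw_category)
            except ValueError:
                raise AnnotationError(
                    f"{path}:{row_number}: category {raw_category!r} is not an integer"
                ) from None
            term = (row.get("term") or "").strip() or None
            try:
                records.append(
                    ReviewRecord(
                        pair_id=(row.get("pair_id") or "").strip(),
                        term=term,
                        category=category,
                        comment=(row.get("comment") or "").strip(),
                    )
                )
            except AnnotationError as exc:
                raise AnnotationError(f"{path}:{row_number}: {exc}") from None
    return records


def write_annotations(path: str | Path, records: Sequence[ReviewRecord]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(["pair_id", "term", "category", "comment"])
        for record in records:
            writer.writerow(
                [record.pair_id, record.term or "", record.category, record.comment]
            )


def write_metrics_csv(
    path: str | Path,
    results: Mapping[int, tuple[TierConfusion, TierMetrics]],
) -> None:
    """Per-tier confusion counts and metrics; undefined metrics are flagged."""

    def cell(value: float | None) -> str:
        return "undefined" if value is None else f"{round3(value):.3f}"

    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(["tier", "TP", "FP", "FN", "precision", "recall", "f1"])
        for tier in sorted(results):
            confusion, metrics = results[tier]
            writer.writerow(
                [
                    tier,
                    confusion.TP,
                    confusion.FP,
                    confusion.FN,
                    cell(metrics.precision),
                    cell(metrics.recall),
                    cell(metrics.f1),
                ]
            )
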