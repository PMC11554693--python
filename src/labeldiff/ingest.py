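"""PDF ingestion: text blocks, header/footer roles, reading order.

Labeling PDFs mix a two-column front matter (Highlights, Contents) with a
single-column full text, and decorate pages with ``Page x of y`` /
``Reference ID:`` footers or bare page numbers.  This module turns a PDF into
cleaned :class:`TextBlock` objects, tags headers/footers, and restores the
reading order a human would follow: within each labeling component, left
column top-to-bottom, then right column — not the naive left-to-right sweep
that interleaves components sharing a page.
"""

from __future__ import annotations

import logging
import re
import unicodedata
from dataclasses import dataclass, replace
from typing import Sequence

from . import pdfio
from .pdfio import PageGeometry, TextLine

logger = logging.getLogger(__name__)

__all__ = [
    "TextBlock",
    "PageLayout",
    "Region",
    "extract_blocks",
    "compute_layouts",
    "assign_roles",
    "component_regions",
    "order_blocks",
    "COMPONENT_HEADINGS",
]

BODY = "body"
HEADER = "header"
FOOTER = "footer"

LEFT = "left"
RIGHT = "right"
FULL_WIDTH = "full_width"


@dataclass(frozen=True)
class TextBlock:
    """One positioned chunk of text (top-left-origin bbox, PDF points)."""

    page_index: int
    bbox: tuple[float, float, float, float]  # x0, y0, x1, y1
    text: str
    role: str = BODY
    column: str = FULL_WIDTH

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.bbox
        if not (x0 < x1 and y0 < y1):
            raise ValueError(f"degenerate bbox {self.bbox!r}")
        if not self.text.strip():
            raise ValueError("TextBlock text must be non-empty")

    @property
    def center_x(self) -> float:
        return (self.bbox[0] + self.bbox[2]) / 2.0

    @property
    def center_y(self) -> float:
        return (self.bbox[1] + self.bbox[3]) / 2.0

    @property
    def width(self) -> float:
        return self.bbox[2] - self.bbox[0]


@dataclass(frozen=True)
class PageLayout:
    page_index: int
    page_width: float
    page_height: float
    column_split_x: float | None = None  # None = single column


# The three major components of a labeling document.  The full-text heading
# is a prefix of the contents heading, so the latter must be tried first.
COMPONENT_HEADINGS: dict[str, re.Pattern[str]] = {
    "highlights": re.compile(r"^\s*HIGHLIGHTS OF PRESCRIBING INFORMATION\b"),
    "contents": re.compile(r"^\s*FULL PRESCRIBING INFORMATION:\s*CONTENTS\b"),
    "full_text": re.compile(r"^\s*FULL PRESCRIBING INFORMATION\s*$"),
}


def match_component_heading(text: str) -> str | None:
    first_line = text.split("\n", 1)[0]
    for name in ("highlights", "contents", "full_text"):
        if COMPONENT_HEADINGS[name].match(first_line):
            return name
    return None


# ---------------------------------------------------------------------------
# block extraction


_CHAR_MAP = str.maketrans(
    {
        "‘": "'",
        "’": "'",
        "“": '"',
        "”": '"',
        "–": "-",  # en dash
        "—": "-",  # em dash
        " ": " ",
        "•": "*",
    }
)


def normalize_text(text: str) -> str:
    """NFKC-normalize and map typographic punctuation to ASCII."""
    return unicodedata.normalize("NFKC", text).translate(_CHAR_MAP)


def _join_lines(parts: Sequence[str]) -> str:
    """Join the lines of a block, rejoining end-of-line hyphenation.

    A line ending in ``-`` followed by a lowercase continuation is a word
    split by the typesetter; AE terms broken this way must still match the
    dictionary, so the hyphen is dropped and the halves fused.
    """
    out = ""
    for part in parts:
        part = part.strip()
        if not part:
            continue
        if out.endswith("-") and part[:1].islower():
            out = out[:-1] + part
        elif out:
            out += " " + part
        else:
            out = part
    return out


# Vertical gap (in multiples of the font size) below which consecutive lines
# belong to the same paragraph block.
_LINE_GAP_FACTOR = 1.6


def _is_furniture_line(text: str) -> bool:
    """Page-furniture candidates are kept as isolated one-line blocks so the
    footer/header rules can see their exact text."""
    stripped = text.strip()
    return bool(
        _PAGE_X_OF_Y.match(stripped)
        or _REFERENCE_ID.match(stripped)
        or _BARE_NUMBER.match(stripped)
    )


def _lines_to_blocks(page_lines: list[TextLine]) -> list[TextBlock]:
    ordered = sorted(page_lines, key=lambda l: (l.y_top, l.x))
    open_blocks: list[dict] = []
    done: list[dict] = []
    for line in ordered:
        x0, x1 = line.x, line.x + line.approx_width
        attached = None
        for block in () if _is_furniture_line(line.text) else open_blocks:
            if _is_furniture_line(block["lines"][-1].text):
                continue
            last = block["lines"][-1]
            gap = line.y_top - last.y_top
            if gap <= 0 or gap > _LINE_GAP_FACTOR * max(last.size, line.size):
                continue
            lx0, lx1 = last.x, last.x + last.approx_width
            overlap = min(x1, lx1) - max(x0, lx0)
            if overlap >= 0.5 * min(x1 - x0, lx1 - lx0):
                attached = block
                break
        if attached is None:
            attached = {"lines": []}
            open_blocks.append(attached)
        attached["lines"].append(line)
        # close blocks whose last line is far above the current scan position
        still_open = []
        for block in open_blocks:
            if line.y_top - block["lines"][-1].y_top > 3.0 * line.size:
                done.append(block)
            else:
                still_open.append(block)
        open_blocks = still_open
    done.extend(open_blocks)

    blocks: list[TextBlock] = []
    for block in done:
        lines = block["lines"]
        text = normalize_text(_join_lines([l.text for l in lines]))
        if not text.strip():
            continue
        x0 = min(l.x for l in lines)
        x1 = max(l.x + l.approx_width for l in lines)
        size = max(l.size for l in lines)
        y0 = min(l.y_top for l in lines) - size
        y1 = max(l.y_top for l in lines) + 0.25 * size
        blocks.append(
            TextBlock(
                page_index=lines[0].page_index,
                bbox=(x0, y0, max(x1, x0 + 1.0), y1),
                text=text,
            )
        )
    blocks.sort(key=lambda b: (b.bbox[1], b.bbox[0]))
    return blocks


def extract_blocks(
    pdf_source: pdfio.PdfSource,
) -> tuple[list[TextBlock], list[PageGeometry]]:
    """Convert a PDF into cleaned text blocks (native top-down page order).

    Raises :class:`labeldiff.pdfio.PdfError` subclasses for encrypted input
    or input without a text layer.
    """
    geometries, lines = pdfio.extract_lines(pdf_source)
    blocks: list[TextBlock] = []
    for geom in geometries:
        page_lines = [l for l in lines if l.page_index == geom.page_index]
        blocks.extend(_lines_to_blocks(page_lines))
    return blocks, geometries


# ---------------------------------------------------------------------------
# layout analysis


# A page is two-column when block centers leave a horizontal gap of at least
# this fraction of the page width.
_MIN_COLUMN_GAP = 0.10
# Blocks wider than this fraction of the page are full-width banners and do
# not vote in the column histogram.
_MAX_COLUMN_BLOCK_WIDTH = 0.60


def compute_layouts(
    blocks: Sequence[TextBlock], geometries: Sequence[PageGeometry]
) -> list[PageLayout]:
    """Estimate per-page column structure from the x-histogram of centers.

    Only body blocks vote (centered footers would fill real column gaps),
    and near-full-width banner blocks abstain.
    """
    layouts = []
    for geom in geometries:
        centers = sorted(
            b.center_x
            for b in blocks
            if b.page_index == geom.page_index
            and b.role == BODY
            and b.width < _MAX_COLUMN_BLOCK_WIDTH * geom.width
        )
        split = None
        if len(centers) >= 2:
            best_gap, best_mid = 0.0, None
            for a, b in zip(centers, centers[1:]):
                if b - a > best_gap:
                    best_gap, best_mid = b - a, (a + b) / 2.0
            if best_gap >= _MIN_COLUMN_GAP * geom.width and best_mid is not None:
                split = best_mid
        layouts.append(
            PageLayout(geom.page_index, geom.width, geom.height, split)
        )
    return layouts


# ---------------------------------------------------------------------------
# header / footer roles


_PAGE_X_OF_Y = re.compile(r"^\s*page\s+\d+\s+of\s+\d+\s*$", re.IGNORECASE)
_REFERENCE_ID = re.compile(r"^\s*Reference ID:")
_BARE_NUMBER = re.compile(r"^\s*\d+\s*$")

# Bare page numbers only count as furniture inside this top/bottom band (pt).
_MARGIN_BAND = 60.0


def assign_roles(
    blocks: Sequence[TextBlock], pages: Sequence[object]
) -> list[TextBlock]:
    """Tag footer/header blocks; everything else stays body.

    ``Page x of y`` and ``Reference ID:`` blocks are footers wherever they
    sit.  A digits-only block is page furniture only within the top or bottom
    margin band; a trailing number in the body region (e.g. spilled from a
    table) is deliberately kept as body for human review.
    Idempotent: applying twice gives the same labels.

    ``pages`` accepts either :class:`PageGeometry` or :class:`PageLayout`
    entries (anything carrying the page height).
    """
    heights = {
        p.page_index: getattr(p, "page_height", None) or getattr(p, "height")
        for p in pages
    }
    out: list[TextBlock] = []
    for block in blocks:
        role = BODY
        if _PAGE_X_OF_Y.match(block.text) or _REFERENCE_ID.match(block.text):
            role = FOOTER
        elif _BARE_NUMBER.match(block.text):
            height = heights.get(block.page_index, 792.0)
            if block.center_y <= _MARGIN_BAND:
                role = HEADER
            elif block.center_y >= height - _MARGIN_BAND:
                role = FOOTER
        out.append(replace(block, role=role) if block.role != role else block)
    return out


# ---------------------------------------------------------------------------
# reading order


@dataclass(frozen=True)
class Region:
    """A vertical band of one page belonging to one labeling component."""

    page_index: int
    y_top: float
    y_bottom: float
    component: str | None  # None = continuation of the previous region


def component_regions(blocks: Sequence[TextBlock]) -> list[Region]:
    """Split pages into bands at component headings.

    Blocks above the first heading of a page continue the previous page's
    component, so a region with ``component=None`` is emitted for them.
    """
    regions: list[Region] = []
    pages = sorted({b.page_index for b in blocks})
    for page in pages:
        page_blocks = [b for b in blocks if b.page_index == page and b.role == BODY]
        headings = sorted(
            (b for b in page_blocks if match_component_heading(b.text)),
            key=lambda b: b.bbox[1],
        )
        cursor = 0.0
        for head in headings:
            top = head.bbox[1]
            if top > cursor:
                regions.append(Region(page, cursor, top, None))
            regions.append(
                Region(page, top, float("inf"), match_component_heading(head.text))
            )
            cursor = top
        if not headings:
            regions.append(Region(page, 0.0, float("inf"), None))
    # close each region at the start of the next one on the same page
    closed: list[Region] = []
    for i, region in enumerate(regions):
        bottom = region.y_bottom
        for nxt in regions[i + 1 :]:
            if nxt.page_index == region.page_index and nxt.y_top > region.y_top:
                bottom = nxt.y_top
                break
        closed.append(replace(region, y_bottom=bottom))
    return closed


def _column_of(block: TextBlock, layout: PageLayout) -> str:
    split = layout.column_split_x
    if split is None:
        return FULL_WIDTH
    x0, _, x1, _ = block.bbox
    if x1 <= split:
        return LEFT
    if x0 >= split:
        return RIGHT
    return FULL_WIDTH


def order_blocks(
    blocks: Sequence[TextBlock],
    layouts: Sequence[PageLayout],
    regions: Sequence[Region] | None = None,
) -> list[TextBlock]:
    """Reading-order the body blocks.

    Within each component region: full-width and left-column blocks
    top-to-bottom, then the right column top-to-bottom.  Regions follow
    their first appearance (page, vertical position).  Headers and footers
    are dropped.  The output is a permutation of the body input blocks.
    """
    body = [b for b in blocks if b.role == BODY]
    if regions is None:
        regions = component_regions(blocks)
    layout_by_page = {l.page_index: l for l in layouts}

    def region_of(block: TextBlock) -> int:
        for i, region in enumerate(regions):
            if (
                region.page_index == block.page_index
                and region.y_top <= block.center_y < region.y_bottom
            ):
                return i
        return len(regions)  # no region info: stable tail bucket

    ordered: list[TextBlock] = []
    buckets: dict[int, list[TextBlock]] = {}
    for block in body:
        buckets.setdefault(region_of(block), []).append(block)
    for index in sorted(buckets):
        members = buckets[index]
        layout = layout_by_page.get(
            members[0].page_index, PageLayout(members[0].page_index, 612.0, 792.0)
        )
        with_cols = [replace(b, column=_column_of(b, layout)) for b in members]
        with_cols.sort(
            key=lambda b: (
                1 if b.column == RIGHT else 0,
                b.bbox[1],
                b.bbox[0],
            )
        )
        ordered.extend(with_cols)
    return ordered


def ingest_pdf(
    pdf_source: pdfio.PdfSource,
) -> tuple[list[TextBlock], list[PageLayout]]:
    """Full ingestion pipeline: extract, tag roles, analyse layout, order."""
    blocks, geometries = extract_blocks(pdf_source)
    blocks = assign_roles(blocks, geometries)
    layouts = compute_layouts(blocks, geometries)
    return order_blocks(blocks, layouts), layouts
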