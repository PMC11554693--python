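"""Minimal PDF text extraction.

Drug-labeling PDFs carry a plain text layer; this module recovers positioned
text lines from the subset of ISO 32000 such documents use: indirect objects,
the page tree, uncompressed or Flate-compressed content streams, and the text
operators (``BT``/``ET``, ``Tf``, ``Td``, ``TD``, ``TL``, ``Tm``, ``T*``,
``Tj``, ``TJ``, ``'``, ``"``).  Transformation matrices are treated as
translations (rotated or skewed text is out of scope), glyph widths are
approximated from the font size, and strings are decoded as WinAnsi/cp1252
(the standard-font default) with a Latin-1 fallback.

Encrypted files and files without a text layer are rejected explicitly —
scanned labels would need OCR, which this package deliberately does not do.
"""

from __future__ import annotations

import re
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import BinaryIO, Iterator, Union

__all__ = [
    "PdfError",
    "EncryptedPdfError",
    "NoTextLayerError",
    "PageGeometry",
    "TextLine",
    "extract_lines",
]

# Average Helvetica advance per glyph, as a fraction of the font size.  Used
# only to estimate line widths for layout analysis, never for rendering.
CHAR_WIDTH_FACTOR = 0.5


class PdfError(ValueError):
    """The input is not a PDF this extractor can process."""


class EncryptedPdfError(PdfError):
    """The PDF is encrypted; decryption is unsupported."""


class NoTextLayerError(PdfError):
    """The PDF contains no extractable text (likely a scanned image)."""


@dataclass(frozen=True)
class PageGeometry:
    page_index: int
    width: float
    height: float


@dataclass(frozen=True)
class TextLine:
    """One positioned run of shown text, with a top-left-origin baseline."""

    page_index: int
    x: float
    y_top: float
    size: float
    text: str

    @property
    def approx_width(self) -> float:
        return CHAR_WIDTH_FACTOR * self.size * len(self.text)


PdfSource = Union[bytes, str, Path, BinaryIO]


def _read_bytes(source: PdfSource) -> bytes:
    if isinstance(source, bytes):
        return source
    if isinstance(source, (str, Path)):
        return Path(source).read_bytes()
    return source.read()


# ---------------------------------------------------------------------------
# object-level parsing


_WHITESPACE = b" \t\r\n\x00\x0c"
_DELIMS = b"()<>[]{}/%"

_ESCAPES = {
    b"n": b"\n",
    b"r": b"\r",
    b"t": b"\t",
    b"b": b"\b",
    b"f": b"\f",
    b"(": b"(",
    b")": b")",
    b"\\": b"\\",
}


def _parse_objects(data: bytes) -> dict[int, tuple[bytes, bytes | None]]:
    """Map object number -> (dictionary/head bytes, raw stream bytes or None)."""
    objects: dict[int, tuple[bytes, bytes | None]] = {}
    for match in re.finditer(rb"(\d+)\s+\d+\s+obj\b", data):
        num = int(match.group(1))
        start = match.end()
        end = data.find(b"endobj", start)
        if end < 0:
            end = len(data)
        body = data[start:end]
        stream_match = re.search(rb"stream\r?\n", body)
        if stream_match is None:
            objects[num] = (body, None)
            continue
        head = body[: stream_match.start()]
        raw = body[stream_match.end():]
        stop = raw.rfind(b"endstream")
        if stop >= 0:
            raw = raw[:stop]
        objects[num] = (head, raw.rstrip(b"\r\n"))
    return objects


def _decode_stream(head: bytes, raw: bytes) -> bytes:
    if b"/FlateDecode" in head:
        try:
            return zlib.decompress(raw)
        except zlib.error as exc:  # pragma: no cover - corrupt input
            raise PdfError(f"cannot inflate content stream: {exc}") from exc
    if b"/Filter" in head:
        raise PdfError("unsupported stream filter (only FlateDecode handled)")
    return raw


def _refs(value: bytes) -> list[int]:
    return [int(m.group(1)) for m in re.finditer(rb"(\d+)\s+\d+\s+R", value)]


def _dict_entry(head: bytes, key: bytes) -> bytes | None:
    """Very small lookup: value bytes following /key up to the next /key."""
    match = re.search(key + rb"\s*((?:\[[^\]]*\])|(?:\d+\s+\d+\s+R)|[^/>\]]*)", head)
    return match.group(1) if match else None


def _media_box(head: bytes) -> tuple[float, float] | None:
    match = re.search(
        rb"/MediaBox\s*\[\s*([\d.+-]+)\s+([\d.+-]+)\s+([\d.+-]+)\s+([\d.+-]+)",
        head,
    )
    if not match:
        return None
    x0, y0, x1, y1 = (float(match.group(i)) for i in range(1, 5))
    return (abs(x1 - x0), abs(y1 - y0))


def _page_objects(objects: dict[int, tuple[bytes, bytes | None]]) -> list[int]:
    """Page object numbers in document order (page-tree walk with fallback)."""
    catalog = None
    for num, (head, _) in objects.items():
        if re.search(rb"/Type\s*/Catalog\b", head):
            catalog = head
            break
    ordered: list[int] = []

    def walk(num: int, seen: set[int]) -> None:
        if num in seen or num not in objects:
            return
        seen.add(num)
        head, _ = objects[num]
        if re.search(rb"/Type\s*/Pages\b", head):
            kids = _dict_entry(head, rb"/Kids")
            for ref in _refs(kids or b""):
                walk(ref, seen)
        elif re.search(rb"/Type\s*/Page\b", head):
            ordered.append(num)

    if catalog is not None:
        pages_entry = _dict_entry(catalog, rb"/Pages")
        for ref in _refs(pages_entry or b""):
            walk(ref, set())
    if not ordered:
        ordered = sorted(
            num
            for num, (head, _) in objects.items()
            if re.search(rb"/Type\s*/Page(?!s)", head)
        )
    return ordered


# ---------------------------------------------------------------------------
# content-stream interpretation


def _tokenize(stream: bytes) -> Iterator[tuple[str, object]]:
    i, n = 0, len(stream)
    while i < n:
        c = stream[i : i + 1]
        if c in _WHITESPACE:
            i += 1
            continue
        if c == b"%":
            j = stream.find(b"\n", i)
            i = n if j < 0 else j + 1
            continue
        if c == b"(":
            out = bytearray()
            depth = 1
            j = i + 1
            while j < n and depth:
                ch = stream[j : j + 1]
                if ch == b"\\":
                    nxt = stream[j + 1 : j + 2]
                    if nxt in _ESCAPES:
                        out += _ESCAPES[nxt]
                        j += 2
                    elif nxt.isdigit():
                        k = j + 1
                        while k < min(n, j + 4) and stream[k : k + 1].isdigit():
                            k += 1
                        out.append(int(stream[j + 1 : k], 8) & 0xFF)
                        j = k
                    else:  # line continuation or unknown escape
                        j += 2
                elif ch == b"(":
                    depth += 1
                    out += ch
                    j += 1
                elif ch == b")":
                    depth -= 1
                    if depth:
                        out += ch
                    j += 1
                else:
                    out += ch
                    j += 1
            yield ("str", bytes(out))
            i = j
            continue
        if stream[i : i + 2] == b"<<":
            yield ("op", b"<<")
            i += 2
            continue
        if stream[i : i + 2] == b">>":
            yield ("op", b">>")
            i += 2
            continue
        if c == b"<":
            j = stream.find(b">", i)
            if j < 0:
                break
            hexs = re.sub(rb"\s", b"", stream[i + 1 : j])
            if len(hexs) % 2:
                hexs += b"0"
            yield ("str", bytes.fromhex(hexs.decode("ascii", "replace")))
            i = j + 1
            continue
        if c == b"/":
            j = i + 1
            while j < n and stream[j : j + 1] not in _WHITESPACE + _DELIMS:
                j += 1
            yield ("name", stream[i + 1 : j])
            i = j
            continue
        if c in b"[]":
            yield ("op", c)
            i += 1
            continue
        j = i
        while j < n and stream[j : j + 1] not in _WHITESPACE + _DELIMS:
            j += 1
        tok = stream[i:j]
        try:
            yield ("num", float(tok))
        except ValueError:
            yield ("op", tok)
        i = j


# In a TJ array, a strongly negative kern is how some producers encode an
# inter-word gap; anything milder is intra-word kerning and yields no space.
_TJ_SPACE_KERN = -180.0


def _interpret_content(content: bytes, page_height: float) -> list[tuple[float, float, float, str]]:
    """Return (x, y_top, size, text) for every text-showing operator."""
    shows: list[tuple[float, float, float, str]] = []
    stack: list[tuple[str, object]] = []
    size = 10.0
    leading = 0.0
    lx = ly = 0.0

    def nums(count: int) -> list[float]:
        vals = [v for k, v in stack if k == "num"]
        return vals[-count:] if len(vals) >= count else []

    def emit(raw: bytes) -> None:
        # WinAnsi (cp1252) is the standard-font default; fall back to
        # latin-1 for the few bytes cp1252 leaves undefined
        try:
            text = raw.decode("cp1252")
        except UnicodeDecodeError:
            text = raw.decode("latin-1")
        if text:
            shows.append((lx, page_height - ly, size, text))

    for kind, val in _tokenize(content):
        if kind in ("num", "str", "name"):
            stack.append((kind, val))
            continue
        op = val
        if op in (b"[", b"]"):
            stack.append(("op", op))
            continue
        if op == b"BT":
            lx = ly = 0.0
        elif op == b"Tf":
            got = nums(1)
            if got:
                size = got[0] or size
        elif op == b"TL":
            got = nums(1)
            if got:
                leading = got[0]
        elif op in (b"Td", b"TD"):
            got = nums(2)
            if got:
                lx += got[0]
                ly += got[1]
                if op == b"TD":
                    leading = -got[1]
        elif op == b"Tm":
            got = nums(6)
            if got:
                # translation components only; scale/rotation unsupported
                lx, ly = got[4], got[5]
        elif op == b"T*":
            ly -= leading
        elif op == b"Tj":
            if stack and stack[-1][0] == "str":
                emit(stack[-1][1])  # type: ignore[arg-type]
        elif op in (b"'", b'"'):
            ly -= leading
            if stack and stack[-1][0] == "str":
                emit(stack[-1][1])  # type: ignore[arg-type]
        elif op == b"TJ":
            items: list[tuple[str, object]] = []
            for entry in reversed(stack):
                if entry == ("op", b"["):
                    break
                items.append(entry)
            items.reverse()
            parts: list[bytes] = []
            for kind2, val2 in items:
                if kind2 == "str":
                    parts.append(val2)  # type: ignore[arg-type]
                elif kind2 == "num" and val2 <= _TJ_SPACE_KERN and parts:
                    parts.append(b" ")
            emit(b"".join(parts))
        stack.clear()
    return shows


# Shows on (nearly) the same baseline belong to one visual line unless the
# horizontal gap between them is wide — then they sit in different columns.
_BASELINE_TOL = 0.6


def _assemble_lines(
    page_index: int, shows: list[tuple[float, float, float, str]]
) -> list[TextLine]:
    lines: list[TextLine] = []
    by_baseline: dict[float, list[tuple[float, float, float, str]]] = {}
    for x, y_top, size, text in shows:
        key = round(y_top / _BASELINE_TOL) * _BASELINE_TOL
        by_baseline.setdefault(key, []).append((x, y_top, size, text))
    for key in sorted(by_baseline):
        runs = sorted(by_baseline[key], key=lambda s: s[0])
        current: list[tuple[float, float, float, str]] = []
        for run in runs:
            if current:
                prev = current[-1]
                prev_end = prev[0] + CHAR_WIDTH_FACTOR * prev[2] * len(prev[3])
                if run[0] - prev_end > 2.0 * max(prev[2], run[2]):
                    lines.append(_merge_runs(page_index, current))
                    current = []
            current.append(run)
        if current:
            lines.append(_merge_runs(page_index, current))
    return lines


def _merge_runs(
    page_index: int, runs: list[tuple[float, float, float, str]]
) -> TextLine:
    text = " ".join(r[3] for r in runs) if len(runs) > 1 else runs[0][3]
    return TextLine(
        page_index=page_index,
        x=runs[0][0],
        y_top=runs[0][1],
        size=max(r[2] for r in runs),
        text=text,
    )


def extract_lines(source: PdfSource) -> tuple[list[PageGeometry], list[TextLine]]:
    """Extract positioned text lines from a PDF.

    Raises :class:`EncryptedPdfError` for encrypted files,
    :class:`NoTextLayerError` when no text operator is found, and
    :class:`PdfError` for anything that is not parseable as a PDF.
    """
    data = _read_bytes(source)
    if not data.lstrip().startswith(b"%PDF"):
        raise PdfError("not a PDF file (missing %PDF header)")
    if re.search(rb"/Encrypt\s+\d+\s+\d+\s+R", data):
        raise EncryptedPdfError("PDF is encrypted; cannot extract text")

    objects = _parse_objects(data)
    if not objects:
        raise PdfError("no indirect objects found; malformed PDF")
    page_nums = _page_objects(objects)
    if not page_nums:
        raise PdfError("no pages found; malformed PDF")

    geometries: list[PageGeometry] = []
    lines: list[TextLine] = []
    any_show = False
    for index, num in enumerate(page_nums):
        head, _ = objects[num]
        box = _media_box(head)
        if box is None:
            parent = _dict_entry(head, rb"/Parent")
            for ref in _refs(parent or b""):
                if ref in objects:
                    box = _media_box(objects[ref][0])
        width, height = box if box else (612.0, 792.0)
        geometries.append(PageGeometry(index, width, height))

        contents_entry = _dict_entry(head, rb"/Contents")
        chunks: list[bytes] = []
        for ref in _refs(contents_entry or b""):
            if ref in objects and objects[ref][1] is not None:
                chunks.append(_decode_stream(objects[ref][0], objects[ref][1]))
        if not chunks:
            continue
        shows = _interpret_content(b"\n".join(chunks), height)
        if shows:
            any_show = True
        lines.extend(_assemble_lines(index, shows))

    if not any_show:
        raise NoTextLayerError(
            "PDF has no text layer (scanned image?); OCR is not supported"
        )
    return geometries, lines
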