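# Methods

## Problem and pipeline

`labeldiff` answers one question for pharmacovigilance review: *which
adverse-event terms were added to (or removed from) a drug's Full
Prescribing Information between two labeling versions?* The pipeline has
five stages — PDF processing, content preparation, difference highlighting,
AE-term detection, and performance evaluation — each exposed as a module
with an importable API.

## PDF processing

Labeling PDFs are born-digital and carry a text layer; `pdfio` implements
the subset of ISO 32000 needed to read it (page tree, uncompressed or
Flate-compressed content streams, the positional text operators, WinAnsi
string decoding). Encrypted files and files with no text operators are
rejected with specific errors rather than OCR'd: a scanned label has no
reliable text layer, and silently degraded extraction would corrupt every
downstream count. Transformation matrices are honored as translations only,
and glyph advances are approximated as 0.5 × font size — sufficient for
layout analysis, not for rendering.

`ingest` groups extracted lines into paragraph blocks (consecutive lines
closer than 1.6 × font size with ≥ 50 % horizontal overlap), rejoins
end-of-line hyphenation when the continuation starts lowercase (an AE term
split across lines must still match the dictionary), and NFKC-normalizes
text with curly quotes/dashes mapped to ASCII. Header/footer detection uses
the wording rules first — a block matching `Page x of y`
(case-insensitively, whitespace-tolerant) or starting `Reference ID:` is a
footer wherever it sits — and geometry second: a digits-only block is page
furniture only inside a 60 pt top/bottom band. A trailing number in the
body region (a spilled table cell) is deliberately **kept** as body text, as
are unrecognized footer-like strings; uncommon patterns are a matter for
human review, not silent deletion.

Column structure is estimated per page from the x-histogram of block
centers: the largest gap between centers, if at least 10 % of the page
width, is the column split. Near-full-width blocks (> 60 % of page width)
and non-body blocks abstain from the histogram — centered footers would
otherwise fill real column gaps. Reading order is restored per *component
region*: pages are cut into horizontal bands at the component headings
(`HIGHLIGHTS OF PRESCRIBING INFORMATION`, `FULL PRESCRIBING INFORMATION:
CONTENTS`, `FULL PRESCRIBING INFORMATION`), and within each band the left
column is read top-to-bottom before the right column. This is what makes
two components sharing a two-column page come out 1–2–3–4 rather than the
naive left-to-right sweep's 1–3–2–4.

## Content preparation

Only the full-text component is parsed for sections; the Contents component
duplicates every section title and would corrupt spans. Section titles are
matched case-sensitively against canonical all-caps strings with a gradient
strategy: the numbered line-start form (`6 ADVERSE REACTIONS`,
`6. ADVERSE REACTIONS`) first, then the bare title with leading whitespace
allowed. The Boxed Warning has no number and is located by its banner
(`BOXED WARNING` or `WARNING…`); the title table is configurable because
real labels vary. Absent sections are omitted; duplicate matches keep the
first and log a warning. Each section runs to the next top-level numbered
title of *any* section, so non-AE sections (§1, §8, …) bound their
neighbors.

Subsection titles are found by the dotted-number pattern — `.digits`
followed by a space and a capital letter — prefixed with the enclosing
section's own number. The prefix guard matters: the bare pattern would
false-positive on prose like "5.2% Of patients…", while `5.1 Hepatic
Effects` inside section 5 still splits. Text before the first sub-title
(or a whole unnumbered section) becomes one implicit untitled subsection,
so every section has at least one.

Sentences are split by a regex boundary (sentence-final punctuation,
optional closing quote/paren, whitespace, capital/numeral start) with a
protection list of labeling-frequent abbreviations (`e.g.`, `i.e.`, `vs.`,
`et al.`, `Fig.`, …) checked at word boundaries; decimal numbers are
inherently protected because their dot is not followed by whitespace. Every
sentence carries its 0-based half-open source span, and concatenating the
sentences of a subsection reproduces its text up to whitespace — an
invariant the tests enforce.

## Difference highlighting

Old and new sentences of a matched subsection (matched by number, then
normalized title, then position) are aligned with an explicit
longest-common-subsequence dynamic program on case-folded,
whitespace-collapsed text. `difflib`'s matcher was deliberately not used:
it does not guarantee a maximum-length common subsequence, and the test
suite checks LCS-length equality against an exhaustive oracle on short
lists. Tie-breaks during backtracking consume the old side first, making
the alignment deterministic; unmatched runs are paired positionally as
replacements, leftovers become insertions/deletions. With repeated
sentences several maximum alignments exist, so only the matched-pair count
is direction-symmetric in general; for realistic edit scenarios (unique
sentences) swapping the inputs mirrors the alignment exactly, and both
properties are tested at that strength.

For a replaced pair, tokens are maximal word-character runs *and*
punctuation runs (punctuation-only edits count as changes). The changed
fraction is `max(changed_old, changed_new) / max(token counts)`; above the
`ratio_threshold` the whole sentence is flagged on both sides, otherwise
each changed run gets a precise span. The threshold defaults to 0.5 — the
display behavior ("many changes → highlight the whole sentence") constrains
but does not pin this value, so it is CLI-configurable.

## AE-term detection

Dictionary matching is case-insensitive at word boundaries, with
whitespace-collapsed multi-word terms allowed to span a line break. Word
boundaries are enforced so `rash` cannot fire inside an unrelated longer
word. By default only maximal matches are kept (leftmost, then longest:
`blood pressure` suppresses the contained `pressure`); `nested=True`
reports contained matches too, which is exactly the behavior that produces
"inaccurate" sub-term findings and is kept available for studying them.
A stoplist removes LLT entries that are almost always ordinary words in
prose (`all`, `high`); loading fails loudly if nothing survives.

The NER side is a contract, not a model: any callable mapping text to
`(span, "AE")` tuples plugs in, and the result is unioned with dictionary
matches keyed by (normalized term, location) — a term found by both at the
same spot is reported once with source `both`. No model weights ship with
the package. Detection runs over *all* sentences of the five AE sections in
both versions, not only changed ones, because novelty scoping needs the
full major section of the old document anyway; the report ties findings to
the changed sentences for display.

## Change classification

Term identity is the case-folded, whitespace-collapsed form with trailing
punctuation stripped — formatting differences must not make an old term
look new, but genuine spelling variants stay distinct terms. Scoping is the
major section: newly added means absent from the entire same section of the
old version (any subsection); removed is symmetric; everything else is
pre-existing. Each (term, section, change type) appears once. A term that
moved from §5 to §6 is newly added in §6 and removed from §5: novelty is a
property of the section, not the document. Boxed Warning is treated as its
own major section for scoping.

## Tiered evaluation

Reviewer records carry categories 1–6. Category 1 (no AE updated) is
correct but never enters the confusion matrix; category 6 (missed) is the
FN count in every tier; category 5 (irrelevant) is always FP. Categories 3
(not new) and 4 (inaccurate) move: Tier 1 counts both TP, Tier 2 counts 4
as FP, Tier 3 counts both FP. Because TP + FP is constant across tiers
while TP mass moves to FP, precision is non-increasing from Tier 1 to
Tier 3 — a property tested on random count vectors. Metrics are kept as raw
fractions with half-up 3-decimal rounding for display, and a zero
denominator yields an explicit `undefined` flag rather than a silent zero.

## Synthetic data

The generator emulates what the pipeline must survive in real labeling
PDFs, not their typography: a Highlights/Contents front matter in two
columns (optionally sharing a page, which is the hard ordering case), a
single-column full text with numbered sections §1–§8 (five of them
AE-related, with dotted subsections under §5 and §6), and the four page
furniture dialects (`Page x of y` + `Reference ID:`, bare bottom number,
none, top number). Filler prose is drawn from a fixed vocabulary verified
by a test to contain no demo-dictionary term even as a substring, so
planted terms are the only detectable AEs — the construction is the oracle.
Injected changes place a term sentence in the new version only (newly
added), the old only (removed), or both (pre-existing); an
`also_elsewhere_in_major_section` flag plants the term in another
subsection of the old version's same section, turning an apparent addition
into a pre-existing term and exercising the scoping rule. Batches cycle
footer dialects deterministically and draw 0–5 changes per pair; rendering
uses fixed Helvetica and uncompressed streams so the same seed yields
byte-identical files.

What passing on synthetic pairs does **not** show: robustness to embedded
subset fonts, tables (cells surface as plain text blocks; a real validation
noted a miss in a table footnote), multi-column body text, scanned pages,
or title variants beyond the configurable canon. The generator's automatic
reviewer (category 2 for confirmed plants, 4 for sub-terms of a plant, 3
for terms present in the old section, 5 otherwise, 6 for misses) encodes
the category definitions literally, with none of a human reviewer's
judgment calls.

## Problem sizes and numerics

The test suite and the acceptance script use 20-pair batches, 50-pair
symmetry sweeps, 100–200 random vectors/lists for property checks, and
sentence lists of length ≤ 8 against the exhaustive LCS oracle — sizes
chosen so the whole suite runs in seconds while every property still has
room to fail. All randomness flows through explicit seeds; the comparison
pipeline itself contains none, and reports are byte-identical across runs.

Known limitations: no OCR; no SPL/XML ingestion; no semantic sentence
matching (a heavily reworded sentence pairs positionally or splits into
delete+insert); no negation or hypothetical-context handling around
detected terms; partially overlapping dictionary/NER spans are kept as
separate findings rather than reconciled.
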