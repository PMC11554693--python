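# labeldiff

Compare two versions of a drug-labeling PDF (Full Prescribing Information)
and classify adverse-event (AE) term changes.

When a drug's postmarketing experience reveals new adverse reactions, its
labeling is revised — but most of the document stays the same, and finding
the safety-relevant additions by manually diffing two PDFs is slow and
error-prone for pharmacovigilance reviewers. `labeldiff` automates that
review: it extracts the text of both versions, restores the reading order of
the two-column Highlights/Contents front matter, isolates the five
AE-related sections (Boxed Warning; Contraindications, §4; Warnings and
Precautions, §5; Adverse Reactions, §6; Drug Interactions, §7), aligns and
highlights sentence-level differences, detects AE terms with a
MedDRA-LLT-style dictionary (plus an optional pluggable NER adapter), and
labels every term as **newly added**, **removed**, or **pre-existing**.

A term found in the new document is *newly added* only when its normalized
form appears nowhere in the **same major section** of the old document —
`cardio-respiratory arrest` in new §6.1 counts only if it is absent from all
of old §6. Repeated occurrences are reported once per section.

Tool output is scored against reviewer annotations in six categories
(1 no AE updated, 2 true new AE, 3 not new, 4 inaccurate, 5 irrelevant,
6 missed) with a three-tier confusion mapping — the ambiguous categories 3
and 4 count as TP in the tolerant Tier 1, while the strict Tier 3 counts
both as FP; category 6 is FN everywhere, category 1 never enters the
matrix — and per-tier

```
precision = TP/(TP+FP),  recall = TP/(TP+FN),  F1 = 2·P·R/(P+R).
```

MedDRA is licensed and is **not** bundled; supply your own LLT list via
`--dict` (one term per line, or `code<TAB>term`). A small demo dictionary
ships for tests and examples.

## Worked example

```sh
python examples/compare_label_pair.py
```

generates a synthetic labeling pair with three injected changes and prints:

```
newly added (2):
  abscess                        in warnings_precautions_5
  cardio-respiratory arrest      in adverse_reactions_6
removed (1):
  syncope                        in drug_interactions_7
pre-existing (7):
  fatigue                        in boxed_warning
  ...
```

The two newly added terms are exactly the ones injected into the new
version's §5.2 and §6.1 (and absent from those major sections of the old
version); `syncope` was removed from §7; the pre-existing terms occur in
both versions and are listed for context. `examples/tiered_evaluation.py`
and `examples/synthetic_batch.py` show the scoring side.

From the shell, the same pipeline is:

```sh
labeldiff compare old.pdf new.pdf --dict my_llts.txt --out results/
labeldiff evaluate annotations.csv --out metrics.csv
labeldiff generate-fixtures --count 4 --seed 3 --out fixtures/
```

`compare` writes `report.csv` (one row per changed sentence pair plus one
per AE change) and `report.html`, a static side-by-side page with blue
styling for text edits and yellow highlighting for detected AE terms.

## Layout

- `src/labeldiff/` — `pdfio` (minimal PDF text extraction), `ingest`
  (blocks, header/footer roles, reading order), `structure` (components,
  sections, subsections, sentences), `diff` (LCS alignment, highlight
  spans), `detect` (dictionary + NER adapter), `classify` (change types),
  `evaluate` (tiered metrics), `report` (pipeline + CSV/HTML writers),
  `fixtures` (synthetic pair generator), `cli`.
- `docs/methods.md` — models, parameters, and design choices.
- `examples/` — one short narrative script per capability.
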