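"""Score reviewer annotations with the three-tier confusion metrics.

Feeds the category counts of a validation review (21 no-change pairs, 305
true new AEs, 27 not-new, 75 inaccurate, 54 irrelevant, 1 missed) through
the tier mapping and prints precision/recall/F1 per tier.  Tier 1 tolerates
not-new and inaccurate findings as true positives; Tier 3 counts both as
false positives, so precision falls while recall (driven only by the single
miss) stays put.
"""

from labeldiff.evaluate import compute_metrics, round3, tier_confusion

counts = {1: 21, 2: 305, 3: 27, 4: 75, 5: 54, 6: 1}

print("tier  TP   FP  FN  precision  recall  F1")
for tier in (1, 2, 3):
    confusion = tier_confusion(counts, tier)
    metrics = compute_metrics(confusion)
    print(
        f"  {tier}  {confusion.TP:4d} {confusion.FP:4d}  {confusion.FN}"
        f"   {round3(metrics.precision):.3f}     {round3(metrics.recall):.3f}"
        f"  {round3(metrics.f1):.3f}"
    )
print("\nCategory 1 (no AE updated) is correct but never enters the matrix;")
print("category 6 (missed) is the false-negative count in every tier.")
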