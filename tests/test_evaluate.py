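"""Category tallies, tier confusion mapping, and precision/recall/F1."""

import random

import pytest

from labeldiff import evaluate
from labeldiff.evaluate import (
    AnnotationError,
    ReviewRecord,
    TierConfusion,
    compute_metrics,
    evaluate_annotations,
    read_annotations,
    round3,
    tally_categories,
    tier_confusion,
    write_annotations,
    write_metrics_csv,
)

# Category counts of the published validation study: 87 label pairs, 462
# tool findings plus 21 no-change pairs and one miss.
STUDY_COUNTS = {1: 21, 2: 305, 3: 27, 4: 75, 5: 54, 6: 1}


def records_from_counts(counts):
    out = []
    for category, count in counts.items():
        for index in range(count):
            out.append(
                ReviewRecord(
                    pair_id=f"p{index}",
                    term=None if category == 1 else f"t{category}-{index}",
                    category=category,
                )
            )
    return out


class TestTally:
    def test_study_multiset(self):
        counts = tally_categories(records_from_counts(STUDY_COUNTS))
        assert counts == STUDY_COUNTS
        assert sum(counts.values()) == 483

    def test_empty_input_all_zero(self):
        assert tally_categories([]) == {c: 0 for c in range(1, 7)}

    def test_total_matches_record_count(self):
        records = records_from_counts({1: 2, 3: 5, 6: 3})
        assert sum(tally_categories(records).values()) == 10

    def test_invalid_category_rejected(self):
        with pytest.raises(AnnotationError):
            ReviewRecord(pair_id="p", term="t", category=7)


class TestTierConfusion:
    def test_tier_mappings_on_study_counts(self):
        assert tier_confusion(STUDY_COUNTS, 1) == TierConfusion(1, TP=407, FP=54, FN=1)
        assert tier_confusion(STUDY_COUNTS, 2) == TierConfusion(2, TP=332, FP=129, FN=1)
        assert tier_confusion(STUDY_COUNTS, 3) == TierConfusion(3, TP=305, FP=156, FN=1)

    def test_category_1_never_counted(self):
        with_c1 = dict(STUDY_COUNTS)
        without_c1 = {**STUDY_COUNTS, 1: 0}
        for tier in (1, 2, 3):
            assert tier_confusion(with_c1, tier) == tier_confusion(without_c1, tier)

    def test_all_zero(self):
        assert tier_confusion({}, 2) == TierConfusion(2, 0, 0, 0)

    def test_unknown_tier_rejected(self):
        with pytest.raises(ValueError):
            tier_confusion(STUDY_COUNTS, 4)


class TestMetrics:
    def test_tier2_study_values(self):
        metrics = compute_metrics(TierConfusion(2, TP=332, FP=129, FN=1))
        assert round3(metrics.precision) == 0.720
        assert round3(metrics.recall) == 0.997
        assert round3(metrics.f1) == 0.836

    def test_tier3_study_values(self):
        metrics = compute_metrics(TierConfusion(3, TP=305, FP=156, FN=1))
        assert round3(metrics.recall) == 0.997
        assert round3(metrics.f1) == 0.795

    def test_perfect_detector(self):
        metrics = compute_metrics(TierConfusion(1, TP=5, FP=0, FN=0))
        assert (metrics.precision, metrics.recall, metrics.f1) == (1.0, 1.0, 1.0)

    def test_zero_denominators_flagged_not_zeroed(self):
        metrics = compute_metrics(TierConfusion(1, TP=0, FP=0, FN=0))
        assert metrics.precision is None and metrics.recall is None
        assert metrics.undefined == ("precision", "recall", "f1")

    def test_matches_independent_formula_on_random_counts(self):
        rng = random.Random(5)
        for _ in range(100):
            tp, fp, fn = rng.randint(1, 500), rng.randint(0, 500), rng.randint(0, 50)
            metrics = compute_metrics(TierConfusion(1, tp, fp, fn))
            precision = tp / (tp + fp)
            recall = tp / (tp + fn)
            assert metrics.precision == pytest.approx(precision)
            assert metrics.recall == pytest.approx(recall)
            assert metrics.f1 == pytest.approx(
                2 * precision * recall / (precision + recall)
            )
            # harmonic mean lies between precision and recall
            assert (
                min(precision, recall) - 1e-12
                <= metrics.f1
                <= max(precision, recall) + 1e-12
            )

    def test_precision_monotone_from_tier1_to_tier3(self):
        """Moving categories 3 and 4 from TP to FP keeps TP+FP fixed, so
        precision can only decrease from the tolerant to the strict tier."""
        rng = random.Random(17)
        for _ in range(100):
            counts = {c: rng.randint(0, 200) for c in range(1, 7)}
            if counts[2] + counts[3] + counts[4] + counts[5] == 0:
                counts[2] = 1
            metrics = {
                tier: compute_metrics(tier_confusion(counts, tier))
                for tier in (1, 2, 3)
            }
            p1, p2, p3 = (metrics[t].precision for t in (1, 2, 3))
            assert p1 >= p2 >= p3

    def test_recall_depends_only_on_tp_and_fn(self):
        counts = dict(STUDY_COUNTS)
        inflated = {**counts, 5: counts[5] + 1000}
        for tier in (1, 2, 3):
            a = compute_metrics(tier_confusion(counts, tier)).recall
            b = compute_metrics(tier_confusion(inflated, tier)).recall
            assert a == b

    def test_scale_invariance(self):
        for k in (2, 10):
            scaled = {c: v * k for c, v in STUDY_COUNTS.items()}
            for tier in (1, 2, 3):
                a = compute_metrics(tier_confusion(STUDY_COUNTS, tier))
                b = compute_metrics(tier_confusion(scaled, tier))
                assert a.precision == pytest.approx(b.precision)
                assert a.recall == pytest.approx(b.recall)
                assert a.f1 == pytest.approx(b.f1)


class TestCsvInterfaces:
    def test_annotation_roundtrip_and_order_invariance(self, tmp_path):
        records = records_from_counts({2: 3, 4: 1, 6: 1})
        path = tmp_path / "ann.csv"
        write_annotations(path, records)
        loaded = read_annotations(path)
        assert tally_categories(loaded) == tally_categories(records)

        rng = random.Random(0)
        shuffled = list(records)
        rng.shuffle(shuffled)
        path2 = tmp_path / "ann2.csv"
        write_annotations(path2, shuffled)
        assert evaluate_annotations(read_annotations(path2)) == evaluate_annotations(
            loaded
        )

    def test_schema_errors_name_the_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "pair_id,term,category,comment\np1,t,2,\np2,t,9,\n", encoding="utf-8"
        )
        with pytest.raises(AnnotationError, match=":3"):
            read_annotations(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("pair_id,term\np1,t\n", encoding="utf-8")
        with pytest.raises(AnnotationError, match="category"):
            read_annotations(path)

    def test_metrics_csv_has_undefined_markers(self, tmp_path):
        path = tmp_path / "metrics.csv"
        write_metrics_csv(path, evaluate_annotations([]))
        content = path.read_text("utf-8")
        assert "undefined" in content
        assert content.splitlines()[0] == "tier,TP,FP,FN,precision,recall,f1"
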