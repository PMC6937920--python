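"""Scoring, metrics closed forms, Cohen's kappa and count summaries."""

import random

import pytest

from birads_extract import (
    ConfusionCounts,
    GoldAnnotation,
    GoldFinding,
    GoldLesion,
    GoldValue,
    LesionRecord,
    ReportExtraction,
    cohen_kappa,
    compare_extractions,
    compute_metrics,
    perfect_recovery_fraction,
    summarize_counts,
    summarize_feature_counts,
)
from birads_extract.evaluation import SlotCounts
from birads_extract.extract import FeatureValue, SizeMeasurement


def _gold_single(features=None, final=4):
    features = features or {
        "location": GoldValue(value="the upper outer quadrant of the left breast"),
        "shape": GoldValue(value="oval"),
        "size": GoldValue(dims_mm=[16.0, 12.0]),
    }
    lesion = GoldLesion(
        entity_type="mass",
        location="the upper outer quadrant of the left breast",
        features=features,
        feature_count=len(features),
    )
    return GoldAnnotation(
        report_id="r1",
        lesions=[lesion],
        index_lesion_index=0,
        birads_per_lesion=[final],
        final_birads=final,
    )


def _pred_from_gold(gold: GoldAnnotation) -> ReportExtraction:
    lesions = []
    for i, g in enumerate(gold.lesions):
        values = {}
        for name, gv in g.features.items():
            if gv.dims_mm is not None:
                values[name] = FeatureValue(size=SizeMeasurement(dimensions_mm=gv.dims_mm))
            else:
                values[name] = FeatureValue(value=gv.value)
        lesion = LesionRecord(
            lesion_index=i,
            entity_type=g.entity_type,
            section_index=i,
            location=g.location,
            feature_values=values,
        )
        lesion.recount()
        lesions.append(lesion)
    return ReportExtraction(
        report_id=gold.report_id,
        lesions=lesions,
        index_lesion_index=gold.index_lesion_index,
        birads_per_lesion=list(gold.birads_per_lesion),
        final_birads=gold.final_birads,
    )


# ---------------------------------------------------------------------------
# comparison protocol
# ---------------------------------------------------------------------------


def test_identical_prediction_has_no_errors():
    gold = _gold_single()
    counts = compare_extractions([_pred_from_gold(gold)], [gold])
    for slot in counts.slots.values():
        assert slot.fp == 0 and slot.fn == 0
    assert counts.slots["mass.shape"].tp == 1
    assert counts.slots["index_lesion"].tp == 1
    assert counts.slots["birads_category"].tp == 1


def test_missing_feature_is_false_negative_not_detected():
    gold = _gold_single()
    pred = _pred_from_gold(gold)
    del pred.lesions[0].feature_values["shape"]
    pred.lesions[0].recount()
    counts = compare_extractions([pred], [gold])
    slot = counts.slots["mass.shape"]
    assert (slot.fn, slot.not_detected, slot.fp) == (1, 1, 0)


def test_wrong_value_counts_fp_and_fn_not_detected_correctly():
    gold = _gold_single()
    pred = _pred_from_gold(gold)
    pred.lesions[0].feature_values["shape"] = FeatureValue(value="round")
    counts = compare_extractions([pred], [gold])
    slot = counts.slots["mass.shape"]
    assert (slot.fp, slot.fn, slot.not_detected_correctly) == (1, 1, 1)


def test_finding_polarity_mismatch_scored_as_wrong_value():
    gold = _gold_single()
    gold.associated_findings = [GoldFinding(finding="skin_invasion", polarity="negated")]
    pred = _pred_from_gold(gold)
    counts = compare_extractions([pred], [gold])
    assert counts.slots["skin_invasion"].not_detected == 1

    from birads_extract import AssociatedFinding

    pred.associated_findings = [AssociatedFinding(finding="skin_invasion", polarity="asserted")]
    counts = compare_extractions([pred], [gold])
    assert counts.slots["skin_invasion"].not_detected_correctly == 1


def test_report_id_mismatch_raises():
    gold = _gold_single()
    pred = _pred_from_gold(gold)
    pred.report_id = "other"
    with pytest.raises(ValueError, match="report_id mismatch"):
        compare_extractions([pred], [gold])


def test_pipeline_self_agreement_on_synthetic_corpus(lexicon):
    from birads_extract import CorpusConfig, generate_corpus, run_pipeline

    reports, golds = generate_corpus(CorpusConfig(n_reports=40, seed=21), lexicon)
    preds = run_pipeline(reports, lexicon)
    counts = compare_extractions(preds, golds)
    assert all(s.fp == 0 and s.fn == 0 for s in counts.slots.values())
    assert perfect_recovery_fraction(preds, golds) == 1.0


# ---------------------------------------------------------------------------
# metric closed forms
# ---------------------------------------------------------------------------


def test_recall_precision_formulas():
    counts = ConfusionCounts(slots={"s": SlotCounts(tp=9, fn=1, fp=0)})
    report = compute_metrics(counts)
    assert report.slots["s"].recall == pytest.approx(0.9)
    assert report.slots["s"].precision == pytest.approx(1.0)


def test_zero_denominators_flagged_not_zeroed():
    counts = ConfusionCounts(slots={"s": SlotCounts()})
    metrics = compute_metrics(counts).slots["s"]
    assert metrics.recall is None and metrics.precision is None
    assert set(metrics.undefined) == {"recall", "precision"}


def test_micro_average_pools_counts():
    counts = ConfusionCounts(
        slots={"a": SlotCounts(tp=8, fn=2), "b": SlotCounts(tp=6, fn=4)}
    )
    assert compute_metrics(counts).overall_recall == pytest.approx(14 / 20)


def test_micro_metrics_match_bruteforce_tally():
    rng = random.Random(0)
    slots = {
        f"s{i}": SlotCounts(
            tp=rng.randint(0, 20), fp=rng.randint(0, 10), fn=rng.randint(0, 10)
        )
        for i in range(12)
    }
    report = compute_metrics(ConfusionCounts(slots=slots))
    tp = sum(c.tp for c in slots.values())
    fp = sum(c.fp for c in slots.values())
    fn = sum(c.fn for c in slots.values())
    assert report.overall_recall == pytest.approx(tp / (tp + fn))
    assert report.overall_precision == pytest.approx(tp / (tp + fp))


# ---------------------------------------------------------------------------
# Cohen's kappa
# ---------------------------------------------------------------------------


def test_kappa_identical_ratings():
    assert cohen_kappa([1, 2, 3, 2], [1, 2, 3, 2]) == 1.0


def test_kappa_two_by_two_agreement_table():
    # 45 agreements on each class, 5 + 5 disagreements: p_o=0.9, p_e=0.5
    a = [0] * 45 + [0] * 5 + [1] * 5 + [1] * 45
    b = [0] * 45 + [1] * 5 + [0] * 5 + [1] * 45
    assert cohen_kappa(a, b) == pytest.approx(0.8)


def test_kappa_chance_level_is_zero():
    assert cohen_kappa([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(0.0)


def test_kappa_errors_and_symmetry():
    with pytest.raises(ValueError, match="length"):
        cohen_kappa([1, 2], [1])
    rng = random.Random(5)
    a = [rng.choice("xyz") for _ in range(60)]
    b = [rng.choice("xyz") for _ in range(60)]
    assert cohen_kappa(a, b) == pytest.approx(cohen_kappa(b, a))


def test_kappa_agrees_with_independent_reference():
    from sklearn.metrics import cohen_kappa_score

    rng = random.Random(17)
    for _ in range(5):
        a = [rng.choice([2, 3, 4, 5, 6]) for _ in range(80)]
        b = [rng.choice([2, 3, 4, 5, 6]) for _ in range(80)]
        assert cohen_kappa(a, b) == pytest.approx(cohen_kappa_score(a, b), abs=1e-12)


# ---------------------------------------------------------------------------
# feature-count summaries
# ---------------------------------------------------------------------------


def test_summary_mean_of_two_counts():
    assert summarize_counts([9, 3]).mean == pytest.approx(6.0)


def test_summary_single_count_degenerate_ci():
    stats = summarize_counts([7])
    assert stats.sd == 0.0
    assert stats.ci_low == stats.ci_high == 7.0


def test_summary_five_count_fixture():
    stats = summarize_counts([5, 6, 7, 8, 9])
    assert stats.mean == pytest.approx(7.0)
    assert stats.sd == pytest.approx(1.5811, abs=1e-4)
    assert stats.ci_low == pytest.approx(5.614, abs=1e-3)
    assert stats.ci_high == pytest.approx(8.386, abs=1e-3)


def test_summarize_feature_counts_requires_lesions():
    with pytest.raises(ValueError):
        summarize_feature_counts([ReportExtraction(report_id="r")])


def test_summarize_feature_counts_over_extractions():
    gold = _gold_single()
    stats = summarize_feature_counts([_pred_from_gold(gold)])
    assert stats["all_lesions"].n == 1
    assert stats["index_lesions"].mean == pytest.approx(3.0)
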