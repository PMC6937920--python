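"""Scoring of predicted extractions against gold annotations.

Slots follow the error-analysis layout of the target system: one slot per
entity-qualified feature ("mass.shape", "nme.scope"), one per associated
finding, one for index-lesion identity and one for the final BI-RADS
category.  Lesion correspondence is by location phrase first, remaining
lesions by document order.  A missing predicted slot counts as a false
negative classed ``not_detected``; a wrong value counts as a false
positive plus false negative classed ``not_detected_correctly``.

Also provides Cohen's kappa for inter-rater agreement and summary
statistics (mean, SD, normal-approximation 95% CI) of feature counts.
"""

from __future__ import annotations

import math
from collections import Counter
from typing import Optional, Sequence

import pandas as pd
from pydantic import BaseModel, Field

from .pipeline import ReportExtraction
from .synthetic import GoldAnnotation, GoldLesion, GoldValue

SIZE_TOLERANCE_MM = 0.1


class SlotCounts(BaseModel):
    tp: int = 0
    fp: int = 0
    fn: int = 0
    not_detected: int = 0
    not_detected_correctly: int = 0


class ConfusionCounts(BaseModel):
    """Per-slot confusion counts over a corpus."""

    slots: dict[str, SlotCounts] = Field(default_factory=dict)

    def slot(self, name: str) -> SlotCounts:
        return self.slots.setdefault(name, SlotCounts())

    def merged(self, other: "ConfusionCounts") -> "ConfusionCounts":
        out = ConfusionCounts()
        for src in (self, other):
            for name, c in src.slots.items():
                s = out.slot(name)
                s.tp += c.tp
                s.fp += c.fp
                s.fn += c.fn
                s.not_detected += c.not_detected
                s.not_detected_correctly += c.not_detected_correctly
        return out


class SlotMetrics(BaseModel):
    tp: int
    fp: int
    fn: int
    not_detected: int
    not_detected_correctly: int
    recall: Optional[float] = None
    precision: Optional[float] = None
    undefined: list[str] = Field(default_factory=list)


class Stats(BaseModel):
    n: int
    mean: float
    sd: float
    ci_low: float
    ci_high: float
    minimum: float
    maximum: float


class EvalReport(BaseModel):
    slots: dict[str, SlotMetrics] = Field(default_factory=dict)
    overall_recall: Optional[float] = None
    overall_precision: Optional[float] = None
    kappa: dict[str, float] = Field(default_factory=dict)


def _values_equal(pred_value, pred_size, gold: GoldValue, tol: float) -> bool:
    if gold.dims_mm is not None:
        if pred_size is None or len(pred_size.dimensions_mm) != len(gold.dims_mm):
            return False
        return all(
            abs(a - b) <= tol for a, b in zip(pred_size.dimensions_mm, gold.dims_mm)
        )
    if pred_value is None:
        return False
    return pred_value.casefold() == (gold.value or "").casefold()


def _match_lesions(
    pred: ReportExtraction, gold: GoldAnnotation
) -> list[tuple[Optional[int], Optional[int]]]:
    """Pair gold and predicted lesions: by location phrase, then by order."""
    pairs: list[tuple[Optional[int], Optional[int]]] = []
    used_pred: set[int] = set()
    unmatched_gold: list[int] = []
    pred_by_loc: dict[str, int] = {}
    for j, lesion in enumerate(pred.lesions):
        if lesion.location and lesion.location.casefold() not in pred_by_loc:
            pred_by_loc[lesion.location.casefold()] = j
    for i, g in enumerate(gold.lesions):
        j = pred_by_loc.get(g.location.casefold())
        if j is not None and j not in used_pred:
            pairs.append((i, j))
            used_pred.add(j)
        else:
            unmatched_gold.append(i)
    remaining_pred = [j for j in range(len(pred.lesions)) if j not in used_pred]
    for i, j in zip(unmatched_gold, remaining_pred):
        pairs.append((i, j))
        used_pred.add(j)
    matched_gold = {i for i, _ in pairs}
    pairs.extend((i, None) for i in range(len(gold.lesions)) if i not in matched_gold)
    pairs.extend((None, j) for j in range(len(pred.lesions)) if j not in used_pred)
    return sorted(pairs, key=lambda p: (p[0] is None, p[0] if p[0] is not None else p[1]))


def _score_report(
    pred: ReportExtraction,
    gold: GoldAnnotation,
    counts: ConfusionCounts,
    tol: float,
) -> None:
    pairs = _match_lesions(pred, gold)
    gold_to_pred = {i: j for i, j in pairs if i is not None}

    # --- index lesion identity ---
    slot = counts.slot("index_lesion")
    if gold.index_lesion_index is not None:
        mapped = gold_to_pred.get(gold.index_lesion_index)
        if pred.index_lesion_index is None or mapped is None:
            slot.fn += 1
            slot.not_detected += 1
        elif pred.index_lesion_index == mapped:
            slot.tp += 1
        else:
            slot.fp += 1
            slot.fn += 1
            slot.not_detected_correctly += 1
    elif pred.index_lesion_index is not None:
        slot.fp += 1

    # --- feature slots ---
    for i, j in pairs:
        g: Optional[GoldLesion] = gold.lesions[i] if i is not None else None
        p = pred.lesions[j] if j is not None else None
        entity = g.entity_type if g is not None else (p.entity_type if p else "unknown")
        gold_feats = g.features if g is not None else {}
        pred_feats = p.feature_values if p is not None else {}
        for name, gv in gold_feats.items():
            slot = counts.slot(f"{entity}.{name}")
            pv = pred_feats.get(name)
            if pv is None or pv.polarity != "asserted":
                slot.fn += 1
                slot.not_detected += 1
            elif _values_equal(pv.value, pv.size, gv, tol):
                slot.tp += 1
            else:
                slot.fp += 1
                slot.fn += 1
                slot.not_detected_correctly += 1
        for name, pv in pred_feats.items():
            if name not in gold_feats and pv.polarity == "asserted":
                counts.slot(f"{entity}.{name}").fp += 1

    # --- associated findings ---
    gold_findings = {f.finding: f.polarity for f in gold.associated_findings}
    pred_findings = {f.finding: f.polarity for f in pred.associated_findings}
    for name, gpol in gold_findings.items():
        slot = counts.slot(name)
        ppol = pred_findings.get(name)
        if ppol is None:
            slot.fn += 1
            slot.not_detected += 1
        elif ppol == gpol:
            slot.tp += 1
        else:
            slot.fp += 1
            slot.fn += 1
            slot.not_detected_correctly += 1
    for name in pred_findings:
        if name not in gold_findings:
            counts.slot(name).fp += 1

    # --- final BI-RADS category ---
    slot = counts.slot("birads_category")
    if pred.final_birads is None:
        slot.fn += 1
        slot.not_detected += 1
    elif pred.final_birads == gold.final_birads:
        slot.tp += 1
    else:
        slot.fp += 1
        slot.fn += 1
        slot.not_detected_correctly += 1


def compare_extractions(
    pred: Sequence[ReportExtraction],
    gold: Sequence[GoldAnnotation],
    size_tolerance_mm: float = SIZE_TOLERANCE_MM,
) -> ConfusionCounts:
    """Score predictions against gold; both must cover the same report ids."""
    pred_by_id = {p.report_id: p for p in pred}
    gold_by_id = {g.report_id: g for g in gold}
    missing = sorted(set(gold_by_id) ^ set(pred_by_id))
    if missing:
        raise ValueError(f"report_id mismatch between pred and gold: {missing}")
    counts = ConfusionCounts()
    for rid in sorted(gold_by_id):
        _score_report(pred_by_id[rid], gold_by_id[rid], counts, size_tolerance_mm)
    return counts


def compute_metrics(counts: ConfusionCounts) -> EvalReport:
    """Per-slot and micro-averaged (pooled-count) recall and precision.

    Zero denominators leave the metric ``None`` and are listed in the
    slot's ``undefined`` field rather than silently reported as 0.
    """
    report = EvalReport()
    total_tp = total_fp = total_fn = 0
    for name in sorted(counts.slots):
        c = counts.slots[name]
        metrics = SlotMetrics(
            tp=c.tp,
            fp=c.fp,
            fn=c.fn,
            not_detected=c.not_detected,
            not_detected_correctly=c.not_detected_correctly,
        )
        if c.tp + c.fn > 0:
            metrics.recall = c.tp / (c.tp + c.fn)
        else:
            metrics.undefined.append("recall")
        if c.tp + c.fp > 0:
            metrics.precision = c.tp / (c.tp + c.fp)
        else:
            metrics.undefined.append("precision")
        report.slots[name] = metrics
        total_tp += c.tp
        total_fp += c.fp
        total_fn += c.fn
    if total_tp + total_fn > 0:
        report.overall_recall = total_tp / (total_tp + total_fn)
    if total_tp + total_fp > 0:
        report.overall_precision = total_tp / (total_tp + total_fp)
    return report


def metrics_to_dataframe(report: EvalReport) -> pd.DataFrame:
    """Tabular (CSV-ready) form: one row per slot plus an Overall row."""
    rows = []
    for name, m in report.slots.items():
        rows.append(
            {
                "slot": name,
                "TP": m.tp,
                "FP": m.fp,
                "FN": m.fn,
                "not_detected": m.not_detected,
                "not_detected_correctly": m.not_detected_correctly,
                "recall": m.recall,
                "precision": m.precision,
            }
        )
    rows.append(
        {
            "slot": "Overall",
            "TP": sum(m.tp for m in report.slots.values()),
            "FP": sum(m.fp for m in report.slots.values()),
            "FN": sum(m.fn for m in report.slots.values()),
            "not_detected": sum(m.not_detected for m in report.slots.values()),
            "not_detected_correctly": sum(
                m.not_detected_correctly for m in report.slots.values()
            ),
            "recall": report.overall_recall,
            "precision": report.overall_precision,
        }
    )
    return pd.DataFrame(rows)


def cohen_kappa(labels_a: Sequence, labels_b: Sequence) -> float:
    """Chance-corrected agreement between two raters.

    kappa = (p_o - p_e) / (1 - p_e) with p_o the observed agreement and
    p_e the chance agreement from the raters' marginal distributions.
    Returns 1.0 for perfect agreement even when p_e == 1 (both raters
    constant and identical).
    """
    if len(labels_a) != len(labels_b):
        raise ValueError(
            f"label lists differ in length: {len(labels_a)} vs {len(labels_b)}"
        )
    if not labels_a:
        raise ValueError("label lists must be non-empty")
    n = len(labels_a)
    p_o = sum(a == b for a, b in zip(labels_a, labels_b)) / n
    marg_a = Counter(labels_a)
    marg_b = Counter(labels_b)
    p_e = sum(marg_a[k] * marg_b.get(k, 0) for k in marg_a) / (n * n)
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


def summarize_counts(values: Sequence[float]) -> Stats:
    """Mean, sample SD and normal-approximation 95% CI of a value list."""
    if not values:
        raise ValueError("cannot summarize an empty list")
    n = len(values)
    mean = sum(values) / n
    if n > 1:
        sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
    else:
        sd = 0.0
    half = 1.96 * sd / math.sqrt(n)
    return Stats(
        n=n,
        mean=mean,
        sd=sd,
        ci_low=mean - half,
        ci_high=mean + half,
        minimum=min(values),
        maximum=max(values),
    )


def summarize_feature_counts(
    extractions: Sequence[ReportExtraction],
) -> dict[str, Stats]:
    """Feature-count statistics over all lesions and over index lesions."""
    all_counts = [l.feature_count for e in extractions for l in e.lesions]
    index_counts = [
        e.lesions[e.index_lesion_index].feature_count
        for e in extractions
        if e.index_lesion_index is not None
    ]
    if not all_counts:
        raise ValueError("no lesions present in the extractions")
    return {
        "all_lesions": summarize_counts(all_counts),
        "index_lesions": summarize_counts(index_counts),
    }


def perfect_recovery_fraction(
    pred: Sequence[ReportExtraction],
    gold: Sequence[GoldAnnotation],
    size_tolerance_mm: float = SIZE_TOLERANCE_MM,
) -> float:
    """Fraction of reports whose extraction matches gold on every slot.

    A report counts as perfectly recovered when index-lesion identity,
    every feature value, every associated-finding polarity and the final
    BI-RADS category agree with gold, with no spurious extractions.
    """
    pred_by_id = {p.report_id: p for p in pred}
    gold_by_id = {g.report_id: g for g in gold}
    missing = sorted(set(gold_by_id) ^ set(pred_by_id))
    if missing:
        raise ValueError(f"report_id mismatch between pred and gold: {missing}")
    if not gold:
        raise ValueError("empty corpus")
    perfect = 0
    for rid in gold_by_id:
        counts = ConfusionCounts()
        _score_report(pred_by_id[rid], gold_by_id[rid], counts, size_tolerance_mm)
        if all(c.fp == 0 and c.fn == 0 for c in counts.slots.values()):
            perfect += 1
    return perfect / len(gold_by_id)
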