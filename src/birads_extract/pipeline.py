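"""Index-lesion selection, BI-RADS category extraction, final assembly.

The index lesion is defined as the lesion described with the largest
number of imaging features; ties (only possible if a generator or report
actually produces them) break by larger maximal size dimension, then by
document order, and are surfaced via ``tie_flag``.  BI-RADS categories are
read from the diagnostic impression only, as ``<marker> ... <digit>``
patterns within a sentence; the final category is the maximum found.
Reports with no lesion and no stated category default to BI-RADS 1
(negative examination); reports with lesions but no recoverable category
are flagged missing rather than guessed.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

from pydantic import BaseModel, Field

from .extract import (
    AssociatedFinding,
    LesionRecord,
    assemble_lesions,
    detect_negation,
    match_concepts,
)
from .lexicon import Lexicon, default_lexicon
from .preprocess import AnnotatedToken, RawReport, tokenize_and_annotate

logger = logging.getLogger(__name__)


class ReportExtraction(BaseModel):
    """Final structured output for one report."""

    report_id: str
    lesions: list[LesionRecord] = Field(default_factory=list)
    index_lesion_index: Optional[int] = None
    tie_flag: bool = False
    associated_findings: list[AssociatedFinding] = Field(default_factory=list)
    birads_per_lesion: list[int] = Field(default_factory=list)
    final_birads: Optional[int] = None
    warnings: list[str] = Field(default_factory=list)


def count_features(lesion: LesionRecord) -> int:
    """Number of asserted features on a lesion (negated ones do not count)."""
    return sum(1 for fv in lesion.feature_values.values() if fv.polarity == "asserted")


def select_index_lesion(
    lesions: Sequence[LesionRecord],
) -> tuple[Optional[int], bool]:
    """Pick the lesion with the most imaging features.

    Returns ``(ordinal, tie_flag)``; ties break by larger maximal size
    dimension, then by document order.  ``tie_flag`` is set whenever the
    maximal feature count was shared.
    """
    if not lesions:
        return None, False
    counts = [count_features(l) for l in lesions]
    best = max(counts)
    candidates = [i for i, c in enumerate(counts) if c == best]
    tie_flag = len(candidates) > 1
    if tie_flag:
        def size_key(i: int) -> float:
            dim = lesions[i].max_dimension_mm()
            return dim if dim is not None else float("-inf")

        best_size = max(size_key(i) for i in candidates)
        candidates = [i for i in candidates if size_key(i) == best_size]
        logger.debug("index tie broken by size/order among lesions %s", candidates)
    return candidates[0], tie_flag


def extract_birads(
    impression_tokens: Sequence[AnnotatedToken], lexicon: Lexicon
) -> tuple[list[int], list[str]]:
    """Read BI-RADS categories from tokenized impression text.

    Each marker token followed (in the same sentence) by an integer yields
    one category; digits outside 0-6 are flagged and skipped.  Returns
    ``(categories_in_order, warnings)``.
    """
    sentences: dict[int, list[AnnotatedToken]] = {}
    for tok in impression_tokens:
        sentences.setdefault(tok.sentence_index, []).append(tok)
    allowed = set(lexicon.birads_values)
    categories: list[int] = []
    warnings: list[str] = []
    for _, toks in sorted(sentences.items()):
        toks = sorted(toks, key=lambda t: t.token_index)
        for i, tok in enumerate(toks):
            if tok.concept_kind != "birads_marker":
                continue
            for nxt in toks[i + 1 :]:
                if nxt.surface.isdigit():
                    value = int(nxt.surface)
                    if value in allowed:
                        categories.append(value)
                    else:
                        warnings.append(f"BI-RADS digit out of range skipped: {value}")
                    break
    return categories, warnings


def finalize_extraction(
    report_id: str,
    lesions: Sequence[LesionRecord],
    findings: Sequence[AssociatedFinding],
    categories: Sequence[int],
    warnings: Sequence[str] = (),
) -> ReportExtraction:
    """Compose the final per-report extraction.

    ``final_birads`` is the maximum stated category; a lesion-free report
    with no category defaults to 1; lesions without any category leave the
    field missing with a warning.
    """
    warnings = list(warnings)
    index, tie_flag = select_index_lesion(lesions)
    if categories:
        final: Optional[int] = max(categories)
    elif not lesions:
        final = 1
    else:
        final = None
        warnings.append("lesions present but no BI-RADS category found in impression")
    return ReportExtraction(
        report_id=report_id,
        lesions=list(lesions),
        index_lesion_index=index,
        tie_flag=tie_flag,
        associated_findings=list(findings),
        birads_per_lesion=list(categories),
        final_birads=final,
        warnings=warnings,
    )


def extract_report(raw: RawReport, lexicon: Optional[Lexicon] = None) -> ReportExtraction:
    """Run the full pipeline on a single report."""
    lexicon = lexicon or default_lexicon()
    annotated = tokenize_and_annotate(raw, lexicon)
    mentions = match_concepts(annotated, lexicon)
    mentions = detect_negation(mentions, annotated, lexicon)
    lesions, findings, warnings = assemble_lesions(annotated, mentions, lexicon)
    categories, birads_warnings = extract_birads(annotated.impression_tokens, lexicon)
    return finalize_extraction(
        raw.report_id, lesions, findings, categories, warnings + birads_warnings
    )


def run_pipeline(
    reports: Sequence[RawReport], lexicon: Optional[Lexicon] = None
) -> list[ReportExtraction]:
    """Extract every report in input order; per-report failures are isolated.

    A report that raises is recorded as an empty extraction carrying the
    error message in ``warnings``; the remaining reports are unaffected.
    """
    lexicon = lexicon or default_lexicon()
    results: list[ReportExtraction] = []
    for raw in reports:
        try:
            results.append(extract_report(raw, lexicon))
        except Exception as exc:  # noqa: BLE001 - per-report isolation
            logger.error("report %s failed: %s", raw.report_id, exc)
            results.append(
                ReportExtraction(
                    report_id=raw.report_id,
                    warnings=[f"extraction failed: {exc}"],
                )
            )
    return results
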