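"""Report normalization and decomposition into sections, sentences, tokens.

A breast MRI report consists of an imaging description and a diagnostic
impression.  The description is segmented into *sections*, one per lesion:
a section opens with a lesion-introducing sentence that names a lesion
entity (mass or non-mass enhancement) and an anatomical location, and runs
until the next such sentence.  Sentences are split on periods, with a guard
so decimal points inside measurements ("1.1 cm") never break a sentence.
Tokens are whitespace/punctuation split and then greedily merged
longest-match-first into multiword lexicon terms; each token carries
0-based (section, sentence, token) indices.
"""

from __future__ import annotations

import logging
import re
from typing import Optional

from pydantic import BaseModel, Field

from .lexicon import ConceptHit, Lexicon, tokenize_text

logger = logging.getLogger(__name__)

#: section_index used for tokens of the diagnostic impression block
IMPRESSION_SECTION = -1

_PUNCT_ATTACH = {",", ".", ":", ";", ")"}


class RawReport(BaseModel):
    """A free-text report: imaging description plus diagnostic impression."""

    report_id: str
    description: str = ""
    impression: str = ""


class Section(BaseModel):
    """One description section; lesion sections open with a location anchor."""

    section_index: int
    anchor_location: Optional[str] = None
    is_preamble: bool = False
    sentences: list[str] = Field(default_factory=list)


class AnnotatedToken(BaseModel):
    """A (possibly multiword-merged) token with its position indices."""

    surface: str
    normalized: str
    section_index: int
    sentence_index: int
    token_index: int
    concept_id: Optional[str] = None
    concept_kind: Optional[str] = None
    match_type: Optional[str] = None


class AnnotatedReport(BaseModel):
    """The fully decomposed report the matcher operates on."""

    report_id: str
    sections: list[Section] = Field(default_factory=list)
    tokens: list[AnnotatedToken] = Field(default_factory=list)
    impression_sentences: list[str] = Field(default_factory=list)
    impression_tokens: list[AnnotatedToken] = Field(default_factory=list)


def _replace_terms(text: str, table: dict[str, str], *, ignore_case: bool) -> str:
    for wrong, right in table.items():
        pattern = re.compile(rf"\b{re.escape(wrong)}\b", re.IGNORECASE if ignore_case else 0)
        new_text, n = pattern.subn(right, text)
        if n:
            logger.debug("normalize: %r -> %r (%d occurrence(s))", wrong, right, n)
            text = new_text
    return text


def normalize_report(raw: RawReport, lexicon: Lexicon) -> RawReport:
    """Apply spelling corrections and abbreviation expansions.

    Corrections are case-insensitive, expansions case-sensitive, both at
    word boundaries.  The operation is idempotent: corrected/expanded forms
    are never themselves keys of the tables.
    """

    def fix(text: str) -> str:
        text = _replace_terms(text, lexicon.spelling_corrections, ignore_case=True)
        text = _replace_terms(text, lexicon.abbreviation_expansions, ignore_case=False)
        return text

    return RawReport(
        report_id=raw.report_id,
        description=fix(raw.description),
        impression=fix(raw.impression),
    )


def segment_sentences(section_text: str) -> list[str]:
    """Split text at periods, except decimal points inside numbers.

    A period with a digit immediately on both sides is part of a number
    ("1.1 cm") and never a sentence boundary.  Empty fragments are dropped.
    """
    sentences: list[str] = []
    buf: list[str] = []
    for i, ch in enumerate(section_text):
        if ch == "." and not (
            i > 0
            and section_text[i - 1].isdigit()
            and i + 1 < len(section_text)
            and section_text[i + 1].isdigit()
        ):
            fragment = "".join(buf).strip()
            if fragment:
                sentences.append(fragment)
            buf = []
        else:
            buf.append(ch)
    tail = "".join(buf).strip()
    if tail:
        sentences.append(tail)
    return sentences


def _sentence_anchor(sentence: str, lexicon: Lexicon) -> Optional[str]:
    """Location anchor of a lesion-introducing sentence, else ``None``.

    A sentence introduces a lesion when it names a lesion entity (mass /
    non-mass enhancement, possibly via synonym) and contains a location
    phrase; the location works both at the start (original word order) and
    the end ("There is a ... in <location>") of the sentence.
    """
    has_entity = False
    location: Optional[str] = None
    for surface, hit in lexicon.merge_tokens(tokenize_text(sentence)):
        if hit is None:
            continue
        if hit.kind == "entity":
            has_entity = True
        elif hit.kind == "value" and location is None:
            if "location" in lexicon.value_owners.get(hit.concept_id, []):
                location = hit.concept_id
    return location if (has_entity and location is not None) else None


def segment_sections(description_text: str, lexicon: Lexicon) -> list[Section]:
    """Split a normalized description into per-lesion sections.

    Sentences before the first anchor go into a preamble pseudo-section
    flagged non-lesion; an empty description yields no sections.
    """
    sentences = segment_sentences(description_text)
    sections: list[Section] = []
    current: Optional[Section] = None
    for sentence in sentences:
        anchor = _sentence_anchor(sentence, lexicon)
        if anchor is not None:
            current = Section(
                section_index=len(sections), anchor_location=anchor, sentences=[sentence]
            )
            sections.append(current)
        elif current is not None:
            current.sentences.append(sentence)
        else:
            current = Section(
                section_index=len(sections), is_preamble=True, sentences=[sentence]
            )
            sections.append(current)
    return sections


def _annotate_sentence(
    sentence: str, section_index: int, sentence_index: int, lexicon: Lexicon
) -> list[AnnotatedToken]:
    tokens: list[AnnotatedToken] = []
    for k, (surface, hit) in enumerate(lexicon.merge_tokens(tokenize_text(sentence))):
        if hit is not None and hit.kind == "value":
            normalized = hit.concept_id
        elif hit is not None:
            # entity/feature ids are not surfaces; normalize to the exact-match
            # surface form so round-tripping stays readable
            normalized = surface.casefold() if hit.match_type == "exact" else hit.concept_id
        else:
            normalized = surface.casefold()
        tokens.append(
            AnnotatedToken(
                surface=surface,
                normalized=normalized,
                section_index=section_index,
                sentence_index=sentence_index,
                token_index=k,
                concept_id=hit.concept_id if hit else None,
                concept_kind=hit.kind if hit else None,
                match_type=hit.match_type if hit else None,
            )
        )
    return tokens


def tokenize_and_annotate(raw: RawReport, lexicon: Lexicon) -> AnnotatedReport:
    """Full preprocessing pipeline: normalize, segment, tokenize, index.

    The impression block is sentence-segmented and tokenized with
    ``section_index == IMPRESSION_SECTION`` but not split into location
    sections; BI-RADS categories are read from it downstream.
    """
    normalized = normalize_report(raw, lexicon)
    sections = segment_sections(normalized.description, lexicon)
    tokens: list[AnnotatedToken] = []
    for section in sections:
        for s_idx, sentence in enumerate(section.sentences):
            tokens.extend(_annotate_sentence(sentence, section.section_index, s_idx, lexicon))
    impression_sentences = segment_sentences(normalized.impression)
    impression_tokens: list[AnnotatedToken] = []
    for s_idx, sentence in enumerate(impression_sentences):
        impression_tokens.extend(
            _annotate_sentence(sentence, IMPRESSION_SECTION, s_idx, lexicon)
        )
    return AnnotatedReport(
        report_id=normalized.report_id,
        sections=sections,
        tokens=tokens,
        impression_sentences=impression_sentences,
        impression_tokens=impression_tokens,
    )


def detokenize(surfaces: list[str]) -> str:
    """Join token surfaces back into sentence text.

    Policy: single spaces between tokens, with no space before attaching
    punctuation (``, . : ;``) or after an opening parenthesis.
    """
    out: list[str] = []
    for surface in surfaces:
        if out and surface in _PUNCT_ATTACH:
            out[-1] = out[-1] + surface
        elif out and out[-1].endswith("("):
            out[-1] = out[-1] + surface
        else:
            out.append(surface)
    return " ".join(out)
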