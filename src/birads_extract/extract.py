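"""Concept matching, negation detection, size parsing and lesion assembly.

Concept mentions are produced for lesion entities, feature values and
associated findings.  Bare feature-name tokens ("margin", "T2WI") do not
become mentions; they stay in the token stream where they disambiguate
values shared between features ("irregular margin" vs an irregular shape,
"high signal in T2WI" vs DWI).

Negation follows a token-distance rule: a mention is negated when a cue
("no", "without", ...) occurs in the same sentence on the configured side
with at most ``negation_window`` tokens (default three) strictly between
cue and mention.
"""

from __future__ import annotations

import logging
import re
from typing import Literal, Optional, Union

from pydantic import BaseModel, Field

from .lexicon import Lexicon
from .preprocess import AnnotatedReport, AnnotatedToken

logger = logging.getLogger(__name__)

Polarity = Literal["asserted", "negated"]

_NUM_RE = re.compile(r"\d+(?:\.\d+)?$")
_SIZE_RE = re.compile(
    r"\s*\d+(?:\.\d+)?\s*(?:cm|mm)(?:\s*[×x]\s*\d+(?:\.\d+)?\s*(?:cm|mm)){0,2}\s*$",
    re.IGNORECASE,
)
_DIM_RE = re.compile(r"(\d+(?:\.\d+)?)\s*(cm|mm)", re.IGNORECASE)

#: maximum tokens between a value and a disambiguating feature name
_ATTACH_WINDOW = 2


class SizeParseError(ValueError):
    """Raised for text that does not match the size grammar."""


class SizeMeasurement(BaseModel):
    """One to three lesion dimensions, normalized to millimetres."""

    dimensions_mm: list[float]
    raw_text: str = ""


class ConceptMention(BaseModel):
    """One matched concept occurrence with span, match type and polarity."""

    concept_id: str
    concept_kind: Literal["entity", "value", "feature"]
    feature_owner: Optional[str] = None
    section_index: int
    sentence_index: int
    first_token: int
    last_token: int  # half-open
    match_type: Literal["exact", "synonym"] = "exact"
    polarity: Polarity = "asserted"
    size: Optional[SizeMeasurement] = None
    surface: str = ""


class FeatureValue(BaseModel):
    """The value filled into one feature slot of a lesion."""

    value: Optional[str] = None
    size: Optional[SizeMeasurement] = None
    polarity: Polarity = "asserted"


class LesionRecord(BaseModel):
    """One lesion: entity type, location, feature->value map and count."""

    lesion_index: int
    entity_type: Literal["mass", "nme", "unknown"]
    section_index: int
    location: Optional[str] = None
    feature_values: dict[str, FeatureValue] = Field(default_factory=dict)
    feature_count: int = 0

    def recount(self) -> int:
        self.feature_count = sum(
            1 for fv in self.feature_values.values() if fv.polarity == "asserted"
        )
        return self.feature_count

    def max_dimension_mm(self) -> Optional[float]:
        for fv in self.feature_values.values():
            if fv.size is not None and fv.size.dimensions_mm:
                return max(fv.size.dimensions_mm)
        return None


class AssociatedFinding(BaseModel):
    """A report-level finding (lymphadenopathy or an invasion) with polarity."""

    finding: str
    polarity: Literal["asserted", "negated", "absent"] = "asserted"


def parse_size(size_text: str) -> SizeMeasurement:
    """Parse ``1.1 cm × 1.0 cm × 1.5 cm`` style expressions into mm.

    Accepts one to three dimensions, units cm or mm, separators ``×`` or
    ``x``; cm values are multiplied by 10.  Raises :class:`SizeParseError`
    naming the offending text otherwise.
    """
    if not _SIZE_RE.match(size_text):
        raise SizeParseError(f"not a size expression: {size_text!r}")
    dims = [
        float(value) * (10.0 if unit.lower() == "cm" else 1.0)
        for value, unit in _DIM_RE.findall(size_text)
    ]
    if not all(d > 0 for d in dims):
        raise SizeParseError(f"non-positive dimension in {size_text!r}")
    return SizeMeasurement(dimensions_mm=dims, raw_text=size_text)


def render_size(size: SizeMeasurement, unit: str = "mm", sep: str = "×") -> str:
    """Render a measurement back to text (inverse of :func:`parse_size`)."""
    parts = []
    for d in size.dimensions_mm:
        if unit == "cm":
            parts.append(f"{d / 10:g} cm")
        else:
            parts.append(f"{d:g} mm")
    return f" {sep} ".join(parts)


def _group_sentences(tokens: list[AnnotatedToken]) -> dict[tuple[int, int], list[AnnotatedToken]]:
    groups: dict[tuple[int, int], list[AnnotatedToken]] = {}
    for tok in tokens:
        groups.setdefault((tok.section_index, tok.sentence_index), []).append(tok)
    return groups


def _scan_sizes(sentence_tokens: list[AnnotatedToken]) -> list[tuple[int, int, SizeMeasurement]]:
    """Find maximal NUM UNIT (SEP NUM UNIT)* runs; returns (first, last, size)."""
    out: list[tuple[int, int, SizeMeasurement]] = []
    n = len(sentence_tokens)
    i = 0

    def is_num(k: int) -> bool:
        return k < n and bool(_NUM_RE.match(sentence_tokens[k].surface))

    def is_unit(k: int) -> bool:
        return k < n and sentence_tokens[k].normalized in ("cm", "mm")

    def is_sep(k: int) -> bool:
        return k < n and sentence_tokens[k].normalized in ("×", "x")

    while i < n:
        if is_num(i) and is_unit(i + 1):
            j = i + 2
            while is_sep(j) and is_num(j + 1) and is_unit(j + 2):
                j += 3
            raw = " ".join(t.surface for t in sentence_tokens[i:j])
            out.append((i, j, parse_size(raw)))
            i = j
        else:
            i += 1
    return out


def match_concepts(report: AnnotatedReport, lexicon: Lexicon) -> list[ConceptMention]:
    """Produce one mention per lexicon hit plus one per size expression.

    Hits of kind *entity* and *value* always yield mentions; *feature* hits
    yield mentions only for associated findings (their presence is the
    finding).  All mentions start out asserted.
    """
    finding_names = {f.name for f in lexicon.features_for("associated_finding")}
    mentions: list[ConceptMention] = []
    for (sec, sent), toks in sorted(_group_sentences(report.tokens).items()):
        for tok in toks:
            if tok.concept_kind in ("entity", "value") or (
                tok.concept_kind == "feature" and tok.concept_id in finding_names
            ):
                mentions.append(
                    ConceptMention(
                        concept_id=tok.concept_id,
                        concept_kind="feature"
                        if tok.concept_kind == "feature"
                        else tok.concept_kind,
                        section_index=sec,
                        sentence_index=sent,
                        first_token=tok.token_index,
                        last_token=tok.token_index + 1,
                        match_type=tok.match_type or "exact",
                        surface=tok.surface,
                    )
                )
        for first, last, size in _scan_sizes(toks):
            mentions.append(
                ConceptMention(
                    concept_id="size_expression",
                    concept_kind="value",
                    section_index=sec,
                    sentence_index=sent,
                    first_token=first,
                    last_token=last,
                    size=size,
                    surface=size.raw_text,
                )
            )
    mentions.sort(key=lambda m: (m.section_index, m.sentence_index, m.first_token))
    return mentions


def detect_negation(
    mentions: list[ConceptMention], report: AnnotatedReport, lexicon: Lexicon
) -> list[ConceptMention]:
    """Flip mentions to negated under the token-distance negation rule.

    A cue negates a mention when it lies in the same sentence, on the
    configured side (default: cue before concept), with at most
    ``negation_window`` tokens strictly between cue and the mention span.
    """
    cue_positions: dict[tuple[int, int], list[int]] = {}
    for (sec, sent), toks in _group_sentences(report.tokens).items():
        positions = [t.token_index for t in toks if lexicon.is_negation_cue(t.normalized)]
        if positions:
            cue_positions[(sec, sent)] = positions

    window = lexicon.negation_window
    direction = lexicon.negation_direction
    updated: list[ConceptMention] = []
    for mention in mentions:
        cues = cue_positions.get((mention.section_index, mention.sentence_index), [])
        negated = False
        for c in cues:
            before = c < mention.first_token and (mention.first_token - c - 1) <= window
            after = c >= mention.last_token and (c - mention.last_token) <= window
            if direction == "cue_before_concept" and before:
                negated = True
            elif direction == "cue_after_concept" and after:
                negated = True
            elif direction == "both" and (before or after):
                negated = True
            if negated:
                break
        if negated:
            logger.debug(
                "negation: %r negated in report %s (section %d sentence %d)",
                mention.surface,
                report.report_id,
                mention.section_index,
                mention.sentence_index,
            )
            updated.append(mention.model_copy(update={"polarity": "negated"}))
        else:
            updated.append(mention)
    return updated


def _resolve_owner(
    mention: ConceptMention,
    entity_type: str,
    sentence_tokens: list[AnnotatedToken],
    lexicon: Lexicon,
) -> Optional[str]:
    """Pick the feature a value mention fills on this lesion.

    Size expressions map to the entity's numerical feature (size for a
    mass, scope for an NME).  Otherwise the owner comes from the lexicon's
    value->features table, restricted to the lesion's entity type;
    ambiguity (e.g. "irregular", shared by shape and margin; signal values
    shared by T1WI/T2WI/DWI) is resolved by the nearest feature-name token
    within two tokens, preferring one after the value ("high signal in
    T2WI") over one before ("margin is irregular"), with the entity's
    feature-definition order as last resort.
    """
    if mention.concept_id == "size_expression":
        return "size" if entity_type == "mass" else "scope"
    owners = lexicon.owners_for_entity(mention.concept_id, entity_type)
    if not owners:
        return None
    if len(owners) == 1:
        return owners[0]
    best_after: Optional[tuple[int, str]] = None
    best_before: Optional[tuple[int, str]] = None
    for tok in sentence_tokens:
        if tok.concept_kind != "feature" or tok.concept_id not in owners:
            continue
        if tok.token_index >= mention.last_token:
            gap = tok.token_index - mention.last_token
            if gap <= _ATTACH_WINDOW and (best_after is None or gap < best_after[0]):
                best_after = (gap, tok.concept_id)
        elif tok.token_index < mention.first_token:
            gap = mention.first_token - tok.token_index - 1
            if gap <= _ATTACH_WINDOW and (best_before is None or gap < best_before[0]):
                best_before = (gap, tok.concept_id)
    if best_after is not None:
        return best_after[1]
    if best_before is not None:
        return best_before[1]
    return owners[0]


def assemble_lesions(
    report: AnnotatedReport, mentions: list[ConceptMention], lexicon: Lexicon
) -> tuple[list[LesionRecord], list[AssociatedFinding], list[str]]:
    """Build one lesion per lesion-bearing section plus report-wide findings.

    Returns ``(lesions, findings, warnings)``.  Feature conflicts resolve
    first-mention-wins and are logged; negated features are stored but do
    not add to ``feature_count``.  Mentions in a preamble pseudo-section
    contribute only to associated findings.
    """
    sentence_groups = _group_sentences(report.tokens)
    by_section: dict[int, list[ConceptMention]] = {}
    for m in mentions:
        by_section.setdefault(m.section_index, []).append(m)

    warnings: list[str] = []
    lesions: list[LesionRecord] = []
    findings: list[AssociatedFinding] = []
    seen_findings: dict[str, str] = {}
    finding_names = {f.name for f in lexicon.features_for("associated_finding")}

    for section in report.sections:
        section_mentions = by_section.get(section.section_index, [])
        # findings are collected from every section, including the preamble
        for m in section_mentions:
            if m.concept_kind == "feature" and m.concept_id in finding_names:
                if m.concept_id in seen_findings:
                    if seen_findings[m.concept_id] != m.polarity:
                        warnings.append(
                            f"conflicting polarity for finding {m.concept_id}; first kept"
                        )
                    continue
                seen_findings[m.concept_id] = m.polarity
                findings.append(AssociatedFinding(finding=m.concept_id, polarity=m.polarity))
        if section.is_preamble:
            continue

        entity_mention = next((m for m in section_mentions if m.concept_kind == "entity"), None)
        if entity_mention is None:
            entity_type = "unknown"
            warnings.append(
                f"section {section.section_index} has a location but no entity term"
            )
        else:
            entity_type = entity_mention.concept_id
        lesion = LesionRecord(
            lesion_index=len(lesions),
            entity_type=entity_type,
            section_index=section.section_index,
            location=section.anchor_location,
        )
        owner_entity = entity_type if entity_type != "unknown" else "mass"
        for m in section_mentions:
            if m.concept_kind != "value":
                continue
            sentence_tokens = sentence_groups.get((m.section_index, m.sentence_index), [])
            owner = _resolve_owner(m, owner_entity, sentence_tokens, lexicon)
            if owner is None:
                warnings.append(
                    f"value {m.concept_id!r} not attributable to any "
                    f"{owner_entity} feature; skipped"
                )
                continue
            fv = FeatureValue(
                value=None if m.size is not None else m.concept_id,
                size=m.size,
                polarity=m.polarity,
            )
            if owner in lesion.feature_values:
                existing = lesion.feature_values[owner]
                if (existing.value, existing.size) != (fv.value, fv.size):
                    warnings.append(
                        f"conflicting values for {owner} on lesion "
                        f"{lesion.lesion_index}; first mention kept"
                    )
                continue
            lesion.feature_values[owner] = fv
        lesion.recount()
        lesions.append(lesion)

    for w in warnings:
        logger.debug("assemble(%s): %s", report.report_id, w)
    return lesions, findings, warnings
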