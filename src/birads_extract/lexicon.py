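"""BI-RADS MRI lexicon: loading, validation and concept lookup.

The lexicon is the single source of vocabulary for the whole pipeline.  It
defines the imaging features of each lesion entity type (mass, non-mass
enhancement) together with their categorical value sets, the report-level
associated findings, synonym and spelling-correction tables, negation cues
and the BI-RADS category alphabet.  Concept matching is case-insensitive,
longest-match-first over multiword terms, with at most one synonym hop.
"""

from __future__ import annotations

import logging
import re
from functools import cached_property
from importlib import resources
from pathlib import Path
from typing import Literal, NamedTuple, Optional

import yaml
from pydantic import BaseModel, Field

logger = logging.getLogger(__name__)

EntityType = Literal["mass", "nme", "associated_finding"]
ConceptKind = Literal["entity", "feature", "value", "birads_marker"]
NegationDirection = Literal["cue_before_concept", "cue_after_concept", "both"]

# Words keep internal hyphens ("wash-out", "BI-RADS"); decimal numbers stay
# whole; the listed punctuation marks and the dimension sign become their own
# tokens.
_TOKEN_RE = re.compile(r"\d+\.\d+|[^\s,.:;()×]+|[,.:;()×]")


def tokenize_text(text: str) -> list[str]:
    """Split text into word/number/punctuation tokens (decimals intact)."""
    return _TOKEN_RE.findall(text)


class LexiconError(ValueError):
    """Raised when a lexicon file fails schema or invariant validation."""


class ConceptHit(NamedTuple):
    """Result of a lexicon lookup for one surface form."""

    concept_id: str
    kind: ConceptKind
    match_type: Literal["exact", "synonym"]


class FeatureDefinition(BaseModel):
    """One imaging feature of an entity type.

    Numerical features (size, scope) have unit ``mm`` and an empty value
    set; categorical features enumerate their canonical value terms.
    Associated findings are presence features with an empty value set.
    """

    name: str
    entity_type: EntityType
    data_type: Literal["categorical", "numerical"]
    value_set: list[str] = Field(default_factory=list)
    units: Optional[str] = None


class Lexicon(BaseModel):
    """The full vocabulary driving extraction.

    Treat instances as immutable: derived lookup tables are cached on first
    use.  To modify a lexicon, edit its dict form (:func:`Lexicon.to_dict`)
    and rebuild via :func:`lexicon_from_dict`.
    """

    features: list[FeatureDefinition]
    entity_surfaces: dict[str, str]  # entity id -> canonical surface
    feature_terms: dict[str, str]  # surface naming a feature -> feature name
    synonyms: dict[str, str] = Field(default_factory=dict)
    spelling_corrections: dict[str, str] = Field(default_factory=dict)
    abbreviation_expansions: dict[str, str] = Field(default_factory=dict)
    negation_cues: list[str] = Field(default_factory=lambda: ["no"])
    negation_window: int = 3
    negation_direction: NegationDirection = "cue_before_concept"
    birads_marker: str = "BI-RADS"
    birads_values: list[int] = Field(default_factory=lambda: list(range(7)))

    # ------------------------------------------------------------------
    # Derived lookup tables
    # ------------------------------------------------------------------

    @cached_property
    def canonical_terms(self) -> dict[str, tuple[ConceptKind, str]]:
        """Case-folded canonical surface -> (concept kind, canonical id)."""
        table: dict[str, tuple[ConceptKind, str]] = {}
        for entity_id, surface in self.entity_surfaces.items():
            table[surface.casefold()] = ("entity", entity_id)
        for surface, feature_name in self.feature_terms.items():
            table.setdefault(surface.casefold(), ("feature", feature_name))
        for feat in self.features:
            for term in feat.value_set:
                table.setdefault(term.casefold(), ("value", term.casefold()))
        table[self.birads_marker.casefold()] = ("birads_marker", "birads")
        return table

    @cached_property
    def value_owners(self) -> dict[str, list[str]]:
        """Value term -> feature names whose value sets contain it.

        Order follows feature-definition order; ambiguity resolution falls
        back on the first owner valid for the lesion's entity type.
        """
        owners: dict[str, list[str]] = {}
        for feat in self.features:
            for term in feat.value_set:
                names = owners.setdefault(term.casefold(), [])
                if feat.name not in names:
                    names.append(feat.name)
        return owners

    @cached_property
    def _phrase_table(self) -> dict[tuple[str, ...], ConceptHit]:
        """Token-tuple -> hit, for greedy longest-match merging."""
        table: dict[tuple[str, ...], ConceptHit] = {}
        for surface, (kind, cid) in self.canonical_terms.items():
            key = tuple(t.casefold() for t in tokenize_text(surface))
            table[key] = ConceptHit(cid, kind, "exact")
        for syn, target in self.synonyms.items():
            resolved = self.canonical_terms.get(target.casefold())
            if resolved is None:
                continue  # reported by validate(); skip here
            key = tuple(t.casefold() for t in tokenize_text(syn))
            table.setdefault(key, ConceptHit(resolved[1], resolved[0], "synonym"))
        return table

    @cached_property
    def _max_phrase_len(self) -> int:
        return max((len(k) for k in self._phrase_table), default=1)

    @cached_property
    def _cue_set(self) -> set[str]:
        return {c.casefold() for c in self.negation_cues}

    # ------------------------------------------------------------------
    # Queries
    # ------------------------------------------------------------------

    def features_for(self, entity_type: str) -> list[FeatureDefinition]:
        return [f for f in self.features if f.entity_type == entity_type]

    def feature_definition(self, entity_type: str, name: str) -> FeatureDefinition:
        for f in self.features:
            if f.entity_type == entity_type and f.name == name:
                return f
        raise KeyError(f"no feature {name!r} for entity {entity_type!r}")

    def owners_for_entity(self, value_term: str, entity_type: str) -> list[str]:
        entity_features = {f.name for f in self.features_for(entity_type)}
        return [n for n in self.value_owners.get(value_term.casefold(), []) if n in entity_features]

    def is_negation_cue(self, token: str) -> bool:
        return token.casefold() in self._cue_set

    def lookup(self, surface: str) -> Optional[ConceptHit]:
        """Match one surface (word or multiword phrase) against the lexicon.

        Exact canonical hits win; otherwise a single synonym hop is tried.
        Returns ``None`` for out-of-lexicon surfaces.
        """
        if not surface or not surface.strip():
            raise ValueError("lookup surface must be non-empty text")
        key = tuple(t.casefold() for t in tokenize_text(surface))
        return self._phrase_table.get(key)

    def merge_tokens(
        self, raw_tokens: list[str]
    ) -> list[tuple[str, Optional[ConceptHit]]]:
        """Greedy longest-match merge of lexicon terms over a token list.

        Returns ``(surface, hit)`` pairs where multiword lexicon terms have
        been fused into single tokens (surface joined with single spaces).
        """
        merged: list[tuple[str, Optional[ConceptHit]]] = []
        folded = [t.casefold() for t in raw_tokens]
        i = 0
        n = len(raw_tokens)
        while i < n:
            hit = None
            length = 1
            for l in range(min(self._max_phrase_len, n - i), 0, -1):
                candidate = self._phrase_table.get(tuple(folded[i : i + l]))
                if candidate is not None:
                    hit, length = candidate, l
                    break
            merged.append((" ".join(raw_tokens[i : i + length]), hit))
            i += length
        return merged

    # ------------------------------------------------------------------
    # Validation
    # ------------------------------------------------------------------

    def validate_invariants(self) -> list[str]:
        """Return human-readable descriptions of every invariant violation."""
        violations: list[str] = []

        for feat in self.features:
            label = f"{feat.entity_type}.{feat.name}"
            if feat.data_type == "numerical":
                if feat.units != "mm":
                    violations.append(f"numerical feature {label} must use units 'mm'")
                if feat.value_set:
                    violations.append(f"numerical feature {label} must have an empty value set")
            else:
                folded = [v.casefold() for v in feat.value_set]
                if len(set(folded)) != len(folded):
                    violations.append(f"categorical feature {label} has duplicate values")

        for entity_id, expected in (("mass", 9), ("nme", 8)):
            got = len(self.features_for(entity_id))
            if got != expected:
                violations.append(
                    f"entity {entity_id!r} defines {got} features, expected {expected}"
                )

        # canonical surfaces unique after case folding
        seen: dict[str, str] = {}
        surfaces = list(self.entity_surfaces.values()) + list(self.feature_terms) + [
            self.birads_marker
        ]
        for surface in surfaces:
            folded = surface.casefold()
            if folded in seen and seen[folded] != surface:
                violations.append(f"duplicate canonical surface after case folding: {surface!r}")
            elif folded in seen:
                violations.append(f"duplicate canonical surface: {surface!r}")
            seen[folded] = surface

        named_surfaces = set(seen)
        for feat in self.features:
            for term in feat.value_set:
                if term.casefold() in named_surfaces:
                    violations.append(
                        f"value term {term!r} of {feat.entity_type}.{feat.name} "
                        "collides with an entity/feature surface"
                    )

        canon = self.canonical_terms
        for syn, target in self.synonyms.items():
            if target.casefold() not in canon:
                violations.append(f"synonym {syn!r} points to unknown canonical term {target!r}")
            if syn.casefold() in canon:
                violations.append(f"synonym {syn!r} shadows a canonical surface")
            if target in self.synonyms:
                violations.append(f"synonym chain: {syn!r} -> {target!r} -> {self.synonyms[target]!r}")

        if self.negation_window < 1:
            violations.append(f"negation_window must be >= 1, got {self.negation_window}")
        if not self.negation_cues:
            violations.append("negation_cues must be non-empty")
        if sorted(self.birads_values) != list(range(7)):
            violations.append(f"birads_values must be 0..6, got {sorted(self.birads_values)}")
        return violations

    def to_dict(self) -> dict:
        """Round-trippable plain-dict form (the lexicon file schema)."""
        by_entity: dict[str, list[dict]] = {}
        for f in self.features:
            entry: dict = {"name": f.name, "data_type": f.data_type}
            if f.value_set:
                entry["value_set"] = list(f.value_set)
            if f.units:
                entry["units"] = f.units
            by_entity.setdefault(f.entity_type, []).append(entry)
        return {
            "features": by_entity,
            "entities": dict(self.entity_surfaces),
            "feature_terms": dict(self.feature_terms),
            "synonyms": dict(self.synonyms),
            "spelling_corrections": dict(self.spelling_corrections),
            "abbreviations": dict(self.abbreviation_expansions),
            "negation": {
                "cues": list(self.negation_cues),
                "window": self.negation_window,
                "direction": self.negation_direction,
            },
            "birads": {"marker": self.birads_marker, "values": list(self.birads_values)},
        }


def lexicon_from_dict(data: dict) -> Lexicon:
    """Build and validate a :class:`Lexicon` from the file-schema dict."""
    try:
        features = [
            FeatureDefinition(entity_type=entity, **entry)
            for entity, entries in data.get("features", {}).items()
            for entry in entries
        ]
        negation = data.get("negation", {})
        birads = data.get("birads", {})
        lex = Lexicon(
            features=features,
            entity_surfaces=data.get("entities", {}),
            feature_terms=data.get("feature_terms", {}),
            synonyms=data.get("synonyms", {}) or {},
            spelling_corrections=data.get("spelling_corrections", {}) or {},
            abbreviation_expansions=data.get("abbreviations", {}) or {},
            negation_cues=list(negation.get("cues", ["no"])),
            negation_window=int(negation.get("window", 3)),
            negation_direction=negation.get("direction", "cue_before_concept"),
            birads_marker=birads.get("marker", "BI-RADS"),
            birads_values=list(birads.get("values", range(7))),
        )
    except (TypeError, ValueError) as exc:
        raise LexiconError(f"lexicon schema violation: {exc}") from exc
    violations = lex.validate_invariants()
    if violations:
        raise LexiconError("invalid lexicon:\n" + "\n".join(f"- {v}" for v in violations))
    return lex


def load_lexicon(path: str | Path) -> Lexicon:
    """Load and validate a lexicon file (YAML or JSON).

    Raises ``FileNotFoundError`` for a missing file and :class:`LexiconError`
    naming the offending entries for schema or invariant violations.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise LexiconError(f"lexicon file {path} does not contain a mapping")
    lex = lexicon_from_dict(data)
    logger.debug("loaded lexicon from %s (%d features)", path, len(lex.features))
    return lex


def default_lexicon_dict() -> dict:
    """The bundled default lexicon in editable dict form."""
    text = resources.files("birads_extract").joinpath("data/default_lexicon.yaml").read_text(
        encoding="utf-8"
    )
    return yaml.safe_load(text)


def default_lexicon() -> Lexicon:
    """Load the bundled default BI-RADS MRI lexicon."""
    return lexicon_from_dict(default_lexicon_dict())


def lookup_concept(surface: str, lexicon: Lexicon) -> Optional[ConceptHit]:
    """Functional wrapper around :meth:`Lexicon.lookup`."""
    return lexicon.lookup(surface)


def validate_lexicon(lexicon: Lexicon) -> list[str]:
    """Functional wrapper around :meth:`Lexicon.validate_invariants`."""
    return lexicon.validate_invariants()
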