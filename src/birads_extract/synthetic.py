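"""Synthetic breast MRI report generator with gold annotations.

The generator emulates the structure of the study population the pipeline
targets: per-report lesion counts in proportions 7:93:338:40 for 0/1/2/3
lesions, index-lesion feature counts on 5..9 with mean ~8.0 and SD ~1.1,
non-index counts on 3..8 (mean ~4.5 for two-lesion and ~5.2 for
three-lesion reports), and index BI-RADS categories 2..6 in proportions
28:60:87:119:177.  Feature-count laws are discretized truncated normals;
the location/SD parameters below were chosen so the truncated laws land on
those targets.

Rendering uses English sentence templates mirroring the section/sentence
structure the pipeline parses (one section per lesion opened by a
lesion-introducing sentence, an impression with one category statement per
lesion), with value surfaces drawn at random from the lexicon's canonical
terms and synonyms.  A zero-noise rendering is exactly recoverable by the
pipeline; controllable noise (spelling corruption, off-lexicon
paraphrases, extra negated findings) degrades it without touching gold.
"""

from __future__ import annotations

import logging
import math
import random
import re
from typing import Literal, Optional

from pydantic import BaseModel, Field, model_validator

from .extract import SizeMeasurement, render_size
from .lexicon import Lexicon, default_lexicon
from .preprocess import RawReport

logger = logging.getLogger(__name__)

_FINDING_SURFACES = {
    "lymphadenopathy": "lymphadenopathy",
    "nipple_invasion": "nipple invasion",
    "skin_invasion": "skin invasion",
    "chest_wall_invasion": "chest wall invasion",
    "pectoralis_muscle_invasion": "pectoralis muscle invasion",
}

# Off-lexicon paraphrases (the kind of free-form prose that defeats a
# lexicon-driven matcher); keyed by the canonical value they replace.
_PARAPHRASES = {
    "rim enhancement": (
        "a low-enhancement zone of necrosis in the center and rim homogeneous "
        "enhancement in the surrounding area"
    ),
    "heterogeneous": "patchy uneven signal uptake throughout",
    "homogeneous": "uniform signal uptake throughout",
    "wash-out": "rapid early uptake followed by loss of signal",
    "plateau": "early uptake that levels off over time",
}


def truncated_normal_law(mean: float, sd: float, lo: int, hi: int) -> dict[int, float]:
    """Discrete law on ``lo..hi`` with weights from a normal density."""
    weights = {k: math.exp(-((k - mean) ** 2) / (2 * sd * sd)) for k in range(lo, hi + 1)}
    total = sum(weights.values())
    return {k: w / total for k, w in weights.items()}


class NoiseConfig(BaseModel):
    """Controllable corruption rates; all probabilities in [0, 1]."""

    spelling_error_rate: float = 0.0
    paraphrase_rate: float = 0.0
    negation_rate: float = 0.0

    @model_validator(mode="after")
    def _check_rates(self) -> "NoiseConfig":
        for name in ("spelling_error_rate", "paraphrase_rate", "negation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        return self


class CorpusConfig(BaseModel):
    """Study-condition parameters of the generated corpus.

    Defaults encode the reference population: lesion-count weights
    7:93:338:40, index feature counts on 5..9 (truncated-normal location
    9.2, scale 1.8, giving mean ~8.0 and SD ~1.05), non-index counts on
    3..8 (location 4.2/scale 1.4 for two-lesion reports, 5.0/1.9 for
    three-lesion reports), and index-category weights 28:60:87:119:177
    over BI-RADS 2..6.
    """

    n_reports: int = 478
    seed: int = 0
    lesion_count_weights: dict[int, float] = Field(
        default_factory=lambda: {0: 7, 1: 93, 2: 338, 3: 40}
    )
    index_feature_count_law: dict[int, float] = Field(
        default_factory=lambda: truncated_normal_law(9.2, 1.8, 5, 9)
    )
    nonindex_feature_count_law_2lesion: dict[int, float] = Field(
        default_factory=lambda: truncated_normal_law(4.2, 1.4, 3, 8)
    )
    nonindex_feature_count_law_3lesion: dict[int, float] = Field(
        default_factory=lambda: truncated_normal_law(5.0, 1.9, 3, 8)
    )
    birads_weights: dict[int, float] = Field(
        default_factory=lambda: {2: 28, 3: 60, 4: 87, 5: 119, 6: 177}
    )
    mass_probability: float = 0.7
    finding_asserted_rate: float = 0.05
    finding_negated_rate: float = 0.25
    allow_feature_count_ties: bool = False
    noise: NoiseConfig = Field(default_factory=NoiseConfig)

    @model_validator(mode="after")
    def _check(self) -> "CorpusConfig":
        if self.n_reports < 0:
            raise ValueError("n_reports must be >= 0")
        for name in (
            "lesion_count_weights",
            "index_feature_count_law",
            "nonindex_feature_count_law_2lesion",
            "nonindex_feature_count_law_3lesion",
            "birads_weights",
        ):
            weights = getattr(self, name)
            if any(w < 0 for w in weights.values()) or not any(w > 0 for w in weights.values()):
                raise ValueError(f"{name} must be non-negative with at least one positive weight")
        return self


class GoldValue(BaseModel):
    """Gold value of one feature slot: categorical term or mm dimensions."""

    value: Optional[str] = None
    dims_mm: Optional[list[float]] = None


class GoldLesion(BaseModel):
    entity_type: Literal["mass", "nme"]
    location: str
    features: dict[str, GoldValue] = Field(default_factory=dict)
    feature_count: int = 0


class GoldFinding(BaseModel):
    finding: str
    polarity: Literal["asserted", "negated"]


class GoldAnnotation(BaseModel):
    """Everything the pipeline is expected to recover for one report."""

    report_id: str
    lesions: list[GoldLesion] = Field(default_factory=list)
    index_lesion_index: Optional[int] = None
    associated_findings: list[GoldFinding] = Field(default_factory=list)
    birads_per_lesion: list[int] = Field(default_factory=list)
    final_birads: int = 1


def _draw(law: dict[int, float], rng: random.Random) -> int:
    keys = sorted(law)
    return rng.choices(keys, weights=[law[k] for k in keys], k=1)[0]


def _sample_lesion(
    entity_type: str,
    location: str,
    n_features: int,
    lexicon: Lexicon,
    rng: random.Random,
) -> GoldLesion:
    defs = {f.name: f for f in lexicon.features_for(entity_type)}
    optional = [name for name in defs if name != "location"]
    chosen = ["location"] + sorted(rng.sample(optional, n_features - 1))
    features: dict[str, GoldValue] = {}
    for name in chosen:
        feat = defs[name]
        if name == "location":
            features[name] = GoldValue(value=location)
        elif feat.data_type == "numerical":
            ndims = rng.choice([1, 2, 3])
            dims = [float(rng.randint(5, 40)) for _ in range(ndims)]
            features[name] = GoldValue(dims_mm=dims)
        else:
            features[name] = GoldValue(value=rng.choice(feat.value_set).casefold())
    return GoldLesion(
        entity_type=entity_type,
        location=location,
        features=features,
        feature_count=len(features),
    )


def sample_gold(
    report_id: str,
    config: CorpusConfig,
    lexicon: Lexicon,
    rng: random.Random,
) -> GoldAnnotation:
    """Draw one gold annotation from the configured laws."""
    n_lesions = _draw(config.lesion_count_weights, rng)
    if n_lesions == 0:
        findings = _sample_findings(config, rng)
        return GoldAnnotation(
            report_id=report_id, associated_findings=findings, final_birads=1
        )

    location_pool = lexicon.feature_definition("mass", "location").value_set
    locations = rng.sample(location_pool, n_lesions)
    index_pos = rng.randrange(n_lesions)
    index_count = _draw(config.index_feature_count_law, rng)

    lesions: list[GoldLesion] = []
    for i in range(n_lesions):
        if i == index_pos:
            count = index_count
        else:
            law = (
                config.nonindex_feature_count_law_2lesion
                if n_lesions == 2
                else config.nonindex_feature_count_law_3lesion
            )
            count = _draw(law, rng)
            if not config.allow_feature_count_ties:
                # enforce a unique maximum so the gold index is well defined
                truncated = {k: w for k, w in law.items() if k < index_count}
                if not truncated:
                    truncated = {min(law): 1.0}
                count = _draw(truncated, rng)
        if count == 9:
            entity = "mass"
        else:
            entity = "mass" if rng.random() < config.mass_probability else "nme"
        count = min(count, 9 if entity == "mass" else 8)
        lesions.append(_sample_lesion(entity, locations[i], count, lexicon, rng))

    index_cat = _draw(config.birads_weights, rng)
    categories = [
        index_cat if i == index_pos else rng.randint(2, index_cat)
        for i in range(n_lesions)
    ]
    return GoldAnnotation(
        report_id=report_id,
        lesions=lesions,
        index_lesion_index=index_pos,
        associated_findings=_sample_findings(config, rng),
        birads_per_lesion=categories,
        final_birads=max(categories),
    )


def _sample_findings(config: CorpusConfig, rng: random.Random) -> list[GoldFinding]:
    findings: list[GoldFinding] = []
    for name in _FINDING_SURFACES:
        u = rng.random()
        if u < config.finding_asserted_rate:
            findings.append(GoldFinding(finding=name, polarity="asserted"))
        elif u < config.finding_asserted_rate + config.finding_negated_rate:
            findings.append(GoldFinding(finding=name, polarity="negated"))
    return findings


def _surface_choices(lexicon: Lexicon, canonical: str) -> list[str]:
    """Canonical surface plus every synonym resolving to it."""
    surfaces = [canonical]
    for syn, target in lexicon.synonyms.items():
        if target.casefold() == canonical.casefold():
            surfaces.append(syn)
    return surfaces


def _pick_surface(lexicon: Lexicon, canonical: str, rng: random.Random) -> str:
    return rng.choice(_surface_choices(lexicon, canonical))


def _size_text(dims: list[float], rng: random.Random) -> str:
    unit = rng.choice(["mm", "cm"])
    sep = rng.choice(["×", "x"])
    return render_size(SizeMeasurement(dimensions_mm=dims), unit=unit, sep=sep)


_SEQUENCE_SURFACES = {"t1wi": "T1WI", "t2wi": "T2WI", "dwi": "DWI"}


def _render_lesion(gold: GoldLesion, lexicon: Lexicon, rng: random.Random) -> list[str]:
    feats = gold.features
    sentences: list[str] = []

    entity_canonical = lexicon.entity_surfaces[gold.entity_type]
    entity_surface = _pick_surface(lexicon, entity_canonical, rng)
    intro = ["There is a"]
    if gold.entity_type == "mass" and "size" in feats:
        intro.append(_size_text(feats["size"].dims_mm, rng))
    if "shape" in feats:
        intro.append(feats["shape"].value)
    intro.append(entity_surface)
    if "margin" in feats:
        margin_surface = _pick_surface(lexicon, feats["margin"].value, rng)
        margin_word = rng.choice(["margin", "boundary"])
        intro.append(f"with {margin_surface} {margin_word}")
    intro.append(f"in {gold.location}")
    sentences.append(" ".join(intro) + ".")

    signal_parts = [
        f"{_pick_surface(lexicon, feats[name].value, rng)} in {_SEQUENCE_SURFACES[name]}"
        for name in ("t1wi", "t2wi", "dwi")
        if name in feats
    ]
    if signal_parts:
        if len(signal_parts) > 1:
            text = ", ".join(signal_parts[:-1]) + " and " + signal_parts[-1]
        else:
            text = signal_parts[0]
        sentences.append(text[0].upper() + text[1:] + ".")

    if gold.entity_type == "nme" and "distribution_pattern" in feats:
        sentences.append(
            f"The distribution pattern is {feats['distribution_pattern'].value}."
        )
    if gold.entity_type == "nme" and "scope" in feats:
        sentences.append(f"The scope is {_size_text(feats['scope'].dims_mm, rng)}.")

    tail_parts = []
    if "internal_enhancement" in feats:
        tail_parts.append(
            f"internal enhancement is {_pick_surface(lexicon, feats['internal_enhancement'].value, rng)}"
        )
    if "kinetic_curve" in feats:
        tail_parts.append(
            f"kinetic curve is {_pick_surface(lexicon, feats['kinetic_curve'].value, rng)}"
        )
    if tail_parts:
        text = " and ".join(tail_parts)
        sentences.append(text[0].upper() + text[1:] + ".")
    return sentences


def render_report(gold: GoldAnnotation, lexicon: Lexicon, rng: random.Random) -> RawReport:
    """Render a gold annotation into report text the pipeline can recover.

    The description holds one section per lesion followed by one sentence
    per associated finding; the impression states one BI-RADS category per
    lesion.  Raises ``ValueError`` if gold references a value the lexicon
    does not define.
    """
    _validate_gold_against_lexicon(gold, lexicon)
    sentences: list[str] = []
    for lesion in gold.lesions:
        sentences.extend(_render_lesion(lesion, lexicon, rng))
    if not gold.lesions:
        sentences.append("Both breasts show no abnormal enhancement")
        sentences[-1] += "."
    for finding in gold.associated_findings:
        surface = _FINDING_SURFACES[finding.finding]
        if finding.polarity == "negated":
            sentences.append(f"No {surface}.")
        else:
            sentences.append(f"There is {surface}.")
    description = " ".join(sentences)

    impression_sentences = []
    if gold.lesions:
        for lesion, cat in zip(gold.lesions, gold.birads_per_lesion):
            entity_surface = lexicon.entity_surfaces[lesion.entity_type]
            impression_sentences.append(
                f"BI-RADS category of the {entity_surface} in {lesion.location}: {cat}."
            )
    else:
        impression_sentences.append("Both breasts are unremarkable.")
        impression_sentences.append(f"BI-RADS category: {gold.final_birads}.")
    impression = " ".join(impression_sentences)
    return RawReport(report_id=gold.report_id, description=description, impression=impression)


def _validate_gold_against_lexicon(gold: GoldAnnotation, lexicon: Lexicon) -> None:
    for lesion in gold.lesions:
        defs = {f.name: f for f in lexicon.features_for(lesion.entity_type)}
        for name, value in lesion.features.items():
            if name not in defs:
                raise ValueError(
                    f"gold feature {name!r} undefined for entity {lesion.entity_type!r}"
                )
            feat = defs[name]
            if feat.data_type == "categorical" and name != "location":
                allowed = {v.casefold() for v in feat.value_set}
                if value.value is None or value.value.casefold() not in allowed:
                    raise ValueError(
                        f"gold value {value.value!r} not in lexicon for feature {name!r}"
                    )


def _corrupt_word(word: str, rng: random.Random) -> str:
    """Random spelling corruption; the BI-RADS marker gets its catalogued form."""
    if word.casefold() == "bi-rads":
        return "Bi-RAS"
    if len(word) < 4:
        return word
    if rng.random() < 0.5:
        i = rng.randrange(1, len(word) - 1)
        return word[:i] + word[i + 1 :]
    i = rng.randrange(0, len(word) - 1)
    return word[:i] + word[i + 1] + word[i] + word[i + 2 :]


def inject_noise(report: RawReport, noise: NoiseConfig, rng: random.Random) -> RawReport:
    """Apply spelling/paraphrase/extra-negation corruption to report text.

    Gold annotations are never modified; with all rates zero the report is
    returned unchanged.
    """
    if (
        noise.spelling_error_rate == 0
        and noise.paraphrase_rate == 0
        and noise.negation_rate == 0
    ):
        return report
    description = report.description
    impression = report.impression

    if noise.paraphrase_rate > 0:
        for canonical, paraphrase in _PARAPHRASES.items():
            pattern = re.compile(rf"\b{re.escape(canonical)}\b", re.IGNORECASE)
            description = pattern.sub(
                lambda m: paraphrase if rng.random() < noise.paraphrase_rate else m.group(0),
                description,
            )

    if noise.negation_rate > 0 and rng.random() < noise.negation_rate:
        present = {s.casefold() for s in _FINDING_SURFACES.values() if s in description}
        candidates = [s for s in _FINDING_SURFACES.values() if s.casefold() not in present]
        if candidates:
            description += f" No {rng.choice(candidates)}."

    if noise.spelling_error_rate > 0:

        def corrupt_text(text: str) -> str:
            words = text.split(" ")
            out = []
            for w in words:
                core = w.rstrip(".,:;")
                if core.isalpha() and len(core) >= 4 and rng.random() < noise.spelling_error_rate:
                    w = _corrupt_word(core, rng) + w[len(core) :]
                elif core == "BI-RADS" and rng.random() < noise.spelling_error_rate:
                    w = _corrupt_word(core, rng) + w[len(core) :]
                out.append(w)
            return " ".join(out)

        description = corrupt_text(description)
        impression = corrupt_text(impression)

    return RawReport(
        report_id=report.report_id, description=description, impression=impression
    )


def generate_corpus(
    config: CorpusConfig, lexicon: Optional[Lexicon] = None
) -> tuple[list[RawReport], list[GoldAnnotation]]:
    """Generate ``n_reports`` report/gold pairs; same seed, same corpus."""
    lexicon = lexicon or default_lexicon()
    rng = random.Random(config.seed)
    # separate stream so noise never perturbs gold/rendering draws: the same
    # seed yields the same gold corpus at every noise setting
    noise_rng = random.Random((config.seed * 2654435761 + 1) % (2**31))
    reports: list[RawReport] = []
    golds: list[GoldAnnotation] = []
    for i in range(config.n_reports):
        gold = sample_gold(f"R{i:05d}", config, lexicon, rng)
        report = render_report(gold, lexicon, rng)
        report = inject_noise(report, config.noise, noise_rng)
        reports.append(report)
        golds.append(gold)
    logger.info("generated %d synthetic reports (seed=%d)", config.n_reports, config.seed)
    return reports, golds
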