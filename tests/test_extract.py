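"""Concept matching, negation windows, size parsing and lesion assembly."""


import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from birads_extract import (
    RawReport,
    SizeMeasurement,
    SizeParseError,
    assemble_lesions,
    default_lexicon_dict,
    detect_negation,
    lexicon_from_dict,
    match_concepts,
    parse_size,
    render_size,
    tokenize_and_annotate,
)

from conftest import EXAMPLE3_TEXT


def _annotated(text, lexicon, impression=""):
    raw = RawReport(report_id="t", description=text, impression=impression)
    return tokenize_and_annotate(raw, lexicon)


# ---------------------------------------------------------------------------
# concept matching
# ---------------------------------------------------------------------------


def test_first_example_sentence_yields_five_mentions(lexicon):
    text = (
        "There is a 1.1 cm × 1.0 cm × 1.5 cm oval mass with irregular margin "
        "in the upper inner quadrant of the left breast."
    )
    report = _annotated(text, lexicon)
    mentions = match_concepts(report, lexicon)
    assert len(mentions) == 5
    by_id = {m.concept_id: m for m in mentions}
    assert by_id["mass"].concept_kind == "entity"
    assert by_id["size_expression"].size.dimensions_mm == [11.0, 10.0, 15.0]
    assert by_id["oval"].concept_kind == "value"
    assert by_id["irregular"].concept_kind == "value"
    assert "the upper inner quadrant of the left breast" in by_id
    assert all(m.polarity == "asserted" for m in mentions)


def test_sentence_without_lexicon_terms_yields_no_mentions(lexicon):
    report = _annotated("The weather was fine yesterday", lexicon)
    assert match_concepts(report, lexicon) == []


def test_synonym_surfaces_resolve_to_canonical_values(lexicon):
    report = _annotated(EXAMPLE3_TEXT, lexicon)
    mentions = match_concepts(report, lexicon)
    smooth = next(m for m in mentions if m.concept_id == "smooth")
    assert smooth.match_type == "synonym" and smooth.surface == "clear"
    entity = next(m for m in mentions if m.concept_kind == "entity")
    assert entity.concept_id == "mass" and entity.match_type == "synonym"
    lesions, _, _ = assemble_lesions(report, mentions, lexicon)
    assert lesions[0].feature_values["margin"].value == "smooth"


# ---------------------------------------------------------------------------
# negation
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "text, negated",
    [
        ("There is a mass in the upper outer quadrant of the left breast. No skin invasion.", True),
        ("No obvious enlarged lymphadenopathy.", True),
        ("No one two three four skin invasion.", False),  # 4 intervening tokens
    ],
)
def test_negation_cases(lexicon, text, negated):
    report = _annotated(text, lexicon)
    mentions = detect_negation(match_concepts(report, lexicon), report, lexicon)
    finding = next(
        m for m in mentions if m.concept_id in ("skin_invasion", "lymphadenopathy")
    )
    assert (finding.polarity == "negated") is negated


def _sweep(direction, window=3):
    """Exhaustive cue-distance sweep oracle: filler words at every distance."""
    data = default_lexicon_dict()
    data["negation"]["direction"] = direction
    data["negation"]["window"] = window
    lexicon = lexicon_from_dict(data)
    results = {}
    for distance in range(7):
        fillers = " ".join(f"filler{i}" for i in range(distance))
        if direction == "cue_after_concept":
            text = f"skin invasion {fillers} no".replace("  ", " ")
        else:
            text = f"no {fillers} skin invasion".replace("  ", " ")
        report = _annotated(text, lexicon)
        mentions = detect_negation(match_concepts(report, lexicon), report, lexicon)
        mention = next(m for m in mentions if m.concept_id == "skin_invasion")
        results[distance] = mention.polarity == "negated"
    return results


@pytest.mark.parametrize("direction", ["cue_before_concept", "cue_after_concept"])
def test_negation_window_flips_exactly_within_three_tokens(direction):
    assert _sweep(direction) == {d: d <= 3 for d in range(7)}


def test_negation_direction_restricts_side(lexicon):
    # default direction is cue_before_concept: a trailing cue must not negate
    report = _annotated("Skin invasion was not", lexicon)
    mentions = detect_negation(match_concepts(report, lexicon), report, lexicon)
    assert all(m.polarity == "asserted" for m in mentions)

    data = default_lexicon_dict()
    data["negation"]["direction"] = "both"
    both = lexicon_from_dict(data)
    report = _annotated("Skin invasion was not", both)
    mentions = detect_negation(match_concepts(report, both), report, both)
    assert any(m.polarity == "negated" for m in mentions)


# ---------------------------------------------------------------------------
# size parsing
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "text, dims",
    [
        ("1.1 cm × 1.0 cm × 1.5 cm", [11.0, 10.0, 15.0]),
        ("16 mm", [16.0]),
        ("1.6 cm × 1.2 cm × 1.2 cm", [16.0, 12.0, 12.0]),
        ("2 cm x 14 mm", [20.0, 14.0]),
    ],
)
def test_parse_size_values(text, dims):
    assert parse_size(text).dimensions_mm == pytest.approx(dims)


@pytest.mark.parametrize("bad", ["", "large", "1.1 × 1.0", "1.1 cm × ", "3 km"])
def test_parse_size_rejects_malformed_text(bad):
    with pytest.raises(SizeParseError, match="size"):
        parse_size(bad)


@settings(deadline=None, max_examples=100, derandomize=True)
@given(
    dims=st.lists(st.integers(1, 400), min_size=1, max_size=3),
    unit=st.sampled_from(["mm", "cm"]),
    sep=st.sampled_from(["×", "x"]),
)
def test_parse_render_round_trip(dims, unit, sep):
    size = SizeMeasurement(dimensions_mm=[float(d) for d in dims])
    parsed = parse_size(render_size(size, unit=unit, sep=sep))
    assert parsed.dimensions_mm == pytest.approx(size.dimensions_mm, abs=1e-9)


# ---------------------------------------------------------------------------
# lesion assembly
# ---------------------------------------------------------------------------


def test_two_lesion_worked_example_assembles_counts_nine_and_three(
    lexicon, example1_report
):
    report = tokenize_and_annotate(example1_report, lexicon)
    mentions = detect_negation(match_concepts(report, lexicon), report, lexicon)
    lesions, findings, warnings = assemble_lesions(report, mentions, lexicon)
    assert [l.entity_type for l in lesions] == ["mass", "nme"]
    assert [l.feature_count for l in lesions] == [9, 3]
    assert set(lesions[1].feature_values) == {"location", "dwi", "internal_enhancement"}
    assert findings == [] and warnings == []


def test_report_without_sections_yields_findings_only(lexicon):
    report = _annotated("No skin invasion was seen", lexicon)
    mentions = detect_negation(match_concepts(report, lexicon), report, lexicon)
    lesions, findings, _ = assemble_lesions(report, mentions, lexicon)
    assert lesions == []
    assert len(findings) == 1
    assert (findings[0].finding, findings[0].polarity) == ("skin_invasion", "negated")


def test_ambiguous_irregular_binds_to_shape_without_margin_context(lexicon):
    text = "There is an irregular mass with smooth boundary in the upper outer quadrant of the left breast."
    report = _annotated(text, lexicon)
    mentions = match_concepts(report, lexicon)
    lesions, _, _ = assemble_lesions(report, mentions, lexicon)
    fv = lesions[0].feature_values
    assert fv["shape"].value == "irregular"
    assert fv["margin"].value == "smooth"


def test_conflicting_feature_values_keep_first_and_warn(lexicon):
    text = (
        "There is an oval mass in the upper outer quadrant of the left breast. "
        "The shape is round."
    )
    report = _annotated(text, lexicon)
    mentions = match_concepts(report, lexicon)
    lesions, _, warnings = assemble_lesions(report, mentions, lexicon)
    assert lesions[0].feature_values["shape"].value == "oval"
    assert any("conflicting values for shape" in w for w in warnings)


def test_assembled_values_belong_to_feature_value_sets(lexicon):
    """On a synthetic corpus every asserted categorical value is in-lexicon
    and feature counts respect the per-entity maxima."""
    from birads_extract import CorpusConfig, generate_corpus, run_pipeline

    reports, _ = generate_corpus(CorpusConfig(n_reports=50, seed=3), lexicon)
    for extraction in run_pipeline(reports, lexicon):
        for lesion in extraction.lesions:
            limit = 9 if lesion.entity_type == "mass" else 8
            assert lesion.feature_count <= limit
            defs = {
                f.name: f
                for f in lexicon.features_for(lesion.entity_type)
            }
            for name, fv in lesion.feature_values.items():
                assert name in defs
                feat = defs[name]
                if feat.data_type == "categorical" and fv.value is not None:
                    allowed = {v.casefold() for v in feat.value_set}
                    assert fv.value.casefold() in allowed
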