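import pytest

from birads_extract import RawReport, default_lexicon

# Worked-example texts: a two-lesion description (mass with all nine
# features, NME with three) and its impression.
EXAMPLE1_DESCRIPTION = (
    "There is a 1.1 cm × 1.0 cm × 1.5 cm oval mass with irregular margin in "
    "the upper inner quadrant of the left breast. Isointensity in T1WI, high "
    "signal in T2WI and high signal in DWI. There are dark internal "
    "septations in internal enhancement and kinetic curve is plateau. There "
    "is a non-mass enhancement in the upper outer quadrant of the right "
    "breast. Isointensity in DWI, internal enhancement is heterogeneous."
)
EXAMPLE1_IMPRESSION = (
    "BI-RADS category of the mass in the upper inner quadrant of the left breast: 5."
)

# Three sentences; the decimal points in the size expression must not split.
EXAMPLE2_TEXT = (
    "There is a 1.1 cm × 1.0 cm × 1.5 cm oval mass with irregular margin in "
    "the upper inner quadrant of the left breast. Isointensity in T1WI, high "
    "signal in T2WI and high signal in DWI. There are dark internal "
    "septations in internal enhancement and kinetic curve is plateau."
)

# Synonym conversion: "lesion" -> mass, "clear" -> smooth, "boundary" -> margin.
EXAMPLE3_TEXT = (
    "There is a 1.6 cm × 1.2 cm × 1.2 cm oval lesion with clear boundary in "
    "the upper inner quadrant of the left breast."
)


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture()
def example1_report():
    return RawReport(
        report_id="example1",
        description=EXAMPLE1_DESCRIPTION,
        impression=EXAMPLE1_IMPRESSION,
    )
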