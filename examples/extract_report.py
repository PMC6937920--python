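"""Extract lesions, the index lesion and BI-RADS category from one report.

The report below describes two lesions: a mass carrying all nine imaging
features and a non-mass enhancement carrying three.  The lesion described
with the most features is selected as the index lesion.
"""

from birads_extract import RawReport, default_lexicon, extract_report

report = RawReport(
    report_id="demo",
    description=(
        "There is a 1.1 cm × 1.0 cm × 1.5 cm oval mass with irregular margin "
        "in the upper inner quadrant of the left breast. Isointensity in T1WI, "
        "high signal in T2WI and high signal in DWI. There are dark internal "
        "septations in internal enhancement and kinetic curve is plateau. "
        "There is a non-mass enhancement in the upper outer quadrant of the "
        "right breast. Isointensity in DWI, internal enhancement is "
        "heterogeneous. No skin invasion."
    ),
    impression=(
        "BI-RADS category of the mass in the upper inner quadrant of the left "
        "breast: 5. BI-RADS category of the non-mass enhancement in the upper "
        "outer quadrant of the right breast: 3."
    ),
)

extraction = extract_report(report, default_lexicon())

for lesion in extraction.lesions:
    marker = " (index)" if lesion.lesion_index == extraction.index_lesion_index else ""
    print(f"lesion {lesion.lesion_index}: {lesion.entity_type}{marker}, "
          f"{lesion.feature_count} features, in {lesion.location}")
    for name, fv in lesion.feature_values.items():
        value = fv.value if fv.value is not None else f"{fv.size.dimensions_mm} mm"
        print(f"    {name:22s} = {value} [{fv.polarity}]")
for finding in extraction.associated_findings:
    print(f"finding: {finding.finding} [{finding.polarity}]")
print(f"final BI-RADS category: {extraction.final_birads} "
      f"(maximum of {extraction.birads_per_lesion})")

# The mass wins index selection 9 features to 3; the negated invasion is
# reported with its polarity but never counted as lesion evidence.
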