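# Methods

## The extraction model

The pipeline treats a breast MRI report as a two-part document: an imaging
description organized as one *section* per lesion, and a diagnostic
impression stating BI-RADS assessment categories. All linguistic knowledge
lives in an editable lexicon; the code implements only the combinatorics
(segmentation, longest-match merging, windowed negation, slot filling,
counting). The core modeling assumptions are:

- **Sections are lesion-scoped.** A sentence opens a new section iff it
  names a lesion entity (mass or non-mass enhancement, possibly via
  synonym) *and* contains a location phrase. This accepts both word
  orders — location first (as in reports that head each paragraph with the
  anatomy) and location last ("There is a … in the upper outer quadrant of
  the left breast"). Sentences before the first anchor form a *preamble*
  pseudo-section that can contribute associated findings but never a
  lesion. All value mentions inside a section attach to that section's
  lesion; there is no coreference or cross-section attribution.
- **The index lesion is the most-described lesion.** Feature counting uses
  asserted features only: negated mentions are stored with polarity but do
  not count as descriptive evidence. Ties break by larger maximal size
  dimension, then document order, and always raise `tie_flag` — ambiguity
  is surfaced, not hidden.
- **The final category is read, never inferred.** Only
  `<BI-RADS marker> … <digit 0–6>` patterns in the impression produce
  categories; the maximum wins. A lesion-free report defaults to
  category 1 (negative examination). Lesions without any category leave
  the field missing with a warning, so "category not detected" is an
  observable error class rather than a silent default.

### Feature inventory

A mass carries 9 countable features (location, shape, size, T1WI, T2WI,
DWI, margin, internal enhancement, kinetic curve) and an NME 8 (location,
distribution pattern, scope, T1WI, T2WI, DWI, internal enhancement,
kinetic curve); the three signal intensities count separately and the
generic "signal" heading is not itself a feature. Five associated findings
(lymphadenopathy; invasion of nipple, skin, chest wall, pectoralis muscle)
are report-level presence features with polarity asserted/negated.

### Value-to-feature attribution

Several value terms belong to more than one feature ("irregular" to shape
and margin; low/iso/high signal to all three sequences). An ambiguous
value binds to a feature-name token in the same sentence at most two
tokens away, preferring a name *after* the value ("high signal **in
T2WI**") over one before ("**margin** is irregular"), and falling back to
feature-definition order (shape precedes margin) when no name is nearby.
The two-token window covers the copular and prepositional constructions
the templates and the motivating report style use, while keeping the rule
strictly local.

### Negation

Default: a cue negates a concept when it precedes it in the same sentence
with at most 3 tokens strictly between cue and concept span, counted on
merged tokens (a multiword lexicon term is one word unit). Window and
direction (`cue_before_concept`, `cue_after_concept`, `both`) are lexicon
settings and CLI flags, since the appropriate direction depends on the
report language's word order.

### Sizes

The size grammar accepts 1–3 decimal dimensions with units cm or mm and
separators `×` or `x`; everything is normalized to millimetres (cm × 10).
Size comparison in evaluation uses a 0.1 mm tolerance to absorb decimal
float conversion.

## Lexicon

The bundled default lexicon (YAML) encodes the BI-RADS MRI vocabulary:
value sets per feature, 12 canonical location phrases, synonym table
(single hop, validated acyclic — e.g. "lesion" → "mass", "clear" →
"smooth"), spelling corrections (notably "Bi-RAS" → "BI-RADS") and
abbreviations ("NME"). Validation enforces: unique case-folded canonical
surfaces, synonyms resolving to existing canonicals without chains, 9/8
feature counts, window ≥ 1, non-empty cue list, category alphabet 0–6.
Matching is deliberately literal: no edit-distance or embedding fuzziness
beyond the explicit correction table, because the failure modes of a
dictionary system should be auditable term by term.

## Synthetic corpus generator

The generator emulates the structure of a breast-MRI report population
with these defaults (all `CorpusConfig` fields):

| parameter | default | unit/meaning |
|---|---|---|
| lesion-count weights | 7 : 93 : 338 : 40 | reports with 0/1/2/3 lesions |
| index feature-count law | trunc-normal(9.2, 1.8) on {5..9} | mean ≈ 8.0, SD ≈ 1.05 |
| non-index law, 2-lesion | trunc-normal(4.2, 1.4) on {3..8} | mean ≈ 4.5 |
| non-index law, 3-lesion | trunc-normal(5.0, 1.9) on {3..8} | mean ≈ 5.2 |
| index-category weights | 28 : 60 : 87 : 119 : 177 | BI-RADS 2..6 |
| mass probability | 0.7 | entity type per lesion (forced mass if 9 features) |
| finding rates | 0.05 asserted / 0.25 negated | per finding per report |
| dimensions | 1–3 × integers 5–40 mm | rendered in cm or mm |

The discretized truncated-normal locations/scales were set by matching the
truncated law's mean/SD to the target summaries above (support truncation
shifts the raw parameters). Non-index counts are resampled below the index
count so the gold index is unique by construction; `allow_feature_count_ties`
disables this for tie-break testing. Non-index categories are drawn uniform
on {2..index category} so the report maximum equals the index category.

Rendering uses English templates mirroring the section/sentence structure
the pipeline parses, with surfaces drawn at random among canonical terms
and synonyms. **Zero-noise renderings are exactly recoverable** — this is
the repository's principal oracle; the generate → extract → compare loop
must close at 100% on every seed.

Noise injection corrupts text only (gold is immutable): per-token spelling
corruption (character deletion/transposition; the category marker gets its
catalogued "Bi-RAS" form, which the correction table can still rescue),
off-lexicon paraphrases of enhancement/kinetic values (e.g. the rim-
enhancement description rewritten as free prose), and extra negated
findings. A separate RNG stream drives noise, so the same seed yields the
same gold corpus at every noise setting.

### What the generator does not emulate

Real reports vary in template structure, contain hedging, anaphora
("the lesion described above"), inconsistent section order, and language-
specific word order (the motivating population was Chinese free text).
Passing the perfect-recovery oracle therefore demonstrates internal
consistency of the rules on lexicon-compliant text, not clinical-grade
accuracy on real reports; the noise experiments bound how quickly accuracy
decays as compliance drops, not where a given hospital's reports sit.

## Evaluation protocol

Lesion correspondence between prediction and gold is by location phrase
first, remaining lesions by document order. Per slot (entity-qualified
feature, associated finding, index-lesion identity, final category): a
missing prediction is FN classed *not detected*; a wrong value is FP + FN
classed *not detected correctly*; spurious predictions are FP. Overall
rows micro-average by pooling counts. Zero denominators are flagged
undefined, never reported as 0. Cohen's kappa is computed from the
marginal-chance formula, returning 1.0 in the degenerate all-agree
constant case. Feature-count CIs use the normal approximation
mean ± 1.96·SD/√n with sample SD, matching the symmetric intervals such
summaries conventionally report.

## Problem sizes and numerical choices

The test suite and acceptance script use corpora of 100–500 reports for
pipeline checks (the perfect-recovery oracle runs at n = 500) and 5 000
for distribution goodness-of-fit, with 10 seeds × 4 spelling rates for the
monotone-degradation check; these sizes give stable statistics (3-SE
binomial bands, chi-square at α = 0.01) while the whole suite runs in
seconds. All randomness flows from explicit integer seeds; generation and
extraction are fully deterministic given seed and configuration.

## Known limitations

- Negation is purely distance-based: "no evidence of a mass or skin
  invasion" negates only concepts within the window; scope-based cues and
  double negation are out of scope.
- One value per feature per lesion (first mention wins, conflicts logged);
  interval or changed descriptions ("previously smooth, now irregular")
  are not modeled.
- BI-RADS-to-lesion linking in the impression is positional/locational;
  free-form impressions that reference lesions indirectly will still
  contribute to the report maximum but may mislink per-lesion categories.
- The shipped lexicon is a compact English BI-RADS core, not an exhaustive
  clinical vocabulary; production use requires extending it on local
  development reports, which is exactly the workflow the editable YAML
  format is designed for.
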