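# Default BI-RADS MRI lexicon for breast MRI report extraction.
#
# The lexicon drives every pipeline stage: tokenization (multiword terms are
# merged longest-match-first), concept matching (exact or one synonym hop),
# negation detection (cue list + token-distance window), numeric size parsing
# and BI-RADS category extraction.  It is a plain editable file so that users
# can extend value sets, synonyms and correction tables for their own report
# styles without touching code.
#
# Feature sets per entity: a mass carries 9 countable features and a
# non-mass enhancement (NME) 8, counting the T1WI / T2WI / DWI signal
# intensities as three separate features.  "Other associated findings" are
# report-level presence features without value sets.

features:
  mass:
    - name: location
      data_type: categorical
      value_set: &locations
        - the upper inner quadrant of the left breast
        - the upper outer quadrant of the left breast
        - the lower inner quadrant of the left breast
        - the lower outer quadrant of the left breast
        - the upper inner quadrant of the right breast
        - the upper outer quadrant of the right breast
        - the lower inner quadrant of the right breast
        - the lower outer quadrant of the right breast
        - the central region of the left breast
        - the central region of the right breast
        - the retroareolar region of the left breast
        - the retroareolar region of the right breast
    - name: shape
      data_type: categorical
      value_set: [oval, round, irregular]
    - name: size
      data_type: numerical
      units: mm
    - name: t1wi
      data_type: categorical
      value_set: &signal_values [low signal, isointensity, high signal]
    - name: t2wi
      data_type: categorical
      value_set: *signal_values
    - name: dwi
      data_type: categorical
      value_set: *signal_values
    - name: margin
      data_type: categorical
      value_set: [smooth, irregular, spiculated]
    - name: internal_enhancement
      data_type: categorical
      value_set: [homogeneous, heterogeneous, rim enhancement, dark internal septations]
    - name: kinetic_curve
      data_type: categorical
      value_set: &kinetic_values [persistent, plateau, wash-out]
  nme:
    - name: location
      data_type: categorical
      value_set: *locations
    - name: distribution_pattern
      data_type: categorical
      value_set: [focal area, linear, segmental, regional, multiple regions, diffuse]
    - name: scope
      data_type: numerical
      units: mm
    - name: t1wi
      data_type: categorical
      value_set: *signal_values
    - name: t2wi
      data_type: categorical
      value_set: *signal_values
    - name: dwi
      data_type: categorical
      value_set: *signal_values
    - name: internal_enhancement
      data_type: categorical
      value_set: [homogeneous, heterogeneous, clumped, clustered ring]
    - name: kinetic_curve
      data_type: categorical
      value_set: *kinetic_values
  associated_finding:
    - name: lymphadenopathy
      data_type: categorical
    - name: nipple_invasion
      data_type: categorical
    - name: skin_invasion
      data_type: categorical
    - name: chest_wall_invasion
      data_type: categorical
    - name: pectoralis_muscle_invasion
      data_type: categorical

# Canonical surface forms of the two lesion entity types.
entities:
  mass: mass
  nme: non-mass enhancement

# Surfaces that NAME a feature in report text (as opposed to carrying a
# value).  They disambiguate values shared between features, e.g.
# "irregular margin" (margin) vs "irregular mass" (shape) and
# "high signal in T2WI" vs "... in DWI".
feature_terms:
  location: location
  shape: shape
  size: size
  margin: margin
  t1wi: t1wi
  t2wi: t2wi
  dwi: dwi
  internal enhancement: internal_enhancement
  kinetic curve: kinetic_curve
  distribution pattern: distribution_pattern
  scope: scope
  lymphadenopathy: lymphadenopathy
  nipple invasion: nipple_invasion
  skin invasion: skin_invasion
  chest wall invasion: chest_wall_invasion
  pectoralis muscle invasion: pectoralis_muscle_invasion

# One synonym hop: report surface -> canonical surface (never chained).
synonyms:
  lesion: mass
  nodule: mass
  non-mass-like enhancement: non-mass enhancement
  clear: smooth
  circumscribed: smooth
  boundary: margin
  enhancement kinetic curve: kinetic curve
  time-intensity curve: kinetic curve
  washout: wash-out
  hypointensity: low signal
  hypointense: low signal
  isointense: isointensity
  hyperintensity: high signal
  hyperintense: high signal
  enlarged lymph nodes: lymphadenopathy
  enlarged lymph node: lymphadenopathy
  ovoid: oval

# Catalogued misspellings (applied case-insensitively at word boundaries
# before anything else looks at the text).
spelling_corrections:
  Bi-RAS: BI-RADS
  BIRADS: BI-RADS
  irregluar: irregular
  hetrogeneous: heterogeneous
  isointensty: isointensity
  speculated: spiculated

# Abbreviations expanded to their full form (case-sensitive word boundaries).
abbreviations:
  NME: non-mass enhancement

negation:
  cues: ["no", "without", "not", "absent"]
  # maximum number of tokens strictly between cue and concept
  window: 3
  # cue_before_concept | cue_after_concept | both
  direction: cue_before_concept

birads:
  marker: BI-RADS
  values: [0, 1, 2, 3, 4, 5, 6]
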