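# UKBDRS: UK Biobank Dementia Risk Score.
# Provenance: approximate transcription. Age and education carry linear
# per-year weights; their theoretical-maximum contributions are evaluated at
# the conventional anchors of 100 years of age and 20 years of education.
name: UKBDRS
provenance: approximate transcription; linear age/education weights anchored at 100 y / 20 y
items:
  - name: age
    kind: linear
    demographic: true
    slope: 0.17
    anchor: 100
  - name: education
    kind: linear
    demographic: true
    slope: -0.012
    anchor: 20
  - name: sex
    kind: categorical
    demographic: true
    mapping: {female: 0, male: 0.25}
  - name: diabetes
    kind: binary
    points: 0.35
  - name: depression
    kind: binary
    points: 0.35
  - name: stroke
    kind: binary
    points: 0.4
  - name: hypertension
    kind: binary
    points: 0.2
  - name: cholesterol
    kind: banded
    bands:
      - {max: 6.5, points: 0}
      - {min: 6.5, points: 0.15}
  - name: deprivation
    kind: binary
    points: 0.3
  - name: living_alone
    kind: binary
    points: 0.2
  - name: family_history
    kind: binary
    points: 0.3
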