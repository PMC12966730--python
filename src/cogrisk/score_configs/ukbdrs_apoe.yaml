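# UKBDRS-APOE: UK Biobank Dementia Risk Score extended with ApoE-e4 status.
# Provenance: approximate transcription (UKBDRS items plus an ApoE-e4 carrier
# weight); linear age/education anchored at 100 y / 20 y.
name: UKBDRS-APOE
provenance: approximate transcription; UKBDRS plus ApoE-e4 carrier weight
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
  - name: apoe4
    kind: binary
    points: 0.85
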