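# CogDrisk: Cognitive Health and Dementia Risk Assessment.
# Provenance: approximate transcription (broad lifestyle/health coverage,
# protective items negative); replace with published weights for real analyses.
name: CogDrisk
provenance: approximate transcription; replace with published weights for real analyses
items:
  - name: age
    kind: banded
    demographic: true
    bands:
      - {max: 65, points: 0}
      - {min: 65, max: 70, points: 2}
      - {min: 70, max: 75, points: 3}
      - {min: 75, max: 80, points: 4}
      - {min: 80, points: 5}
  - name: sex
    kind: categorical
    demographic: true
    mapping: {female: 0, male: 1}
  - name: education
    kind: banded
    demographic: true
    bands:
      - {max: 8, points: 2}
      - {min: 8, max: 12, points: 1}
      - {min: 12, points: 0}
  - name: diabetes
    kind: binary
    points: 2
  - name: depression
    kind: binary
    points: 2
  - name: smoking
    kind: binary
    points: 2
  - name: head_injury
    kind: binary
    points: 2
  - name: stroke
    kind: binary
    points: 2
  - name: hypertension
    kind: binary
    points: 1
  - name: hearing_loss
    kind: binary
    points: 1
  - name: poor_sleep
    kind: binary
    points: 1
  - name: social_isolation
    kind: binary
    points: 1
  - name: high_alcohol
    kind: binary
    points: 1
  - name: cholesterol
    kind: banded
    bands:
      - {max: 6.5, points: 0}
      - {min: 6.5, points: 1}
  - name: bmi
    kind: banded
    bands:
      - {max: 30, points: 0}
      - {min: 30, points: 2}
  - name: physical_inactivity
    kind: banded
    bands:
      - {max: 0.5, points: -2}
      - {min: 0.5, points: 0}
  - name: low_cognitive_activity
    kind: banded
    bands:
      - {max: 0.5, points: -3}
      - {min: 0.5, points: 0}
  - name: low_fish_intake
    kind: banded
    bands:
      - {max: 0.5, points: -2}
      - {min: 0.5, points: 0}
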