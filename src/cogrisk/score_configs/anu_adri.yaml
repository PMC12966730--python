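# ANU-ADRI: Australian National University Alzheimer's Disease Risk Index.
# Provenance: approximate transcription of the published self-report index
# (point weights, protective items negative). Values are editable; the engine
# is fully config-driven, so a verbatim transcription from the source
# publication drops in with no code change. Age weights are unisex here
# (the published index uses sex-specific age bands).
name: ANU-ADRI
provenance: approximate transcription; unisex age bands; replace with published weights for real analyses
items:
  - name: age
    kind: banded
    demographic: true
    bands:
      - {max: 60, points: 0}
      - {min: 60, max: 65, points: 1}
      - {min: 65, max: 70, points: 8}
      - {min: 70, max: 75, points: 12}
      - {min: 75, max: 80, points: 17}
      - {min: 80, max: 85, points: 21}
      - {min: 85, points: 26}
  - name: sex
    kind: categorical
    demographic: true
    mapping: {female: 0, male: 1}
  - name: education
    kind: banded
    demographic: true
    bands:
      - {max: 8, points: 6}
      - {min: 8, max: 12, points: 3}
      - {min: 12, points: 0}
  - name: bmi
    kind: banded
    bands:
      - {max: 25, points: 0}
      - {min: 25, max: 30, points: 2}
      - {min: 30, points: 5}
  - name: diabetes
    kind: binary
    points: 3
  - name: depression
    kind: binary
    points: 2
  - name: cholesterol
    kind: banded
    bands:
      - {max: 6.5, points: 0}
      - {min: 6.5, points: 3}
  - name: head_injury
    kind: binary
    points: 2
  - name: smoking
    kind: binary
    points: 4
  - name: high_alcohol
    kind: binary
    points: 3
  # Protective behaviours: absence of the risk-coded item earns negative points.
  - name: physical_inactivity
    kind: banded
    bands:
      - {max: 0.5, points: -2}
      - {min: 0.5, points: 0}
  - name: low_cognitive_activity
    kind: banded
    bands:
      - {max: 0.5, points: -7}
      - {min: 0.5, points: 0}
  - name: social_isolation
    kind: banded
    bands:
      - {max: 0.5, points: -4}
      - {min: 0.5, points: 0}
  - name: low_fish_intake
    kind: banded
    bands:
      - {max: 0.5, points: -3}
      - {min: 0.5, points: 0}
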