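# LIBRA2: updated LIfestyle for BRAin health index.
# Provenance: approximate transcription of the updated index on its rescaled
# all-positive point scale (more factors than LIBRA, minimum 0); replace with
# published weights for real analyses. No native demographic weights -- the
# pipeline augments with ANU-ADRI age/sex items.
name: LIBRA2
provenance: approximate transcription, rescaled positive scale; replace with published weights
items:
  - name: diabetes
    kind: binary
    points: 5.2
  - name: depression
    kind: binary
    points: 8.4
  - name: smoking
    kind: binary
    points: 6.0
  - name: physical_inactivity
    kind: binary
    points: 4.4
  - name: heart_disease
    kind: binary
    points: 4.0
  - name: kidney_disease
    kind: binary
    points: 4.4
  - name: hypertension
    kind: binary
    points: 6.4
  - name: cholesterol
    kind: banded
    bands:
      - {max: 6.5, points: 0}
      - {min: 6.5, points: 5.6}
  - name: bmi
    kind: banded
    bands:
      - {max: 30, points: 0}
      - {min: 30, points: 6.4}
  - name: high_alcohol
    kind: binary
    points: 4.0
  - name: poor_diet
    kind: binary
    points: 6.8
  - name: low_cognitive_activity
    kind: binary
    points: 12.8
  - name: hearing_loss
    kind: binary
    points: 4.8
  - name: social_isolation
    kind: binary
    points: 4.4
  - name: poor_sleep
    kind: binary
    points: 4.0
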