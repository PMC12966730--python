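# LIBRA: LIfestyle for BRAin health index.
# Provenance: published relative-risk-derived weights of the original index
# (risk factors positive, protective factors negative; no native demographic
# weights -- the pipeline augments with ANU-ADRI age/sex items for
# head-to-head comparison).
name: LIBRA
provenance: published weights of the original index (no demographics)
items:
  - name: diabetes
    kind: binary
    points: 1.3
  - name: depression
    kind: binary
    points: 2.1
  - name: smoking
    kind: binary
    points: 1.5
  - name: physical_inactivity
    kind: binary
    points: 1.1
  - name: heart_disease
    kind: binary
    points: 1.0
  - name: kidney_disease
    kind: binary
    points: 1.1
  - name: hypertension
    kind: binary
    points: 1.6
  - name: cholesterol          # hypercholesterolemia
    kind: banded
    bands:
      - {max: 6.5, points: 0}
      - {min: 6.5, points: 1.4}
  - name: bmi                  # obesity
    kind: banded
    bands:
      - {max: 30, points: 0}
      - {min: 30, points: 1.6}
  # Protective: low-to-moderate alcohol, healthy diet, high cognitive activity.
  - name: high_alcohol
    kind: banded
    bands:
      - {max: 0.5, points: -1.0}
      - {min: 0.5, points: 0}
  - name: poor_diet
    kind: banded
    bands:
      - {max: 0.5, points: -1.7}
      - {min: 0.5, points: 0}
  - name: low_cognitive_activity
    kind: banded
    bands:
      - {max: 0.5, points: -3.2}
      - {min: 0.5, points: 0}
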