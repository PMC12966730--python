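# CAIDE: Cardiovascular Risk Factors, Aging, and Incidence of Dementia.
# Provenance: integer point weights of the original midlife risk score
# (model without ApoE). This config deliberately encodes the integer-point
# variant and says so: published analyses sometimes use the underlying beta
# coefficients instead, which yield non-integer totals.
name: CAIDE
provenance: integer-point variant (original midlife score, no ApoE)
items:
  - name: age
    kind: banded
    demographic: true
    bands:
      - {max: 47, points: 0}
      - {min: 47, max: 53, points: 3}
      - {min: 53, points: 4}
  - name: education
    kind: banded
    demographic: true
    bands:
      - {max: 7, points: 3}
      - {min: 7, max: 10, points: 2}
      - {min: 10, points: 0}
  - name: sex
    kind: categorical
    demographic: true
    mapping: {female: 0, male: 1}
  - name: systolic_bp
    kind: banded
    bands:
      - {max: 140, points: 0}
      - {min: 140, points: 2}
  - name: bmi
    kind: banded
    bands:
      - {max: 30, points: 0}
      - {min: 30, points: 2}
  - name: cholesterol
    kind: banded
    bands:
      - {max: 6.5, points: 0}
      - {min: 6.5, points: 2}
  - name: physical_inactivity
    kind: binary
    points: 1
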