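# Lancet-based dementia risk score: each of the 14 modifiable risk factors of
# the 2024 Lancet Commission coded absent (=0) or present (=1 x risk factor
# weight), weighted by the Commission's published relative risks and summed.
# The Commission covers only potentially modifiable factors, so the score has
# no native age/sex weights; the pipeline augments it with the ANU-ADRI age
# and sex items for head-to-head comparison. The education weight is flagged
# demographic so demographics-stripped analyses remove it.
name: Lancet
provenance: Lancet Commission 2024 relative risks, present/absent coding
items:
  - name: education          # less education (early life)
    kind: banded
    demographic: true
    bands:
      - {max: 12, points: 1.6}
      - {min: 12, points: 0}
  - name: hearing_loss
    kind: binary
    points: 1.4
  - name: cholesterol        # high LDL cholesterol
    kind: banded
    bands:
      - {max: 6.5, points: 0}
      - {min: 6.5, points: 1.3}
  - name: depression
    kind: binary
    points: 1.9
  - name: head_injury        # traumatic brain injury
    kind: binary
    points: 1.7
  - name: physical_inactivity
    kind: binary
    points: 1.4
  - name: diabetes
    kind: binary
    points: 1.7
  - name: smoking
    kind: binary
    points: 1.3
  - name: hypertension
    kind: binary
    points: 1.3
  - name: bmi                # obesity
    kind: banded
    bands:
      - {max: 30, points: 0}
      - {min: 30, points: 1.3}
  - name: high_alcohol       # excessive alcohol
    kind: binary
    points: 1.2
  - name: social_isolation
    kind: binary
    points: 1.6
  - name: air_pollution
    kind: binary
    points: 1.1
  - name: vision_loss
    kind: binary
    points: 1.5
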