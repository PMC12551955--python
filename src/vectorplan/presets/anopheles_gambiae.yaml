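# Anopheles gambiae life-history thermal responses (editable defaults).
# Cooler thermal window than Ae. aegypti, per published trait fits for
# this species.  Per-day rates; documentation-level defaults.
name: anopheles_gambiae
development:
  egg:
    form: briere
    params: [2.7e-4, 13.2, 36.3]
    floor: 0.0
  larva:
    form: briere
    params: [1.1e-4, 13.2, 36.3]
    floor: 0.0
  pupa:
    form: briere
    params: [2.9e-4, 13.2, 36.3]
    floor: 0.0
mortality:
  egg:
    form: constant
    params: [0.06]
    floor: 1.0e-6
  larva:
    form: constant
    params: [0.06]
    floor: 1.0e-6
  pupa:
    form: constant
    params: [0.06]
    floor: 1.0e-6
  adult:
    form: linear
    params: [0.22, -4.0e-3]
    floor: 0.04
fecundity:
  form: quadratic
  params: [0.12, 16.0, 37.0]          # peaks near 26.5 C
  floor: 0.0
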