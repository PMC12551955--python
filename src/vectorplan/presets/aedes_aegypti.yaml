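# Aedes aegypti life-history thermal responses (editable defaults).
# Stage development and fecundity use Briere-1 curves with critical
# temperatures taken from published trait fits for this species; stage
# mortalities are held constant at typical mid-range values.  Units are
# per-day rates (fecundity: eggs per female per day).  These numbers are
# documentation-level defaults — analyses that need exact published fits
# should supply their own file.
name: aedes_aegypti
development:
  egg:
    form: briere
    params: [2.24e-4, 11.36, 39.17]   # ~0.33/day at 27 C
    floor: 0.0
  larva:
    form: briere
    params: [9.5e-5, 11.36, 39.17]    # ~0.14/day at 27 C
    floor: 0.0
  pupa:
    form: briere
    params: [2.4e-4, 11.36, 39.17]    # ~0.35/day at 27 C
    floor: 0.0
mortality:
  egg:
    form: constant
    params: [0.05]
    floor: 1.0e-6
  larva:
    form: constant
    params: [0.05]
    floor: 1.0e-6
  pupa:
    form: constant
    params: [0.05]
    floor: 1.0e-6
  adult:
    form: linear
    params: [0.18, -3.0e-3]           # longer-lived near the thermal optimum
    floor: 0.03
fecundity:
  form: briere
  params: [8.56e-3, 14.58, 34.61]     # ~8 eggs/female/day at 27 C
  floor: 0.0
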