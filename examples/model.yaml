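model:
  time_unit: years
  centering_constant: 0.2750467473638438
  terms:
  - name: x1
    kind: identity
    coefficient: 0.5297444435025996
    se: 0.03331217964753381
  - name: x2
    kind: identity
    coefficient: -0.3395675370249366
    se: 0.03128027511846611
  - name: x3
    kind: identity
    coefficient: 0.7102934943408827
    se: 0.06273878848268102
  max_followup: 7.0
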