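risk_groups:
  cutpoints:
  - -0.7353892502148643
  - -0.0015912224914846063
  - 0.7307340888313134
  labels:
  - Good
  - Fairly good
  - Fairly poor
  - Poor
  source: derivation centiles
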