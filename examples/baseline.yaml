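baseline:
  form: fp2_log_cumhaz
  powers:
  - -0.5
  - 0.0
  coefficients:
  - -2.3004505005156575
  - 0.14738989652477968
  - 1.2959086625021652
  r_squared: 0.9970796046867618
  time_range:
  - 0.0056591941750518395
  - 6.978341218422563
  time_unit: years
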