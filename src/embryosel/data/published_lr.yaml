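# Fixed coefficients of the published implantation-potential logistic score.
# number_day3 is the transformed Day-3 count |n - 8.4|; fragmentation_day2 is
# the Day-2 volume-loss fraction; tcv_day2 is pre-multiplied by tcv_scale.
version: 1
tcv_scale: 1.0e-05
coefficients:
  intercept: 12.070
  number_day2: 0.817
  tcv_day2: -1.572
  fragmentation_day2: -12.250
  age_male: -0.311
  number_day3: -2.697
  "number_day2:cod_day3": -0.412
  "tcv_day2:age_male": 0.045
  "cod_day2:age_male": -0.065
  "fragmentation_day2:age_male": 0.327
  "cod_day2:number_day3": 1.434
  "parity_day2:number_day3": 0.730
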