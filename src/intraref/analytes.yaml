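# Default analyte configuration: routine (population) reference ranges and
# analytical CVs for the four serum nutrition-status markers.
TRF:
  units: mg/dL
  population_range: [190, 340]
  sex_ranges:
    male: [190, 300]
    female: [200, 340]
  cva_percent: 1.07
  display_decimals: 0
ALB:
  units: g/dL
  population_range: [3.8, 5.2]
  cva_percent: 2.88
  display_decimals: 1
RBP:
  units: mg/dL
  population_range: [2.7, 6.0]
  sex_ranges:
    male: [2.7, 6.0]
    female: [1.9, 4.6]
  cva_percent: 1.38
  display_decimals: 1
TTR:
  units: mg/dL
  population_range: [22.0, 44.0]
  cva_percent: 1.83
  display_decimals: 1
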