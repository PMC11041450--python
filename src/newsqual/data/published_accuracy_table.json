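{
  "cost": {
    "typology": [80.00, 75.00, 60.78, 66.67, 60.00, 54.55],
    "hybrid": [100.00, 92.50, 86.67, 76.25, 67.00, 59.65]
  },
  "harm": {
    "typology": [100.00, 97.50, 86.67, 76.39, 72.94, 66.67],
    "hybrid": [90.00, 90.00, 90.00, 85.00, 81.00, 75.83]
  },
  "conflict": {
    "typology": [75.00, 72.50, 66.67, 61.11, 55.29, 56.41],
    "hybrid": [90.00, 87.50, 81.67, 68.75, 59.00, 50.93]
  }
}
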