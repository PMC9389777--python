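{
  "comment": "SYNTHETIC RECONSTRUCTION of the NEMI quadrant profile for the comparator HPLC method: larger mobile-phase volumes push waste above 50 g per batch.",
  "tool": "NEMI",
  "fields": {
    "pbt_free": true,
    "non_hazardous": false,
    "non_corrosive": true,
    "waste_under_50g": false
  }
}
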