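{
  "comment": "SYNTHETIC RECONSTRUCTION of the NEMI quadrant profile for the spectrofluorometric method (user-declared flags, not database lookups): no PBT-listed reagents, ethanol/acetonitrile are hazardous-listed, pH 2 is within the non-corrosive 2-12 window, waste under 50 g per sample.",
  "tool": "NEMI",
  "fields": {
    "pbt_free": true,
    "non_hazardous": false,
    "non_corrosive": true,
    "waste_under_50g": true
  }
}
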