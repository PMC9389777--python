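{
  "comment": "SYNTHETIC RECONSTRUCTION of the 15-zone GAPI profile for the comparator HPLC method. The published assessment states 4 green and 3 red zones; the zone-by-zone colouring is reconstructed.",
  "tool": "GAPI",
  "fields": {
    "collection": "green",
    "preservation": "green",
    "transport": "green",
    "storage": "green",
    "method_type": "yellow",
    "extraction_scale": "yellow",
    "extraction_solvents": "yellow",
    "additional_treatments": "yellow",
    "reagent_amount": "red",
    "health_hazard": "yellow",
    "safety_hazard": "yellow",
    "energy": "red",
    "occupational_hazard": "yellow",
    "waste_amount": "yellow",
    "waste_treatment": "red"
  }
}
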