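{
  "comment": "SYNTHETIC RECONSTRUCTION of the 15-zone GAPI profile for the spectrofluorometric method. The published assessment states 5 green zones and 1 red zone; the zone-by-zone colouring is reconstructed.",
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
    "reagent_amount": "yellow",
    "health_hazard": "yellow",
    "safety_hazard": "yellow",
    "energy": "yellow",
    "occupational_hazard": "green",
    "waste_amount": "yellow",
    "waste_treatment": "red"
  }
}
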