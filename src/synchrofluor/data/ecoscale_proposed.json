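{
  "comment": "SYNTHETIC RECONSTRUCTION. The published assessment reports only the final eco-scale score (79); the line-by-line penalty decomposition below was reconstructed from the method's reagent list and procedure so that the total (21 penalty points) reproduces it. It is not the original authors' ledger.",
  "entries": [
    {"name": "ethanol", "pictogram_count": 2, "signal_word": "danger", "amount_bracket": "<10", "note": "diluting solvent, <10 mL per sample"},
    {"name": "acetonitrile", "pictogram_count": 2, "signal_word": "danger", "amount_bracket": "<10", "note": "plasma protein precipitation, 3 mL"},
    {"name": "HCl buffer (pH 2)", "pictogram_count": 1, "signal_word": "danger", "amount_bracket": "<10", "note": "1.5 mL of 0.1 N buffer"},
    {"name": "SDS 0.5%", "pictogram_count": 1, "signal_word": "warning", "amount_bracket": "<10", "note": "micellar enhancer, 2 mL"},
    {"name": "spectrofluorometer + ancillary equipment", "category": "instrument", "penalty_points": 2, "note": "scan plus vortex/centrifuge/evaporation for plasma work"},
    {"name": "waste", "category": "waste", "penalty_points": 8, "note": ">10 mL aqueous/organic waste per sample, no treatment"}
  ]
}
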