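{
  "comment": "SYNTHETIC RECONSTRUCTION of the 12-principle AGREE score vector for the spectrofluorometric method. Only the overall value (0.81) is published; these per-principle scores are plausible assignments whose equal-weight mean rounds (half-up, 2 dp) to it.",
  "principles": [
    "sample treatment", "sample amount", "device positioning", "procedure steps",
    "automation/miniaturisation", "derivatization", "waste", "throughput",
    "energy", "reagent source", "toxicity", "operator safety"
  ],
  "principle_scores": [0.70, 0.85, 0.66, 0.80, 0.75, 1.00, 0.72, 0.85, 0.95, 0.80, 0.80, 0.80]
}
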