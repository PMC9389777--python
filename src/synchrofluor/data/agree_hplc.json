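{
  "comment": "SYNTHETIC RECONSTRUCTION of the 12-principle AGREE score vector for the comparator HPLC method. Only the overall value (0.58) is published; these per-principle scores are plausible assignments whose equal-weight mean rounds (half-up, 2 dp) to it.",
  "principles": [
    "sample treatment", "sample amount", "device positioning", "procedure steps",
    "automation/miniaturisation", "derivatization", "waste", "throughput",
    "energy", "reagent source", "toxicity", "operator safety"
  ],
  "principle_scores": [0.40, 0.75, 0.60, 0.55, 0.50, 1.00, 0.35, 0.60, 0.45, 0.70, 0.55, 0.50]
}
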