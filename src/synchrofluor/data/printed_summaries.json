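{
  "comment": "Printed Mean/RSD summary lines of the reference recovery tables. standard_addition FEX rsd: the printed 1.431 disagrees with the value recomputed from its own three rows (1.413), likely a digit transposition; both are stored.",
  "mixtures": {
    "FEX": {"mean": 101.05, "rsd": 0.783},
    "PSE": {"mean": 99.32, "rsd": 0.938}
  },
  "plasma": {
    "FEX": {"mean": 95.21, "rsd": 1.938},
    "PSE": {"mean": 94.89, "rsd": 1.763}
  },
  "standard_addition": {
    "FEX": {"mean": 99.55, "rsd": 1.431, "rsd_recomputed": 1.413},
    "PSE": {"mean": 99.13, "rsd": 0.975}
  }
}
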