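{
  "comment": "Tablet-assay percent-recovery summaries (n = 5 each) for the proposed spectrofluorometric method and the reference HPLC method, with the printed t/F statistics and tabulated critical values at P = 0.05.",
  "critical_t": 2.306,
  "critical_f": 6.388,
  "FEX": {
    "proposed": {"mean": 99.49, "rsd": 0.931, "n": 5},
    "reported_hplc": {"mean": 99.02, "rsd": 1.072, "n": 5},
    "printed_t": 0.759,
    "printed_f": 1.312
  },
  "PSE": {
    "proposed": {"mean": 98.67, "rsd": 0.634, "n": 5},
    "reported_hplc": {"mean": 99.63, "rsd": 1.257, "n": 5},
    "printed_t": 1.540,
    "printed_f": 4.006
  }
}
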