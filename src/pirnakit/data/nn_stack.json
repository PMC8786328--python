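{
  "comment": "Watson-Crick nearest-neighbor stacking free energies, kcal/mol at 37 C (Xia et al. 1998 RNA parameters). Key = 5'->3' dinucleotide on the guide strand, DNA alphabet; complementary strand implied.",
  "stack": {
    "AA": -0.93,
    "TT": -0.93,
    "AT": -1.10,
    "TA": -1.33,
    "CT": -2.08,
    "AG": -2.08,
    "CA": -2.11,
    "TG": -2.11,
    "GT": -2.24,
    "AC": -2.24,
    "GA": -2.35,
    "TC": -2.35,
    "CG": -2.36,
    "GG": -3.26,
    "CC": -3.26,
    "GC": -3.42
  }
}
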