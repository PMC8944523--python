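{
  "comment": "EMBOSS-style pKa values used for isoelectric point calculation; swap this file to use a different published set.",
  "n_terminus": 8.6,
  "c_terminus": 3.6,
  "positive": {"H": 6.5, "K": 10.8, "R": 12.5},
  "negative": {"D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}
}
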