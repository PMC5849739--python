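# Default Ballesteros-Weinstein annotation for the human beta2 adrenergic
# receptor (author/PDB numbering, as in entries 3SN6 and 2RH1).
chain: R
bw_map:
  "1.50": 51
  "2.50": 79
  "3.40": 121
  "3.41": 122
  "3.49": 130
  "3.50": 131
  "5.50": 211
  "5.73": 234
  "5.76": 237
  "6.25": 263
  "6.29": 267
  "6.30": 268
  "6.32": 270
  "6.35": 273
  "6.44": 282
  "7.49": 322
  "7.50": 323
  "7.51": 324
  "7.52": 325
  "7.53": 326
tm_ranges:
  1: [29, 60]
  2: [67, 96]
  3: [103, 136]
  4: [147, 171]
  5: [197, 229]
  6: [262, 298]
  7: [305, 328]
  8: [329, 341]
motifs:
  ionic_lock: ["3.50", "6.30"]
  triad_core: ["3.40", "5.50", "6.44"]
  npxxy: ["7.49", "7.50", "7.51", "7.52", "7.53"]
  tm6_lysines: ["6.25", "6.29", "6.32", "6.35"]
protonated_residues: [79, 122, 130, 234, 237, 268]
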