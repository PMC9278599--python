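# Fatal-CVD outcome definitions (ICD-10).  Ranges are read at the
# 3-character category level; a dotted entry names a single sub-code.
globorisk:
  include: ["I20-I25", "I46.1", "I60-I69"]
  exclude: []
score:
  include: ["I10-I15", "I20-I25", "R96.0", "R96.1", "I44-I73"]
  exclude: ["I45.6", "I51.4", "I52", "I60", "I62", "I67.1", "I67.5", "I67.7"]
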