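{
  "core": {"total": 11400},
  "species": [
    {"name": "sigma70", "total": 7600, "kd_core": "0.01 nM", "kon_core": 1e8},
    {"name": "sigmaAlt", "total": 7600, "kd_core": "0.01 nM", "kon_core": 1e8}
  ],
  "promoters": [
    {"name": "P70", "cognate_sigma": "sigma70", "count": 200, "km": "1 nM",
     "kmax": "40/min", "operon_length": 2000, "retention_length": 300,
     "release_mode": "separate_release"},
    {"name": "PAlt", "cognate_sigma": "sigmaAlt", "count": 200, "km": "1 nM",
     "kmax": "40/min", "operon_length": 2000, "retention_length": 300,
     "release_mode": "separate_release"}
  ],
  "model": "cycle"
}
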