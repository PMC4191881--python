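{
  "core": {"total": 10300},
  "species": [
    {"name": "sigma70", "total": 9000, "kd_core": "1 nM"},
    {"name": "sigmaAlt", "total": 5000, "kd_core": "4 nM"}
  ],
  "promoters": [
    {"name": "PmRNA", "cognate_sigma": "sigma70", "km": "10 uM"},
    {"name": "PAlt", "cognate_sigma": "sigmaAlt", "km": "10 uM"}
  ],
  "model": "free",
  "response": {"control": "core", "promoter": "PAlt",
               "grid": {"start": 5000, "stop": 13000, "num": 200}}
}
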