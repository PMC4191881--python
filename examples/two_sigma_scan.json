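{
  "context": {"volume_fl": 1.32},
  "core": {"total": 11400},
  "species": [
    {"name": "sigma70", "total": 5700, "kd_core": "1 nM"},
    {"name": "sigmaAlt", "total": 0, "kd_core": "1 nM"}
  ],
  "model": "free",
  "scan": {"control": "sigmaAlt", "grid": {"start": 100, "stop": 20000, "num": 50}},
  "onset": {"control": "sigmaAlt", "reference_species": "sigma70"}
}
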