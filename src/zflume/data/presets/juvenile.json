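{
  "name": "juvenile",
  "u0": 6.0,
  "du": 1.5,
  "stage_s": 30,
  "max_stages": null,
  "regime": "fast"
}
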