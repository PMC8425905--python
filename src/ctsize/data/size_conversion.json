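{
  "comment": "Exponential fits f = a * exp(-b * d) for the size conversion factor as a function of patient size d in cm, per AAPM Report 204 (body 32-cm and head 16-cm PMMA reference phantoms).",
  "valid_range_cm": [6.0, 55.0],
  "curves": {
    "body-32cm": {"a": 3.704369, "b": 0.03671937},
    "head-16cm": {"a": 1.874799, "b": 0.03871313}
  }
}
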