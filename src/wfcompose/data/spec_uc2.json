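{
  "input": {"data": "data:0943", "format": "format:3712"},
  "output": {"data": "data:2600", "format": "format:1915"},
  "constraints": [
    "use operation:3631",
    "use operation:2436",
    "use operation:2436 only after operation:3631",
    "use ProteinProphet only after PeptideProphet"
  ],
  "max_length": 6,
  "mode": "shortest_only"
}
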