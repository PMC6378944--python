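{
  "input": {"data": "data:0943", "format": "format:3712"},
  "output": {"data": "data:0928", "format": "format:1915"},
  "constraints": [
    "use operation:3639",
    "use operation:3639 only after operation:3648"
  ],
  "max_length": 4,
  "mode": "shortest_only"
}
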