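{
  "schema": 1,
  "name": "colorloop",
  "phases": {
    "prep": [],
    "main": [
      {"id": "s1", "type": "action", "component": "mixer", "method": "dose_red", "args": {"v": {"dynamic": "red"}}},
      {"id": "s2", "type": "action", "component": "mixer", "method": "dose_blue", "args": {"v": {"dynamic": "blue"}}},
      {"id": "s3", "type": "action", "component": "mixer", "method": "measure", "args": {}, "save_as": "score"}
    ],
    "cleanup": []
  }
}
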