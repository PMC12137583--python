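{
  "schema": 1,
  "name": "fixture",
  "phases": {
    "prep": [
      {"id": "s1", "type": "action", "component": "balance", "method": "tare", "args": {}}
    ],
    "main": [
      {"id": "s2", "type": "action", "component": "pump", "method": "dose", "args": {"volume": {"literal": 1.0}}},
      {"id": "s3", "type": "action", "component": "sdl", "method": "analyze",
       "args": {"param_1": {"dynamic": "param_1"}, "param_2": {"dynamic": "param_2"}},
       "save_as": "score"}
    ],
    "cleanup": [
      {"id": "s4", "type": "action", "component": "balance", "method": "tare", "args": {}}
    ]
  }
}
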