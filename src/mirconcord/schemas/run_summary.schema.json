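{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "mirconcord run summary",
  "type": "object",
  "required": ["parameters", "seed", "stages", "warnings"],
  "properties": {
    "parameters": {"type": "object"},
    "seed": {"type": ["integer", "null"]},
    "stages": {
      "type": "object",
      "additionalProperties": {"type": "object"}
    },
    "warnings": {"type": "array", "items": {"type": "string"}}
  },
  "additionalProperties": false
}
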