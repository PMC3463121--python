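{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "smbpls module document",
  "type": "object",
  "required": ["schema_version", "tool", "tool_version", "stop_reason", "modules"],
  "properties": {
    "schema_version": {"type": "string"},
    "tool": {"type": "string"},
    "tool_version": {"type": "string"},
    "stop_reason": {"type": "string", "enum": ["objective_floor", "max_modules", "degenerate"]},
    "modules": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["samples", "variables", "response", "block_weights", "objective", "provenance"],
        "properties": {
          "samples": {"type": "array", "minItems": 1, "items": {"type": "string"}},
          "variables": {"type": "object"},
          "response": {"type": "array", "minItems": 1, "items": {"type": "string"}},
          "block_weights": {"type": "array", "items": {"type": "number"}},
          "objective": {"type": "number"},
          "provenance": {"type": "object"}
        }
      }
    }
  }
}
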