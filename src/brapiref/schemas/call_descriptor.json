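{
  "type": "object",
  "properties": {
    "call": {
      "type": "string"
    },
    "category": {
      "type": "string"
    },
    "methods": {
      "type": "array",
      "items": {
        "type": "string"
      }
    },
    "datatypes": {
      "type": "array",
      "items": {
        "type": "string"
      }
    },
    "versions": {
      "type": "array",
      "items": {
        "type": "string"
      }
    }
  },
  "required": [
    "call",
    "category",
    "datatypes",
    "methods",
    "versions"
  ],
  "additionalProperties": false
}
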