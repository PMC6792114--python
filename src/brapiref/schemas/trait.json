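{
  "type": "object",
  "properties": {
    "traitDbId": {
      "type": "string"
    },
    "name": {
      "type": [
        "string",
        "null"
      ]
    },
    "description": {
      "type": [
        "string",
        "null"
      ]
    }
  },
  "required": [
    "description",
    "name",
    "traitDbId"
  ],
  "additionalProperties": false
}
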