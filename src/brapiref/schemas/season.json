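{
  "type": "object",
  "properties": {
    "seasonDbId": {
      "type": "string"
    },
    "season": {
      "type": [
        "string",
        "null"
      ]
    },
    "year": {
      "type": [
        "integer",
        "null"
      ]
    }
  },
  "required": [
    "season",
    "seasonDbId",
    "year"
  ],
  "additionalProperties": false
}
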