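{
  "type": "object",
  "properties": {
    "programDbId": {
      "type": "string"
    },
    "name": {
      "type": [
        "string",
        "null"
      ]
    },
    "abbreviation": {
      "type": [
        "string",
        "null"
      ]
    },
    "objective": {
      "type": [
        "string",
        "null"
      ]
    }
  },
  "required": [
    "abbreviation",
    "name",
    "objective",
    "programDbId"
  ],
  "additionalProperties": false
}
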