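{
  "type": "object",
  "properties": {
    "matrixDbId": {
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
    "matrixDbId",
    "name"
  ],
  "additionalProperties": false
}
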