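{
  "type": "object",
  "properties": {
    "studyTypeDbId": {
      "type": "string"
    },
    "name": {
      "type": [
        "string",
        "null"
      ]
    }
  },
  "required": [
    "name",
    "studyTypeDbId"
  ],
  "additionalProperties": false
}
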