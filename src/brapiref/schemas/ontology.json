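{
  "type": "object",
  "properties": {
    "ontologyDbId": {
      "type": "string"
    },
    "ontologyName": {
      "type": [
        "string",
        "null"
      ]
    },
    "version": {
      "type": [
        "string",
        "null"
      ]
    }
  },
  "required": [
    "ontologyDbId",
    "ontologyName",
    "version"
  ],
  "additionalProperties": false
}
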