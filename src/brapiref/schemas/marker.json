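{
  "type": "object",
  "properties": {
    "markerDbId": {
      "type": "string"
    },
    "defaultDisplayName": {
      "type": [
        "string",
        "null"
      ]
    },
    "type": {
      "type": [
        "string",
        "null"
      ]
    },
    "refAlt": {
      "type": "array",
      "items": {
        "type": "string"
      }
    },
    "synonyms": {
      "type": "array",
      "items": {
        "type": "string"
      }
    }
  },
  "required": [
    "defaultDisplayName",
    "markerDbId",
    "refAlt",
    "synonyms",
    "type"
  ],
  "additionalProperties": false
}
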