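{
  "type": "object",
  "properties": {
    "markerDbId": {
      "type": "string"
    },
    "markerProfileDbId": {
      "type": "string"
    },
    "alleleCall": {
      "type": "string"
    }
  },
  "required": [
    "alleleCall",
    "markerDbId",
    "markerProfileDbId"
  ],
  "additionalProperties": false
}
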