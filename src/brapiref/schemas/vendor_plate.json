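{
  "type": "object",
  "properties": {
    "plateDbId": {
      "type": "string"
    },
    "plateName": {
      "type": [
        "string",
        "null"
      ]
    },
    "sampleDbIds": {
      "type": "array",
      "items": {
        "type": "string"
      }
    }
  },
  "required": [
    "plateDbId",
    "plateName",
    "sampleDbIds"
  ],
  "additionalProperties": false
}
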