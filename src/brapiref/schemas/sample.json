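{
  "type": "object",
  "properties": {
    "sampleDbId": {
      "type": "string"
    },
    "germplasmDbId": {
      "type": "string"
    },
    "observationUnitDbId": {
      "type": "string"
    },
    "plateName": {
      "type": [
        "string",
        "null"
      ]
    },
    "well": {
      "type": [
        "string",
        "null"
      ]
    },
    "takenBy": {
      "type": [
        "string",
        "null"
      ]
    },
    "sampleTimestamp": {
      "type": [
        "string",
        "null"
      ]
    }
  },
  "required": [
    "germplasmDbId",
    "observationUnitDbId",
    "plateName",
    "sampleDbId",
    "sampleTimestamp",
    "takenBy",
    "well"
  ],
  "additionalProperties": false
}
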