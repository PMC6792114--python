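{
  "type": "object",
  "properties": {
    "observationUnitDbId": {
      "type": "string"
    },
    "studyDbId": {
      "type": "string"
    },
    "germplasmDbId": {
      "type": "string"
    },
    "replicate": {
      "type": [
        "integer",
        "null"
      ]
    },
    "blockNumber": {
      "type": [
        "integer",
        "null"
      ]
    },
    "positionCoordinateX": {
      "type": [
        "string",
        "null"
      ]
    },
    "positionCoordinateY": {
      "type": [
        "string",
        "null"
      ]
    }
  },
  "required": [
    "blockNumber",
    "germplasmDbId",
    "observationUnitDbId",
    "positionCoordinateX",
    "positionCoordinateY",
    "replicate",
    "studyDbId"
  ],
  "additionalProperties": false
}
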