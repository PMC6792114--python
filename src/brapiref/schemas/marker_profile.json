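{
  "type": "object",
  "properties": {
    "markerProfileDbId": {
      "type": "string"
    },
    "germplasmDbId": {
      "type": "string"
    },
    "extractDbId": {
      "type": [
        "string",
        "null"
      ]
    },
    "analysisMethod": {
      "type": [
        "string",
        "null"
      ]
    },
    "resultCount": {
      "type": "integer",
      "minimum": 0
    }
  },
  "required": [
    "analysisMethod",
    "extractDbId",
    "germplasmDbId",
    "markerProfileDbId",
    "resultCount"
  ],
  "additionalProperties": false
}
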