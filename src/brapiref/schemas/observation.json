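{
  "type": "object",
  "properties": {
    "observationDbId": {
      "type": "string"
    },
    "observationUnitDbId": {
      "type": "string"
    },
    "observationVariableDbId": {
      "type": "string"
    },
    "value": {
      "type": [
        "string",
        "null"
      ]
    },
    "observationTimeStamp": {
      "type": [
        "string",
        "null"
      ]
    }
  },
  "required": [
    "observationDbId",
    "observationTimeStamp",
    "observationUnitDbId",
    "observationVariableDbId",
    "value"
  ],
  "additionalProperties": false
}
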