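{
  "type": "object",
  "properties": {
    "studyDbId": {
      "type": "string"
    },
    "trialDbId": {
      "type": "string"
    },
    "locationDbId": {
      "type": "string"
    },
    "studyName": {
      "type": [
        "string",
        "null"
      ]
    },
    "studyType": {
      "type": [
        "string",
        "null"
      ]
    },
    "seasons": {
      "type": "array",
      "items": {
        "type": "string"
      }
    }
  },
  "required": [
    "locationDbId",
    "seasons",
    "studyDbId",
    "studyName",
    "studyType",
    "trialDbId"
  ],
  "additionalProperties": false
}
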