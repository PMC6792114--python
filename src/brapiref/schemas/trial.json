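{
  "type": "object",
  "properties": {
    "trialDbId": {
      "type": "string"
    },
    "programDbId": {
      "type": "string"
    },
    "trialName": {
      "type": [
        "string",
        "null"
      ]
    },
    "studies": {
      "type": "array",
      "items": {
        "type": "object",
        "properties": {
          "studyDbId": {
            "type": "string"
          },
          "studyName": {
            "type": [
              "string",
              "null"
            ]
          }
        },
        "required": [
          "studyDbId",
          "studyName"
        ],
        "additionalProperties": false
      }
    }
  },
  "required": [
    "programDbId",
    "studies",
    "trialDbId",
    "trialName"
  ],
  "additionalProperties": false
}
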