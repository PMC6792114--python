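{
  "type": "object",
  "properties": {
    "mapDbId": {
      "type": "string"
    },
    "name": {
      "type": [
        "string",
        "null"
      ]
    },
    "type": {
      "enum": [
        "genetic",
        "physical"
      ]
    },
    "linkageGroups": {
      "type": "array",
      "items": {
        "type": "object",
        "properties": {
          "linkageGroupName": {
            "type": "string"
          },
          "markerCount": {
            "type": "integer",
            "minimum": 0
          },
          "maxPosition": {
            "type": "number"
          }
        },
        "required": [
          "linkageGroupName",
          "markerCount",
          "maxPosition"
        ],
        "additionalProperties": false
      }
    }
  },
  "required": [
    "linkageGroups",
    "mapDbId",
    "name",
    "type"
  ],
  "additionalProperties": false
}
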