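{
  "type": "object",
  "properties": {
    "locationDbId": {
      "type": "string"
    },
    "name": {
      "type": [
        "string",
        "null"
      ]
    },
    "countryCode": {
      "type": [
        "string",
        "null"
      ]
    },
    "latitude": {
      "type": [
        "number",
        "null"
      ]
    },
    "longitude": {
      "type": [
        "number",
        "null"
      ]
    }
  },
  "required": [
    "countryCode",
    "latitude",
    "locationDbId",
    "longitude",
    "name"
  ],
  "additionalProperties": false
}
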