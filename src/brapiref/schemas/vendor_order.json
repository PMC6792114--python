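{
  "type": "object",
  "properties": {
    "orderDbId": {
      "type": "string"
    },
    "clientId": {
      "type": [
        "string",
        "null"
      ]
    },
    "plates": {
      "type": "array",
      "items": {
        "type": "string"
      }
    },
    "status": {
      "enum": [
        "registered",
        "received",
        "completed"
      ]
    },
    "results": {
      "type": "array",
      "items": {
        "type": "string"
      }
    }
  },
  "required": [
    "clientId",
    "orderDbId",
    "plates",
    "results",
    "status"
  ],
  "additionalProperties": false
}
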