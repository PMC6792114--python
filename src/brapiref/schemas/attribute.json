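{
  "type": "object",
  "properties": {
    "attributeDbId": {
      "type": "string"
    },
    "name": {
      "type": [
        "string",
        "null"
      ]
    },
    "attributeCategoryDbId": {
      "type": "string"
    },
    "datatype": {
      "type": [
        "string",
        "null"
      ]
    }
  },
  "required": [
    "attributeCategoryDbId",
    "attributeDbId",
    "datatype",
    "name"
  ],
  "additionalProperties": false
}
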