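{
  "type": "object",
  "properties": {
    "pageSize": {
      "type": "integer",
      "minimum": 0
    },
    "currentPage": {
      "type": "integer",
      "minimum": 0
    },
    "totalCount": {
      "type": "integer",
      "minimum": 0
    },
    "totalPages": {
      "type": "integer",
      "minimum": 0
    }
  },
  "required": [
    "pageSize",
    "currentPage",
    "totalCount",
    "totalPages"
  ],
  "additionalProperties": false
}
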