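{
  "type": "object",
  "properties": {
    "metadata": {
      "type": "object",
      "properties": {
        "pagination": {
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
        },
        "status": {
          "type": "array",
          "items": {
            "type": "object",
            "properties": {
              "code": {
                "type": "string"
              },
              "message": {
                "type": "string"
              }
            },
            "required": [
              "code",
              "message"
            ],
            "additionalProperties": false
          }
        },
        "datafiles": {
          "type": "array",
          "items": {
            "type": "string"
          }
        }
      },
      "required": [
        "pagination",
        "status",
        "datafiles"
      ],
      "additionalProperties": false
    },
    "result": {
      "type": [
        "object",
        "null"
      ]
    }
  },
  "required": [
    "metadata",
    "result"
  ],
  "additionalProperties": false
}
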