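{
  "type": "object",
  "properties": {
    "observationVariableDbId": {
      "type": "string"
    },
    "name": {
      "type": [
        "string",
        "null"
      ]
    },
    "trait": {
      "type": "object",
      "properties": {
        "traitDbId": {
          "type": "string"
        },
        "name": {
          "type": [
            "string",
            "null"
          ]
        },
        "description": {
          "type": [
            "string",
            "null"
          ]
        }
      },
      "required": [
        "description",
        "name",
        "traitDbId"
      ],
      "additionalProperties": false
    },
    "method": {
      "type": "object",
      "properties": {
        "methodDbId": {
          "type": "string"
        },
        "name": {
          "type": [
            "string",
            "null"
          ]
        },
        "description": {
          "type": [
            "string",
            "null"
          ]
        }
      },
      "required": [
        "description",
        "methodDbId",
        "name"
      ],
      "additionalProperties": false
    },
    "scale": {
      "type": "object",
      "properties": {
        "scaleDbId": {
          "type": "string"
        },
        "name": {
          "type": [
            "string",
            "null"
          ]
        },
        "dataType": {
          "type": [
            "string",
            "null"
          ]
        },
        "validValues": {
          "type": "object",
          "properties": {
            "min": {
              "type": [
                "number",
                "null"
              ]
            },
            "max": {
              "type": [
                "number",
                "null"
              ]
            },
            "categories": {
              "type": "array",
              "items": {
                "type": "string"
              }
            }
          },
          "required": [
            "categories",
            "max",
            "min"
          ],
          "additionalProperties": false
        }
      },
      "required": [
        "dataType",
        "name",
        "scaleDbId",
        "validValues"
      ],
      "additionalProperties": false
    }
  },
  "required": [
    "method",
    "name",
    "observationVariableDbId",
    "scale",
    "trait"
  ],
  "additionalProperties": false
}
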