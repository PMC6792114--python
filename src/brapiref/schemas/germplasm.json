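{
  "type": "object",
  "properties": {
    "germplasmDbId": {
      "type": "string"
    },
    "germplasmName": {
      "type": [
        "string",
        "null"
      ]
    },
    "accessionNumber": {
      "type": [
        "string",
        "null"
      ]
    },
    "genus": {
      "type": [
        "string",
        "null"
      ]
    },
    "species": {
      "type": [
        "string",
        "null"
      ]
    },
    "countryOfOriginCode": {
      "type": [
        "string",
        "null"
      ]
    },
    "pedigree": {
      "type": [
        "string",
        "null"
      ]
    },
    "biologicalStatusOfAccessionCode": {
      "type": [
        "string",
        "null"
      ]
    },
    "instituteCode": {
      "type": [
        "string",
        "null"
      ]
    },
    "synonyms": {
      "type": "array",
      "items": {
        "type": "string"
      }
    },
    "commonCropName": {
      "type": [
        "string",
        "null"
      ]
    }
  },
  "required": [
    "germplasmDbId",
    "germplasmName",
    "accessionNumber",
    "genus",
    "species",
    "countryOfOriginCode",
    "pedigree",
    "biologicalStatusOfAccessionCode",
    "instituteCode",
    "synonyms",
    "commonCropName"
  ],
  "additionalProperties": false
}
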