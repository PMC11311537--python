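{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Synthetic stand-in JSON Schema for mzQC 1.0.0 structural rules",
  "description": "Hand-written schema capturing the structural constraints of the mzQC format (root object, required fields, version and timestamp and accession patterns, non-empty lists, value shapes). It is a locally authored stand-in used as an independent validation oracle, not the published schema. JSON Schema cannot express equal table-column lengths or per-element metric-accession uniqueness; those two rules are checked separately by the test harness.",
  "type": "object",
  "required": ["mzQC"],
  "properties": {
    "mzQC": {
      "type": "object",
      "required": ["version", "creationDate", "controlledVocabularies"],
      "properties": {
        "version": {
          "type": "string",
          "pattern": "^[0-9]+\\.[0-9]+\\.[0-9]+$"
        },
        "creationDate": {
          "type": "string",
          "pattern": "^[0-9]{4}-[0-9]{2}-[0-9]{2}T[0-9]{2}:[0-9]{2}:[0-9]{2}(\\.[0-9]+)?(Z|[+-][0-9]{2}:[0-9]{2})?$"
        },
        "description": { "type": "string" },
        "contactName": { "type": "string" },
        "contactAddress": { "type": "string" },
        "controlledVocabularies": {
          "type": "array",
          "minItems": 1,
          "items": { "$ref": "#/$defs/cvReference" }
        },
        "runQualities": {
          "type": "array",
          "items": { "$ref": "#/$defs/qualityElement" }
        },
        "setQualities": {
          "type": "array",
          "items": { "$ref": "#/$defs/qualityElement" }
        }
      },
      "anyOf": [
        {
          "required": ["runQualities"],
          "properties": { "runQualities": { "minItems": 1 } }
        },
        {
          "required": ["setQualities"],
          "properties": { "setQualities": { "minItems": 1 } }
        }
      ]
    }
  },
  "$defs": {
    "accession": {
      "type": "string",
      "pattern": "^[A-Z]+[A-Z0-9]*:[0-9]+$"
    },
    "cvReference": {
      "type": "object",
      "required": ["name", "uri"],
      "properties": {
        "name": { "type": "string", "minLength": 1 },
        "uri": { "type": "string", "minLength": 1 },
        "version": { "type": "string" }
      }
    },
    "cvParam": {
      "type": "object",
      "required": ["accession", "name"],
      "properties": {
        "accession": { "$ref": "#/$defs/accession" },
        "name": { "type": "string" }
      }
    },
    "inputFile": {
      "type": "object",
      "required": ["name", "location"],
      "properties": {
        "name": { "type": "string", "minLength": 1 },
        "location": { "type": "string", "minLength": 1 },
        "fileFormat": { "$ref": "#/$defs/cvParam" },
        "fileProperties": {
          "type": "array",
          "items": { "$ref": "#/$defs/cvParam" }
        }
      }
    },
    "softwareRef": {
      "type": "object",
      "required": ["accession", "name", "version"],
      "properties": {
        "accession": { "$ref": "#/$defs/accession" },
        "name": { "type": "string" },
        "version": { "type": "string" }
      }
    },
    "metadata": {
      "type": "object",
      "required": ["inputFiles", "analysisSoftware"],
      "properties": {
        "inputFiles": {
          "type": "array",
          "minItems": 1,
          "items": { "$ref": "#/$defs/inputFile" }
        },
        "analysisSoftware": {
          "type": "array",
          "minItems": 1,
          "items": { "$ref": "#/$defs/softwareRef" }
        },
        "label": { "type": "string" },
        "cvParameters": {
          "type": "array",
          "items": { "$ref": "#/$defs/cvParam" }
        }
      }
    },
    "scalar": { "type": ["number", "string", "boolean"] },
    "metricValue": {
      "anyOf": [
        { "$ref": "#/$defs/scalar" },
        {
          "type": "array",
          "minItems": 1,
          "items": { "$ref": "#/$defs/scalar" }
        },
        {
          "type": "object",
          "minProperties": 1,
          "additionalProperties": {
            "type": "array",
            "items": { "$ref": "#/$defs/scalar" }
          }
        }
      ]
    },
    "qualityMetric": {
      "type": "object",
      "required": ["accession", "name", "value"],
      "properties": {
        "accession": { "$ref": "#/$defs/accession" },
        "name": { "type": "string" },
        "description": { "type": "string" },
        "value": { "$ref": "#/$defs/metricValue" },
        "unit": {
          "anyOf": [
            { "$ref": "#/$defs/cvParam" },
            { "type": "array", "items": { "$ref": "#/$defs/cvParam" } }
          ]
        }
      }
    },
    "qualityElement": {
      "type": "object",
      "required": ["metadata", "qualityMetrics"],
      "properties": {
        "metadata": { "$ref": "#/$defs/metadata" },
        "qualityMetrics": {
          "type": "array",
          "minItems": 1,
          "items": { "$ref": "#/$defs/qualityMetric" }
        }
      }
    }
  }
}
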