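{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "dSON JSON export",
  "type": "object",
  "required": ["name", "facets", "negated_concepts", "multiple_concept_queries"],
  "additionalProperties": false,
  "properties": {
    "name": {"type": "string"},
    "facets": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["name", "children"],
        "additionalProperties": false,
        "properties": {
          "name": {"type": "string"},
          "children": {"type": "array", "items": {"$ref": "#/$defs/node"}}
        }
      }
    },
    "negated_concepts": {"type": "array", "items": {"$ref": "#/$defs/node"}},
    "multiple_concept_queries": {"type": "array", "items": {"$ref": "#/$defs/node"}}
  },
  "$defs": {
    "node": {
      "type": "object",
      "required": ["name", "type", "simple_terms", "query", "children"],
      "additionalProperties": false,
      "properties": {
        "name": {"type": "string"},
        "type": {
          "type": "string",
          "enum": ["concept", "negated_concept", "composite_term", "multiple_concept_query"]
        },
        "simple_terms": {
          "type": "object",
          "required": ["en", "de"],
          "additionalProperties": false,
          "properties": {
            "en": {"type": "array", "items": {"type": "string"}},
            "de": {"type": "array", "items": {"type": "string"}}
          }
        },
        "query": {
          "type": "object",
          "additionalProperties": false,
          "properties": {
            "en": {"type": "string"},
            "de": {"type": "string"}
          }
        },
        "children": {"type": "array", "items": {"$ref": "#/$defs/node"}}
      }
    }
  }
}
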