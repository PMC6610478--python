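{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "$id": "lifescreen-report.schema.json",
  "title": "Lifestyle screening report",
  "type": "object",
  "required": ["meta", "components", "messages", "referral"],
  "properties": {
    "meta": {
      "type": "object",
      "required": ["engine", "ruleset_version", "schema_version", "rule_variant"],
      "properties": {
        "engine": {"const": "lifescreen"},
        "ruleset_version": {"type": "string"},
        "schema_version": {"type": "string"},
        "rule_variant": {"enum": ["as_printed", "narrative_corrected"]},
        "respondent_id": {"type": ["string", "null"]},
        "generated_at": {"type": "string"}
      }
    },
    "components": {
      "type": "array",
      "minItems": 8,
      "maxItems": 8,
      "items": {
        "type": "object",
        "required": ["id", "title", "aggregate", "color", "sub_blocks", "items"],
        "properties": {
          "id": {"type": "integer", "minimum": 1, "maximum": 8},
          "title": {"type": "string"},
          "aggregate": {"enum": ["low", "moderate", "relevant", "not_scored"]},
          "color": {"enum": ["green", "yellow", "orange", "none"]},
          "sub_blocks": {
            "type": "object",
            "additionalProperties": {"enum": ["low", "moderate", "relevant", "not_scored"]}
          },
          "items": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["item", "answer", "risk", "rule"],
              "properties": {
                "item": {"type": "string"},
                "risk": {"enum": ["low", "moderate", "relevant", "not_scored"]},
                "rule": {"type": "string"}
              }
            }
          }
        }
      }
    },
    "messages": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["component", "sub_block", "risk", "text"],
        "properties": {
          "component": {"type": "integer", "minimum": 1, "maximum": 8},
          "sub_block": {"type": "string"},
          "risk": {"enum": ["low", "moderate", "relevant", "not_scored"]},
          "text": {"type": "string"}
        }
      }
    },
    "referral": {
      "type": "object",
      "required": ["instruments", "triggering_components"],
      "properties": {
        "instruments": {
          "type": "array",
          "items": {
            "type": "object",
            "required": ["name", "optional", "triggered_by"],
            "properties": {
              "name": {"type": "string"},
              "optional": {"type": "boolean"},
              "triggered_by": {"type": "array", "items": {"type": "integer"}}
            }
          }
        },
        "triggering_components": {"type": "array", "items": {"type": "integer"}}
      }
    }
  }
}
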