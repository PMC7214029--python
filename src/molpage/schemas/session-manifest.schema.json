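{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "molpage:session-manifest",
  "title": "molpage session manifest",
  "description": "Everything extractable from a desktop-viewer session: loaded structures, per-selection representations, colors, and the 18-float camera state.",
  "type": "object",
  "required": ["schema", "objects", "reps", "view"],
  "additionalProperties": false,
  "properties": {
    "schema": {"const": 1},
    "objects": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "object",
        "required": ["id"],
        "additionalProperties": false,
        "properties": {
          "id": {"type": "string", "minLength": 1},
          "pdb_text": {"type": "string", "minLength": 1},
          "pdb_path": {"type": "string", "minLength": 1},
          "visible": {"type": "boolean", "default": true}
        }
      }
    },
    "reps": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["object_id", "kind", "selection"],
        "additionalProperties": false,
        "properties": {
          "object_id": {"type": "string"},
          "kind": {"type": "string"},
          "selection": {"type": "string", "minLength": 1},
          "color": {
            "anyOf": [
              {"type": "string"},
              {"type": "integer", "minimum": 0},
              {
                "type": "array",
                "minItems": 1,
                "items": {
                  "type": "object",
                  "required": ["selection", "color"],
                  "additionalProperties": false,
                  "properties": {
                    "selection": {"type": "string"},
                    "color": {
                      "anyOf": [{"type": "string"},
                                {"type": "integer", "minimum": 0}]
                    }
                  }
                }
              }
            ]
          },
          "opacity": {
            "type": "number",
            "exclusiveMinimum": 0,
            "maximum": 1
          }
        }
      }
    },
    "view": {
      "type": "array",
      "minItems": 18,
      "maxItems": 18,
      "items": {"type": "number"}
    },
    "background": {
      "anyOf": [{"type": "string"}, {"type": "integer", "minimum": 0}]
    }
  }
}
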