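{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "molpage:page-document",
  "title": "molpage page document",
  "description": "Scripted-use JSON form of a PageDocument: title, markdown body with prolink anchors, ordered viewspecs, options.",
  "type": "object",
  "required": ["title", "body_markdown", "viewspecs", "initial_view"],
  "additionalProperties": false,
  "properties": {
    "title": {"type": "string"},
    "body_markdown": {"type": "string"},
    "initial_view": {"type": "string"},
    "front_image": {"type": ["string", "null"]},
    "options": {
      "type": "object",
      "additionalProperties": false,
      "properties": {
        "offline": {"type": "boolean"},
        "background": {"type": "string"},
        "spin": {"type": "boolean"}
      }
    },
    "viewspecs": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "object",
        "required": ["id", "structures"],
        "additionalProperties": false,
        "properties": {
          "id": {"type": "string"},
          "background": {"type": "string"},
          "camera": {
            "anyOf": [
              {"type": "null"},
              {"type": "array", "minItems": 16, "maxItems": 16,
               "items": {"type": "number"}}
            ]
          },
          "structures": {
            "type": "array",
            "minItems": 1,
            "items": {
              "type": "object",
              "required": ["id", "pdb_text"],
              "additionalProperties": false,
              "properties": {
                "id": {"type": "string"},
                "pdb_text": {"type": "string"},
                "visible": {"type": "boolean"}
              }
            }
          },
          "representations": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["kind", "selection"],
              "additionalProperties": false,
              "properties": {
                "kind": {"type": "string"},
                "selection": {"type": "string"},
                "color": {},
                "opacity": {"type": "number"},
                "object_id": {"type": ["string", "null"]},
                "visible": {"type": "boolean"}
              }
            }
          }
        }
      }
    }
  }
}
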