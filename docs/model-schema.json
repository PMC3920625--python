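{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "CS-PBN network file",
  "description": "Context-sensitive probabilistic Boolean network. The document is YAML (any JSON document is valid YAML). Expressions use identifiers, '!' (NOT), '&' (AND), '|' (OR), parentheses and the literals 0/1; '!' binds tighter than '&' tighter than '|'. Per gene the candidate probabilities must sum to 1 (tolerance 1e-9).",
  "type": "object",
  "required": ["genes", "inputs", "q", "x0", "j0"],
  "additionalProperties": false,
  "properties": {
    "genes": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "object",
        "required": ["name", "functions"],
        "additionalProperties": false,
        "properties": {
          "name": {"type": "string", "pattern": "^[A-Za-z_][A-Za-z_0-9]*$"},
          "functions": {
            "type": "array",
            "minItems": 1,
            "items": {
              "type": "object",
              "required": ["expr", "prob"],
              "additionalProperties": false,
              "properties": {
                "expr": {"type": "string", "description": "Boolean update expression over declared gene and input names"},
                "prob": {"type": "number", "minimum": 0, "maximum": 1, "description": "selection probability c_j of this candidate"}
              }
            }
          }
        }
      }
    },
    "inputs": {
      "type": "array",
      "items": {"type": "string", "pattern": "^[A-Za-z_][A-Za-z_0-9]*$"},
      "description": "binary control-input names (may be empty)"
    },
    "q": {
      "type": "number",
      "minimum": 0,
      "maximum": 1,
      "description": "switching probability: per step each gene re-draws its update function with probability q and keeps the current one with 1-q"
    },
    "x0": {
      "type": "array",
      "items": {"type": "integer", "enum": [0, 1]},
      "description": "initial binary state, one entry per gene"
    },
    "j0": {
      "type": "array",
      "items": {"type": "integer", "minimum": 1},
      "description": "1-based index of each gene's initially active candidate function"
    }
  }
}
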