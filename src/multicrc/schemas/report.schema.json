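{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "multicrc analysis report",
  "type": "object",
  "required": ["tool", "input", "config", "results"],
  "properties": {
    "tool": {
      "type": "object",
      "required": ["name", "version"],
      "properties": {
        "name": {"type": "string"},
        "version": {"type": "string"}
      }
    },
    "input": {
      "type": "object",
      "required": ["k", "n", "counts", "n_j", "f_i", "u_j"],
      "properties": {
        "k": {"type": "integer"},
        "n": {"type": "integer"},
        "event_names": {"type": "array", "items": {"type": "string"}},
        "counts": {"type": "object"},
        "n_j": {"type": "array", "items": {"type": "integer"}},
        "f_i": {"type": "array", "items": {"type": "integer"}},
        "u_j": {"type": "array", "items": {"type": "integer"}},
        "warnings": {"type": "array", "items": {"type": "string"}}
      }
    },
    "config": {
      "type": "object",
      "required": ["seed", "level", "methods"],
      "properties": {
        "seed": {"type": "integer"},
        "level": {"type": "number"},
        "methods": {"type": "array", "items": {"type": "string"}}
      }
    },
    "results": {
      "type": "object",
      "properties": {
        "loglinear": {
          "type": "array",
          "items": {
            "type": "object",
            "required": ["model"],
            "properties": {
              "model": {"type": "string"},
              "lower_bound": {"type": "boolean"}
            }
          }
        },
        "chao_moment_bound": {
          "type": "object",
          "required": ["N_hat", "se", "ci"]
        },
        "pairwise": {
          "type": "array",
          "items": {
            "type": "object",
            "required": ["pair", "n_a", "n_b", "m", "N_hat"]
          }
        },
        "bma": {"type": "object"},
        "lcmcr": {"type": "object"}
      }
    }
  }
}
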