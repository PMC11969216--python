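{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "mutclock analysis report",
  "type": "object",
  "required": [
    "version",
    "seed",
    "config",
    "data",
    "global_fit",
    "groups",
    "model_comparison",
    "error_sweep"
  ],
  "properties": {
    "version": {"type": "string"},
    "seed": {"type": "integer"},
    "config": {"type": "object"},
    "data": {
      "type": "object",
      "required": ["n_read", "n_rejected", "n_matched", "dropped_from_tree"],
      "properties": {
        "n_read": {"type": "integer"},
        "n_rejected": {"type": "integer"},
        "n_matched": {"type": "integer"},
        "dropped_from_tree": {"type": "array", "items": {"type": "string"}}
      }
    },
    "global_fit": {
      "type": "object",
      "required": ["coefficients", "standard_errors", "p_values", "adjusted_r2", "lambda", "n"],
      "properties": {
        "coefficients": {"type": "object"},
        "standard_errors": {"type": "object"},
        "p_values": {"type": "object"},
        "adjusted_r2": {"type": "number"},
        "residual_variance": {"type": "number"},
        "lambda": {"type": "number"},
        "n": {"type": "integer"},
        "df_residual": {"type": "integer"},
        "log_likelihood": {"type": "number"},
        "doubling_effect_percent": {"type": "number"}
      }
    },
    "groups": {"type": "array", "items": {"type": "object"}},
    "groups_skipped": {"type": "array", "items": {"type": "object"}},
    "model_comparison": {
      "type": "object",
      "required": ["aic", "lrt"],
      "properties": {
        "aic": {"type": "array", "items": {"type": "object"}},
        "lrt": {"type": "array", "items": {"type": "object"}}
      }
    },
    "error_sweep": {
      "type": "object",
      "required": ["config", "target_slope", "crossing_ratio", "analytic_crossing_ratio", "grid"],
      "properties": {
        "config": {"type": "object"},
        "target_slope": {"type": "number"},
        "crossing_ratio": {"type": "number"},
        "analytic_crossing_ratio": {"type": "number"},
        "grid": {"type": "array", "items": {"type": "object"}}
      }
    }
  }
}
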